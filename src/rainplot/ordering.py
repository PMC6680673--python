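"""Row orderings for rain plots and heatmaps, plus top-k selection.

Three orderings are supported, mirroring the three ways a metabolite x
outcome display is conventionally arranged: ascending summary P value,
ascending mass-to-charge ratio, and hierarchical-clustering leaf order over
each metabolite's effect-size profile.

All orderings return a 0-based permutation of the grid's metabolite
indices; sorts are stable so ties preserve input order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist

from .core_io import AssociationGrid, MetaboliteAnnotation, SchemaError

__all__ = [
    "OrderingSpec",
    "order_by_pvalue",
    "order_by_mz",
    "order_by_cluster",
    "select_top_k",
    "summary_pvalues",
    "DEFAULT_TOP_K",
]

DEFAULT_TOP_K = 50


@dataclass(frozen=True)
class OrderingSpec:
    """How to arrange metabolite rows.

    ``pvalue_summary`` controls which P value represents a metabolite when
    several outcomes exist per row: the minimum across outcomes (default) or
    a single anchor outcome's P. ``anchor`` is required exactly when
    ``pvalue_summary="anchor_outcome"``.
    """

    method: Literal["pvalue", "mz", "cluster", "given"] = "pvalue"
    pvalue_summary: Literal["min_across_outcomes", "anchor_outcome"] = (
        "min_across_outcomes"
    )
    anchor: str | None = None
    linkage: Literal["average", "complete", "single", "ward"] = "average"
    distance: Literal["euclidean", "correlation"] = "euclidean"

    def __post_init__(self) -> None:
        if self.pvalue_summary == "anchor_outcome" and self.anchor is None:
            raise SchemaError("anchor outcome required for anchor_outcome summary")
        if self.pvalue_summary == "min_across_outcomes" and self.anchor is not None:
            raise SchemaError("anchor given but pvalue_summary is min_across_outcomes")


def summary_pvalues(grid: AssociationGrid, spec: OrderingSpec) -> np.ndarray:
    """Per-metabolite summary P used for sorting and top-k selection.

    Non-converged (NaN) cells are ignored; a metabolite with no usable P
    sorts last (summary +inf).
    """
    P = grid.p_matrix()
    if spec.pvalue_summary == "anchor_outcome":
        if spec.anchor not in grid.outcomes:
            raise SchemaError(
                f"anchor outcome {spec.anchor!r} not in panel {grid.outcomes}"
            )
        vals = P[spec.anchor].to_numpy()
    else:
        with np.errstate(all="ignore"):
            vals = np.nanmin(P.to_numpy(), axis=1)
    return np.where(np.isnan(vals), np.inf, vals)


def order_by_pvalue(
    grid: AssociationGrid, spec: OrderingSpec | None = None
) -> np.ndarray:
    """Metabolite indices sorted by ascending summary P (stable on ties)."""
    spec = spec or OrderingSpec()
    return np.argsort(summary_pvalues(grid, spec), kind="stable")


def order_by_mz(annotations: Sequence[MetaboliteAnnotation]) -> np.ndarray:
    """Indices sorted by ascending mass-to-charge value (stable on ties)."""
    mz = np.array([a.mz for a in annotations], dtype=float)
    if np.isnan(mz).any():
        bad = [annotations[i].metabolite_id for i in np.flatnonzero(np.isnan(mz))]
        raise SchemaError(f"missing m/z for metabolites: {bad}")
    return np.argsort(mz, kind="stable")


def _leaf_order(Z: np.ndarray, n: int) -> np.ndarray:
    """Dendrogram leaf order with the smaller cluster index visited first
    at every merge (deterministic, independent of library internals)."""
    order: list[int] = []
    stack = [int(2 * n - 2)]  # root cluster index
    while stack:
        node = stack.pop()
        if node < n:
            order.append(node)
            continue
        left, right = int(Z[node - n, 0]), int(Z[node - n, 1])
        if left > right:
            left, right = right, left
        # LIFO stack: push the larger index first so the smaller is visited first
        stack.append(right)
        stack.append(left)
    return np.array(order, dtype=int)


def order_by_cluster(
    grid: AssociationGrid, spec: OrderingSpec | None = None
) -> np.ndarray:
    """Leaf order of agglomerative hierarchical clustering on beta profiles.

    Each metabolite is represented by its vector of beta coefficients
    across outcomes; rows are clustered (default: Euclidean distance,
    average linkage) and returned in dendrogram leaf order with a
    deterministic child-ordering rule (smaller cluster index first).
    """
    spec = spec or OrderingSpec(method="cluster")
    B = grid.beta_matrix().to_numpy()
    if not np.all(np.isfinite(B)):
        bad = [
            grid.metabolite_ids[i]
            for i in np.flatnonzero(~np.isfinite(B).all(axis=1))
        ]
        raise SchemaError(f"non-finite beta for metabolites: {bad[:5]}")
    n = B.shape[0]
    if n == 1:
        return np.array([0])
    D = pdist(B, metric=spec.distance)
    if not np.all(np.isfinite(D)):
        raise SchemaError(
            "non-finite pairwise distances (constant beta profile under "
            "correlation distance?)"
        )
    Z = linkage(D, method=spec.linkage)
    return _leaf_order(Z, n)


def select_top_k(
    grid: AssociationGrid,
    k: int = DEFAULT_TOP_K,
    spec: OrderingSpec | None = None,
) -> AssociationGrid:
    """Restrict the grid to the k metabolites with smallest summary P.

    Uses the same summary rule as :func:`order_by_pvalue`; the returned
    grid keeps the selected metabolites in ascending summary-P order and is
    still complete over the retained rows. ``k >= n`` returns all
    metabolites.
    """
    if k < 1:
        raise SchemaError(f"k must be >= 1, got {k}")
    spec = spec or OrderingSpec()
    perm = order_by_pvalue(grid, spec)
    keep = perm[: min(k, grid.n_metabolites)]
    return grid.subset([grid.metabolite_ids[i] for i in keep])
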