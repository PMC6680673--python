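"""Renderer-independent plot models for the four figure types.

Every visual encoding rule lives here, on plain data structures, so it can
be tested without rasterizing anything:

* RainPlotModel — metabolites x outcomes grid of circles ("droplets"):
  fill color encodes the beta coefficient on a symmetric diverging scale,
  circle size encodes -log10(P).
* ManhattanModel — one facet per outcome sharing a y axis; points at
  (m/z, -log10 P) colored by effect direction. Significance and direction
  only: no magnitude channel.
* BarScatterModel — one outcome; signed beta bars plus -log10(P) dots on a
  shared metabolite axis.
* PairedHeatmapModel — two aligned matrices (betas, -log10 P) that jointly
  convey what the rain plot conveys in one panel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .core_io import AssociationGrid, SchemaError

__all__ = [
    "NEGLOG10_CAP",
    "neglog10",
    "RainPlotConfig",
    "RainCell",
    "RainPlotModel",
    "ManhattanModel",
    "BarScatterModel",
    "PairedHeatmapModel",
    "build_rainplot_model",
    "build_manhattan_model",
    "build_barscatter_model",
    "build_paired_heatmap_model",
]

NEGLOG10_CAP = 300.0
DEFAULT_ALPHA = 0.05


def neglog10(p: float | np.ndarray, cap: float = NEGLOG10_CAP):
    """-log10(p) for p in (0, 1], capped at ``cap`` for underflow-level p."""
    arr = np.asarray(p, dtype=float)
    if np.any(arr <= 0) or np.any(arr > 1):
        raise SchemaError(f"P values must lie in (0, 1], got {arr[(arr <= 0) | (arr > 1)]}")
    out = np.minimum(-np.log10(arr), cap)
    return float(out) if np.isscalar(p) or arr.ndim == 0 else out


def _bonferroni_cap(n_metabolites: int, alpha: float = DEFAULT_ALPHA) -> float:
    """-log10 of the Bonferroni threshold alpha / m."""
    return float(-math.log10(alpha / n_metabolites))


def _symmetric_limits(betas: np.ndarray) -> tuple[float, float]:
    finite = betas[np.isfinite(betas)]
    L = float(np.max(np.abs(finite))) if finite.size else 1.0
    if L == 0.0:
        L = 1.0
    return (-L, L)


@dataclass(frozen=True)
class RainPlotConfig:
    """Tunable encodings for the rain plot.

    Radii are in cell units (a grid cell is 1 x 1). ``size_mode`` selects
    whether the radius or the disc area grows linearly with capped
    -log10(P); ``sig_bins`` switches to a stepped encoding with that many
    significance tiers instead of a continuous one.
    """

    r_min: float = 0.08
    r_max: float = 0.42
    size_mode: str = "radius"  # or "area"
    cap_sig: float | None = None  # default: Bonferroni -log10(alpha/m)
    alpha: float = DEFAULT_ALPHA
    color_limit: float | None = None  # default: max |beta| over the grid
    sig_bins: int | None = None
    cap: float = NEGLOG10_CAP

    def __post_init__(self) -> None:
        if not (0 <= self.r_min < self.r_max):
            raise SchemaError("require 0 <= r_min < r_max")
        if self.size_mode not in ("radius", "area"):
            raise SchemaError(f"unknown size_mode {self.size_mode!r}")
        if self.sig_bins is not None and self.sig_bins < 2:
            raise SchemaError("sig_bins must be >= 2")


@dataclass(frozen=True)
class RainCell:
    row: int
    col: int
    metabolite_id: str
    outcome: str
    fill_value: float  # beta, clipped to color_limits
    radius_value: float  # capped -log10(p)
    radius: float  # display radius in cell units


@dataclass(frozen=True)
class RainPlotModel:
    rows: tuple[str, ...]
    cols: tuple[str, ...]
    cells: tuple[RainCell, ...]
    color_limits: tuple[float, float]
    radius_range: tuple[float, float]
    cap: float

    # channels exposed by this display (one model object carries all three,
    # for every outcome at once)
    channels = ("magnitude", "directionality", "significance")
    multi_outcome = True


def _display_radius(frac: np.ndarray, cfg: RainPlotConfig) -> np.ndarray:
    if cfg.size_mode == "radius":
        return cfg.r_min + (cfg.r_max - cfg.r_min) * frac
    # area mode: disc area interpolates linearly
    return np.sqrt(cfg.r_min**2 + (cfg.r_max**2 - cfg.r_min**2) * frac)


def build_rainplot_model(
    grid: AssociationGrid,
    row_order: Sequence[int] | None = None,
    config: RainPlotConfig | None = None,
) -> RainPlotModel:
    """Encode a complete grid as a rain plot.

    Rows follow ``row_order`` top to bottom (default: grid order); columns
    follow panel display order left to right. Fill is beta clipped to
    symmetric color limits; the display radius grows monotonically with
    -log10(P), saturating at ``cap_sig`` (default: the Bonferroni threshold
    -log10(alpha/m), a floor of maximal visual significance).
    """
    cfg = config or RainPlotConfig()
    n = grid.n_metabolites
    if row_order is None:
        row_order = np.arange(n)
    row_order = np.asarray(row_order, dtype=int)
    if sorted(row_order.tolist()) != list(range(n)):
        raise SchemaError("row_order is not a permutation of metabolite indices")

    ordered = grid.reorder(row_order)
    B = ordered.beta_matrix().to_numpy()
    P = ordered.p_matrix().to_numpy()

    lim = cfg.color_limit
    color_limits = (-lim, lim) if lim else _symmetric_limits(B)
    cap_sig = cfg.cap_sig if cfg.cap_sig is not None else _bonferroni_cap(n, cfg.alpha)

    cells: list[RainCell] = []
    for i, mid in enumerate(ordered.metabolite_ids):
        for j, out in enumerate(ordered.outcomes):
            p, b = P[i, j], B[i, j]
            if not (np.isfinite(p) and np.isfinite(b)):
                continue  # non-converged sentinel: droplet omitted
            rv = neglog10(p, cfg.cap)
            frac = min(rv, cap_sig) / cap_sig
            if cfg.sig_bins is not None:
                frac = math.floor(frac * cfg.sig_bins) / cfg.sig_bins
                frac = min(frac + 1.0 / cfg.sig_bins, 1.0) if rv > 0 else frac
            radius = float(_display_radius(np.asarray(frac), cfg))
            cells.append(
                RainCell(
                    row=i,
                    col=j,
                    metabolite_id=mid,
                    outcome=out,
                    fill_value=float(np.clip(b, *color_limits)),
                    radius_value=rv,
                    radius=radius,
                )
            )
    return RainPlotModel(
        rows=tuple(ordered.metabolite_ids),
        cols=tuple(ordered.outcomes),
        cells=tuple(cells),
        color_limits=color_limits,
        radius_range=(cfg.r_min, cfg.r_max),
        cap=cap_sig,
    )


@dataclass(frozen=True)
class ManhattanModel:
    facets: tuple[str, ...]  # outcomes, panel order
    points: pd.DataFrame  # columns: outcome, metabolite_id, mz, y, direction
    threshold_line: float
    ylim: tuple[float, float]
    x_mode: str  # "mz" or "rank"

    channels = ("significance", "directionality")
    multi_outcome = True

    def facet_points(self, outcome: str) -> pd.DataFrame:
        return self.points[self.points["outcome"] == outcome]


def build_manhattan_model(
    grid: AssociationGrid,
    alpha: float = DEFAULT_ALPHA,
    *,
    bonferroni: bool = True,
    x_mode: str = "mz",
    cap: float = NEGLOG10_CAP,
) -> ManhattanModel:
    """One facet per outcome; points at (m/z, -log10 P), shared y axis.

    The significance line defaults to the Bonferroni cutoff alpha / m with
    m = number of metabolites; ``bonferroni=False`` draws it at raw alpha.
    ``x_mode="rank"`` positions points by m/z rank instead of value.
    """
    if x_mode not in ("mz", "rank"):
        raise SchemaError(f"unknown x_mode {x_mode!r}")
    mz = grid.mz_values
    if np.isnan(mz).any():
        raise SchemaError("missing m/z values; Manhattan x axis needs them")
    x = mz if x_mode == "mz" else np.argsort(np.argsort(mz, kind="stable")) + 1.0

    rows = []
    for j, out in enumerate(grid.outcomes):
        pcol = grid.p_matrix()[out].to_numpy()
        bcol = grid.beta_matrix()[out].to_numpy()
        for i, mid in enumerate(grid.metabolite_ids):
            if not (np.isfinite(pcol[i]) and np.isfinite(bcol[i])):
                continue
            rows.append(
                {
                    "outcome": out,
                    "metabolite_id": mid,
                    "mz": float(x[i]),
                    "y": neglog10(pcol[i], cap),
                    "direction": int(np.sign(bcol[i])),
                }
            )
    points = pd.DataFrame(rows)
    m = grid.n_metabolites
    cutoff = alpha / m if bonferroni else alpha
    threshold = float(-math.log10(cutoff))
    ymax = max(float(points["y"].max()), threshold) * 1.05 if len(points) else 1.0
    return ManhattanModel(
        facets=tuple(grid.outcomes),
        points=points,
        threshold_line=threshold,
        ylim=(0.0, ymax),
        x_mode=x_mode,
    )


@dataclass(frozen=True)
class BarScatterModel:
    outcome: str
    metabolite_ids: tuple[str, ...]
    bar_heights: tuple[float, ...]  # signed betas
    dot_values: tuple[float, ...]  # -log10(p)

    channels = ("magnitude", "directionality", "significance")
    multi_outcome = False


def build_barscatter_model(
    grid: AssociationGrid,
    outcome: str,
    row_order: Sequence[int] | None = None,
    cap: float = NEGLOG10_CAP,
) -> BarScatterModel:
    """Signed beta bars and -log10(P) dots for a single outcome."""
    if outcome not in grid.outcomes:
        raise SchemaError(f"outcome {outcome!r} not in panel {grid.outcomes}")
    n = grid.n_metabolites
    if row_order is None:
        row_order = np.arange(n)
    row_order = np.asarray(row_order, dtype=int)
    if sorted(row_order.tolist()) != list(range(n)):
        raise SchemaError("row_order is not a permutation of metabolite indices")
    ordered = grid.reorder(row_order)
    betas = ordered.beta_matrix()[outcome].to_numpy()
    ps = ordered.p_matrix()[outcome].to_numpy()
    keep = np.isfinite(betas) & np.isfinite(ps)
    return BarScatterModel(
        outcome=outcome,
        metabolite_ids=tuple(np.array(ordered.metabolite_ids)[keep]),
        bar_heights=tuple(float(b) for b in betas[keep]),
        dot_values=tuple(float(v) for v in neglog10(ps[keep], cap)),
    )


@dataclass(frozen=True)
class PairedHeatmapModel:
    rows: tuple[str, ...]
    cols: tuple[str, ...]
    fills_beta: np.ndarray  # diverging scale
    fills_p: np.ndarray  # -log10(p), sequential scale
    beta_limits: tuple[float, float]
    p_limits: tuple[float, float]

    channels = ("magnitude", "directionality", "significance")
    multi_outcome = True
    n_matrices = 2  # two aligned plots needed for what the rain plot shows in one


def build_paired_heatmap_model(
    grid: AssociationGrid,
    row_order: Sequence[int] | None = None,
    cap: float = NEGLOG10_CAP,
) -> PairedHeatmapModel:
    """Two aligned matrices: betas (symmetric diverging limits) and
    -log10(P) (sequential [0, cap] limits), identical row/col orders."""
    n = grid.n_metabolites
    if row_order is None:
        row_order = np.arange(n)
    row_order = np.asarray(row_order, dtype=int)
    if sorted(row_order.tolist()) != list(range(n)):
        raise SchemaError("row_order is not a permutation of metabolite indices")
    ordered = grid.reorder(row_order)
    B = ordered.beta_matrix().to_numpy()
    P = ordered.p_matrix().to_numpy()
    finite = np.isfinite(P)
    NLP = np.full_like(P, np.nan)
    NLP[finite] = neglog10(P[finite], cap)
    pmax = float(np.nanmax(NLP)) if finite.any() else 1.0
    return PairedHeatmapModel(
        rows=tuple(ordered.metabolite_ids),
        cols=tuple(ordered.outcomes),
        fills_beta=B,
        fills_p=NLP,
        beta_limits=_symmetric_limits(B),
        p_limits=(0.0, pmax),
    )
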