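"""Domain types, invariant enforcement, and CSV/TSV readers/writers.

All tabular interchange is plain UTF-8 CSV or TSV with a mandatory header
row. Missing values are written as ``NA`` and parsed from either ``NA`` or
the empty string, covering both R- and spreadsheet-exported files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RainplotError",
    "SchemaError",
    "ParseError",
    "MetaboliteAnnotation",
    "AbundanceMatrix",
    "PhenotypeTable",
    "ModelSpec",
    "AssociationRecord",
    "AssociationGrid",
    "read_table",
    "write_association_grid",
]

NA_VALUES = ["", "NA"]


class RainplotError(Exception):
    """Base class for all errors raised by this package."""


class SchemaError(RainplotError, ValueError):
    """A table violates a structural or domain invariant."""


class ParseError(RainplotError, ValueError):
    """A cell could not be parsed as the expected type."""


@dataclass(frozen=True)
class MetaboliteAnnotation:
    """One LC-MS feature: an opaque id and its mass-to-charge (m/z) value."""

    metabolite_id: str
    mz: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.mz) or self.mz <= 0:
            raise SchemaError(
                f"metabolite {self.metabolite_id!r}: m/z must be finite and "
                f"positive, got {self.mz!r}"
            )


class AbundanceMatrix:
    """Samples x metabolites raw intensity matrix with explicit missingness.

    Values are stored in a float DataFrame indexed by sample id with one
    column per metabolite; missing intensities are NaN. Negative finite
    intensities and all-missing metabolite columns are rejected.
    """

    def __init__(self, values: pd.DataFrame):
        if not isinstance(values, pd.DataFrame):
            raise SchemaError("AbundanceMatrix requires a pandas DataFrame")
        if values.index.has_duplicates:
            dups = values.index[values.index.duplicated()].unique().tolist()
            raise SchemaError(f"duplicate sample ids: {dups}")
        if values.columns.has_duplicates:
            dups = values.columns[values.columns.duplicated()].unique().tolist()
            raise SchemaError(f"duplicate metabolite ids: {dups}")
        try:
            values = values.astype(float)
        except (TypeError, ValueError) as exc:
            raise ParseError(f"non-numeric intensity value: {exc}") from exc
        arr = values.to_numpy()
        if np.any(arr[np.isfinite(arr)] < 0):
            bad = values.columns[np.nanmin(arr, axis=0) < 0].tolist()
            raise SchemaError(f"negative intensities in metabolites: {bad}")
        all_missing = values.columns[values.isna().all(axis=0)].tolist()
        if all_missing:
            raise SchemaError(
                f"metabolite columns entirely missing: {all_missing}"
            )
        self.values = values

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.values.index]

    @property
    def metabolite_ids(self) -> list[str]:
        return [str(m) for m in self.values.columns]

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_metabolites(self) -> int:
        return self.values.shape[1]

    def n_missing(self) -> int:
        return int(self.values.isna().to_numpy().sum())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AbundanceMatrix):
            return NotImplemented
        return self.values.equals(other.values)

    def __repr__(self) -> str:
        return (
            f"AbundanceMatrix({self.n_samples} samples x "
            f"{self.n_metabolites} metabolites, {self.n_missing()} missing)"
        )


class PhenotypeTable:
    """Per-sample outcome and covariate columns, each continuous or binary.

    Binary variables must be coded {0, 1} (missing allowed). If ``kinds`` is
    omitted, a column whose observed values are a subset of {0, 1} is tagged
    binary, everything else continuous.
    """

    def __init__(
        self,
        values: pd.DataFrame,
        kinds: Mapping[str, str] | None = None,
    ):
        if values.index.has_duplicates:
            dups = values.index[values.index.duplicated()].unique().tolist()
            raise SchemaError(f"duplicate sample ids: {dups}")
        try:
            values = values.astype(float)
        except (TypeError, ValueError) as exc:
            raise ParseError(f"non-numeric phenotype value: {exc}") from exc
        if kinds is None:
            kinds = {
                col: "binary"
                if set(values[col].dropna().unique()) <= {0.0, 1.0}
                else "continuous"
                for col in values.columns
            }
        else:
            kinds = dict(kinds)
            unknown = set(kinds) - set(values.columns)
            if unknown:
                raise SchemaError(f"kinds given for unknown variables: {sorted(unknown)}")
            missing = set(values.columns) - set(kinds)
            if missing:
                raise SchemaError(f"kinds missing for variables: {sorted(missing)}")
        for col, kind in kinds.items():
            if kind not in ("continuous", "binary"):
                raise SchemaError(f"variable {col!r}: unknown kind {kind!r}")
            if kind == "binary":
                observed = set(values[col].dropna().unique())
                if not observed <= {0.0, 1.0}:
                    raise SchemaError(
                        f"binary variable {col!r} has values outside {{0,1}}: "
                        f"{sorted(observed - {0.0, 1.0})}"
                    )
        self.values = values
        self.kinds = kinds

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.values.index]

    @property
    def variables(self) -> list[str]:
        return list(self.values.columns)

    def __repr__(self) -> str:
        nbin = sum(1 for k in self.kinds.values() if k == "binary")
        return (
            f"PhenotypeTable({len(self.values)} samples, "
            f"{len(self.variables)} variables, {nbin} binary)"
        )


@dataclass(frozen=True)
class ModelSpec:
    """One outcome's regression definition within a model panel."""

    outcome: str
    family: Literal["linear", "logistic"]
    covariates: tuple[str, ...] = ()
    display_index: int = 0

    def __post_init__(self) -> None:
        if self.family not in ("linear", "logistic"):
            raise SchemaError(f"unknown model family {self.family!r}")
        object.__setattr__(self, "covariates", tuple(self.covariates))
        if self.outcome in self.covariates:
            raise SchemaError(
                f"outcome {self.outcome!r} may not appear among its covariates"
            )
        if self.display_index < 0:
            raise SchemaError("display_index must be >= 0")


def _validate_panel(panel: Sequence[ModelSpec]) -> list[ModelSpec]:
    panel = sorted(panel, key=lambda m: m.display_index)
    idx = [m.display_index for m in panel]
    if len(set(idx)) != len(idx):
        raise SchemaError(f"display_index values not unique: {idx}")
    names = [m.outcome for m in panel]
    if len(set(names)) != len(names):
        raise SchemaError(f"duplicate outcomes in panel: {names}")
    return panel


@dataclass(frozen=True)
class AssociationRecord:
    """Effect of one metabolite (per 1-SD log abundance) on one outcome.

    ``beta`` is the linear coefficient for continuous outcomes and the
    log-odds coefficient for binary ones. Non-converged fits are represented
    by NaN beta/se/p with ``converged=False``; otherwise p must lie in (0, 1]
    and se must be positive.
    """

    metabolite_id: str
    outcome: str
    beta: float
    se: float
    p: float
    converged: bool = True

    def __post_init__(self) -> None:
        if not self.converged:
            return
        if not math.isfinite(self.beta):
            raise SchemaError(
                f"({self.metabolite_id}, {self.outcome}): beta must be finite"
            )
        if not (self.se > 0 and math.isfinite(self.se)):
            raise SchemaError(
                f"({self.metabolite_id}, {self.outcome}): se must be > 0, "
                f"got {self.se!r}"
            )
        if not (0 < self.p <= 1):
            raise SchemaError(
                f"({self.metabolite_id}, {self.outcome}): p must be in (0, 1], "
                f"got {self.p!r}"
            )


class AssociationGrid:
    """A COMPLETE metabolites x outcomes grid of association records.

    Exactly one record must exist for every (metabolite, outcome) pair.
    Metabolite row order is the order of first appearance in ``records``;
    outcome column order is the panel display order.
    """

    def __init__(
        self,
        records: Sequence[AssociationRecord],
        annotations: Sequence[MetaboliteAnnotation],
        panel: Sequence[ModelSpec],
    ):
        self.panel = _validate_panel(panel)
        self.outcomes = [m.outcome for m in self.panel]

        ann_ids = [a.metabolite_id for a in annotations]
        if len(set(ann_ids)) != len(ann_ids):
            raise SchemaError("duplicate metabolite ids in annotations")
        self.annotations = list(annotations)
        self._mz = {a.metabolite_id: a.mz for a in self.annotations}

        # row order = first appearance in the record stream
        seen: dict[str, None] = {}
        for r in records:
            seen.setdefault(r.metabolite_id, None)
        self.metabolite_ids = list(seen)

        missing_ann = set(self.metabolite_ids) - set(ann_ids)
        if missing_ann:
            raise SchemaError(
                f"records reference unannotated metabolites: {sorted(missing_ann)}"
            )

        index: dict[tuple[str, str], AssociationRecord] = {}
        for r in records:
            key = (r.metabolite_id, r.outcome)
            if key in index:
                raise SchemaError(f"duplicate record for pair {key}")
            if r.outcome not in self._outcome_set():
                raise SchemaError(
                    f"record outcome {r.outcome!r} not in panel {self.outcomes}"
                )
            index[key] = r
        expected = len(self.metabolite_ids) * len(self.outcomes)
        if len(index) != expected:
            missing = [
                (m, o)
                for m in self.metabolite_ids
                for o in self.outcomes
                if (m, o) not in index
            ]
            raise SchemaError(
                f"incomplete grid: {len(index)} records for "
                f"{len(self.metabolite_ids)} x {len(self.outcomes)} pairs; "
                f"missing e.g. {missing[:5]}"
            )
        self._index = index

    def _outcome_set(self) -> set[str]:
        return set(self.outcomes)

    # -- accessors ---------------------------------------------------------
    @property
    def n_metabolites(self) -> int:
        return len(self.metabolite_ids)

    @property
    def n_outcomes(self) -> int:
        return len(self.outcomes)

    def record(self, metabolite_id: str, outcome: str) -> AssociationRecord:
        return self._index[(metabolite_id, outcome)]

    @property
    def records(self) -> list[AssociationRecord]:
        """Records in row-major (metabolite, outcome) display order."""
        return [
            self._index[(m, o)]
            for m in self.metabolite_ids
            for o in self.outcomes
        ]

    def mz(self, metabolite_id: str) -> float:
        return self._mz[metabolite_id]

    @property
    def mz_values(self) -> np.ndarray:
        return np.array([self._mz[m] for m in self.metabolite_ids])

    def annotations_in_row_order(self) -> list[MetaboliteAnnotation]:
        by_id = {a.metabolite_id: a for a in self.annotations}
        return [by_id[m] for m in self.metabolite_ids]

    def _matrix(self, attr: str) -> pd.DataFrame:
        data = np.array(
            [
                [getattr(self._index[(m, o)], attr) for o in self.outcomes]
                for m in self.metabolite_ids
            ],
            dtype=float,
        ).reshape(self.n_metabolites, self.n_outcomes)
        return pd.DataFrame(data, index=self.metabolite_ids, columns=self.outcomes)

    def beta_matrix(self) -> pd.DataFrame:
        return self._matrix("beta")

    def se_matrix(self) -> pd.DataFrame:
        return self._matrix("se")

    def p_matrix(self) -> pd.DataFrame:
        return self._matrix("p")

    def subset(self, metabolite_ids: Sequence[str]) -> "AssociationGrid":
        """Complete sub-grid over ``metabolite_ids``, in the given order."""
        keep = list(metabolite_ids)
        unknown = set(keep) - set(self.metabolite_ids)
        if unknown:
            raise SchemaError(f"unknown metabolites: {sorted(unknown)}")
        recs = [self._index[(m, o)] for m in keep for o in self.outcomes]
        anns = [a for a in self.annotations if a.metabolite_id in set(keep)]
        return AssociationGrid(recs, anns, self.panel)

    def reorder(self, permutation: Sequence[int]) -> "AssociationGrid":
        perm = list(permutation)
        if sorted(perm) != list(range(self.n_metabolites)):
            raise SchemaError("not a permutation of metabolite indices")
        return self.subset([self.metabolite_ids[i] for i in perm])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AssociationGrid):
            return NotImplemented
        if self.metabolite_ids != other.metabolite_ids:
            return False
        if self.outcomes != other.outcomes:
            return False
        if self._mz != other._mz:
            return False
        for key, rec in self._index.items():
            o = other._index[key]
            same = (
                (rec.beta == o.beta or (math.isnan(rec.beta) and math.isnan(o.beta)))
                and (rec.se == o.se or (math.isnan(rec.se) and math.isnan(o.se)))
                and (rec.p == o.p or (math.isnan(rec.p) and math.isnan(o.p)))
            )
            if not same:
                return False
        return True

    def __repr__(self) -> str:
        return (
            f"AssociationGrid({self.n_metabolites} metabolites x "
            f"{self.n_outcomes} outcomes)"
        )


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".tab") else ","


def _read_csv(path: Path) -> pd.DataFrame:
    return pd.read_csv(
        path,
        sep=_sep_for(path),
        na_values=NA_VALUES,
        keep_default_na=False,
        dtype={0: str},  # first column is always an id column
        encoding="utf-8",
        float_precision="round_trip",  # bit-exact read of %.17g output
    ).rename(columns=str)


def _require_columns(df: pd.DataFrame, cols: Sequence[str], path: Path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")


def _coerce_numeric(df: pd.DataFrame, path: Path) -> pd.DataFrame:
    """Coerce all columns to float, naming the first offending cell."""
    out = {}
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = df.index[bad][0]
            raise ParseError(
                f"{path}: non-numeric value {df.loc[row, col]!r} at "
                f"row {row!r}, column {col!r}"
            )
        out[col] = coerced
    return pd.DataFrame(out, index=df.index)


def read_table(
    path: str | Path,
    schema: Literal["abundance", "phenotype", "annotation", "association"],
):
    """Read a typed table from CSV/TSV (delimiter sniffed by extension).

    Schemas
    -------
    abundance
        First column = sample id, remaining columns = metabolite intensities.
        Returns :class:`AbundanceMatrix`.
    phenotype
        First column = sample id, remaining columns = traits/covariates.
        Returns :class:`PhenotypeTable` with binary/continuous kinds inferred.
    annotation
        Columns ``metabolite_id, mz``. Returns a list of
        :class:`MetaboliteAnnotation`.
    association
        Long format with columns ``metabolite_id, mz, outcome, beta, se, p``.
        Returns :class:`AssociationGrid` (outcome order = first appearance;
        model families are not carried by the file).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = _read_csv(path)
    if df.columns.size == 0:
        raise SchemaError(f"{path}: no header row")

    if schema == "abundance":
        df = df.set_index(df.columns[0])
        df.index.name = "sample_id"
        return AbundanceMatrix(_coerce_numeric(df, path))

    if schema == "phenotype":
        df = df.set_index(df.columns[0])
        df.index.name = "sample_id"
        return PhenotypeTable(_coerce_numeric(df, path))

    if schema == "annotation":
        _require_columns(df, ["metabolite_id", "mz"], path)
        ids = df["metabolite_id"].astype(str)
        if ids.duplicated().any():
            raise SchemaError(
                f"{path}: duplicate metabolite ids: "
                f"{ids[ids.duplicated()].unique().tolist()}"
            )
        mz = pd.to_numeric(df["mz"], errors="coerce")
        bad = mz.isna() & df["mz"].notna()
        if bad.any():
            row = df.index[bad][0]
            raise ParseError(
                f"{path}: non-numeric m/z {df.loc[row, 'mz']!r} at row {row!r}"
            )
        return [
            MetaboliteAnnotation(str(i), float(m)) for i, m in zip(ids, mz)
        ]

    if schema == "association":
        _require_columns(
            df, ["metabolite_id", "mz", "outcome", "beta", "se", "p"], path
        )
        num = _coerce_numeric(df[["mz", "beta", "se", "p"]], path)
        seen_out: dict[str, None] = {}
        for o in df["outcome"].astype(str):
            seen_out.setdefault(o, None)
        panel = [
            ModelSpec(outcome=o, family="linear", display_index=i)
            for i, o in enumerate(seen_out)
        ]
        ann: dict[str, MetaboliteAnnotation] = {}
        records = []
        for i in range(len(df)):
            mid = str(df["metabolite_id"].iloc[i])
            if mid not in ann:
                ann[mid] = MetaboliteAnnotation(mid, float(num["mz"].iloc[i]))
            beta = float(num["beta"].iloc[i])
            se = float(num["se"].iloc[i])
            p = float(num["p"].iloc[i])
            nan_triple = math.isnan(beta) and math.isnan(se) and math.isnan(p)
            records.append(
                AssociationRecord(
                    metabolite_id=mid,
                    outcome=str(df["outcome"].iloc[i]),
                    beta=beta,
                    se=se,
                    p=p,
                    converged=not nan_triple,
                )
            )
        return AssociationGrid(records, list(ann.values()), panel)

    raise ValueError(f"unknown schema {schema!r}")


def write_association_grid(grid: AssociationGrid, path: str | Path) -> None:
    """Write a grid as long-format CSV/TSV.

    Floats are printed at 17 significant digits so the file round-trips
    bit-identically through :func:`read_table`.
    """
    path = Path(path)
    rows = []
    for rec in grid.records:
        rows.append(
            {
                "metabolite_id": rec.metabolite_id,
                "mz": grid.mz(rec.metabolite_id),
                "outcome": rec.outcome,
                "beta": rec.beta,
                "se": rec.se,
                "p": rec.p,
            }
        )
    df = pd.DataFrame(rows)
    df.to_csv(
        path,
        sep=_sep_for(path),
        index=False,
        float_format="%.17g",
        na_rep="NA",
        encoding="utf-8",
    )
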