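"""Metabolite preprocessing: minimum-fraction imputation, natural-log
transform, and per-metabolite standardization, applied in that order.

Missing intensities are replaced, per metabolite, by 0.25 x the minimum
observed intensity of that metabolite; intensities are then natural-log
transformed and standardized (z-scored) so that effect sizes are per 1-SD
of log abundance and comparable across metabolites.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

from .core_io import AbundanceMatrix, SchemaError

__all__ = [
    "IMPUTATION_FACTOR",
    "PreprocessReport",
    "impute_missing",
    "log_transform",
    "standardize",
    "preprocess_pipeline",
]

IMPUTATION_FACTOR = 0.25  # fraction of the per-metabolite minimum observed value
DEFAULT_MISSING_THRESHOLD = 0.10


@dataclass
class PreprocessReport:
    """Bookkeeping from a preprocessing run.

    ``missing_fraction`` and ``imputation_constant`` are indexed by
    metabolite id; the constant is NaN for metabolites with no missing
    entries. ``n_above_threshold`` counts metabolites whose missing fraction
    exceeds ``missing_threshold`` (reported, not used for exclusion unless a
    ``max_missing_frac`` filter was requested).
    """

    missing_fraction: pd.Series
    imputation_constant: pd.Series
    missing_threshold: float
    n_above_threshold: int
    excluded_metabolites: list[str]

    def to_dict(self) -> dict:
        return {
            "missing_threshold": self.missing_threshold,
            "n_above_threshold": self.n_above_threshold,
            "excluded_metabolites": self.excluded_metabolites,
            "missing_fraction": self.missing_fraction.to_dict(),
            "imputation_constant": {
                k: (None if np.isnan(v) else v)
                for k, v in self.imputation_constant.items()
            },
        }


def impute_missing(column: np.ndarray) -> np.ndarray:
    """Replace missing (NaN) intensities by 0.25 x min(observed).

    Observed entries are returned unchanged. Raises if every entry is
    missing or if the minimum observed value is not strictly positive
    (the downstream log transform would fail).
    """
    col = np.asarray(column, dtype=float)
    observed = ~np.isnan(col)
    if not observed.any():
        raise SchemaError("cannot impute an all-missing column")
    mn = col[observed].min()
    if mn <= 0:
        raise SchemaError(
            f"minimum observed value must be > 0 for imputation, got {mn}"
        )
    out = col.copy()
    out[~observed] = IMPUTATION_FACTOR * mn
    return out


def log_transform(values: pd.DataFrame) -> pd.DataFrame:
    """Elementwise natural logarithm of a complete intensity matrix."""
    arr = values.to_numpy(dtype=float)
    bad = ~(arr > 0)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise SchemaError(
            f"log transform requires strictly positive values; "
            f"value {arr[i, j]!r} at sample {values.index[i]!r}, "
            f"metabolite {values.columns[j]!r}"
        )
    return pd.DataFrame(np.log(arr), index=values.index, columns=values.columns)


def standardize(
    values: pd.DataFrame,
    sd_denominator: Literal["n-1", "n"] = "n-1",
) -> pd.DataFrame:
    """Z-score each metabolite column to mean 0, SD 1.

    The default uses the sample (n-1 denominator) standard deviation; a
    population (n) denominator is available via ``sd_denominator="n"``.
    """
    if sd_denominator not in ("n-1", "n"):
        raise ValueError(f"sd_denominator must be 'n-1' or 'n', got {sd_denominator!r}")
    if len(values) < 2:
        raise SchemaError("standardization requires at least 2 samples")
    arr = values.to_numpy(dtype=float)
    ddof = 1 if sd_denominator == "n-1" else 0
    mean = arr.mean(axis=0)
    sd = arr.std(axis=0, ddof=ddof)
    zero = sd == 0
    if zero.any():
        raise SchemaError(
            f"zero-variance metabolites cannot be standardized: "
            f"{values.columns[zero].tolist()}"
        )
    return pd.DataFrame(
        (arr - mean) / sd, index=values.index, columns=values.columns
    )


def preprocess_pipeline(
    matrix: AbundanceMatrix,
    sd_denominator: Literal["n-1", "n"] = "n-1",
    max_missing_frac: float | None = None,
    missing_threshold: float = DEFAULT_MISSING_THRESHOLD,
) -> tuple[pd.DataFrame, PreprocessReport]:
    """Impute, log-transform, and standardize an abundance matrix.

    Parameters
    ----------
    matrix
        Raw intensities with NaN missingness.
    sd_denominator
        ``"n-1"`` (default) or ``"n"`` for the standardization denominator.
    max_missing_frac
        If given, metabolites whose missing fraction exceeds this value are
        dropped before imputation. Off by default: the standard workflow
        imputes rather than excludes.
    missing_threshold
        Threshold used purely for reporting how many metabolites exceed it.

    Returns
    -------
    (standardized, report)
        ``standardized`` is a samples x metabolites DataFrame of z-scored
        log intensities (every column mean 0, SD 1). It is a plain DataFrame
        rather than an :class:`AbundanceMatrix` because z-scores are signed,
        not raw intensities.
    """
    values = matrix.values
    missing_frac = values.isna().mean(axis=0)

    excluded: list[str] = []
    if max_missing_frac is not None:
        excluded = missing_frac.index[missing_frac > max_missing_frac].tolist()
        values = values.drop(columns=excluded)
        missing_frac = missing_frac.drop(index=excluded)
        if values.shape[1] == 0:
            raise SchemaError("all metabolites excluded by max_missing_frac")

    imputed = values.copy()
    constants = pd.Series(np.nan, index=values.columns, dtype=float)
    for col in values.columns:
        if values[col].isna().any():
            imputed[col] = impute_missing(values[col].to_numpy())
            constants[col] = IMPUTATION_FACTOR * values[col].min()

    logged = log_transform(imputed)
    standardized = standardize(logged, sd_denominator=sd_denominator)

    report = PreprocessReport(
        missing_fraction=missing_frac,
        imputation_constant=constants,
        missing_threshold=missing_threshold,
        n_above_threshold=int((missing_frac > missing_threshold).sum()),
        excluded_metabolites=excluded,
    )
    return standardized, report
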