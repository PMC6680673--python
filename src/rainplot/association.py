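"""Per-(metabolite, outcome) regression fits and grid assembly.

Each metabolite (standardized log abundance) is modeled as the exposure in
a multivariable regression against one clinical outcome at a time: ordinary
least squares with classical standard errors for continuous outcomes,
maximum-likelihood logistic regression via iteratively reweighted least
squares (IRLS) for binary outcomes. Both solvers are implemented here
directly so that the reported beta, SE, and P are fully specified by this
module, not by a downstream library version.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, stats
from scipy.special import expit

from .core_io import (
    AbundanceMatrix,
    AssociationGrid,
    AssociationRecord,
    MetaboliteAnnotation,
    ModelSpec,
    PhenotypeTable,
    RainplotError,
    SchemaError,
)

__all__ = [
    "FitError",
    "FitDiagnostics",
    "fit_linear",
    "fit_logistic",
    "build_grid",
    "default_panel",
    "DEFAULT_OUTCOMES",
]

logger = logging.getLogger(__name__)

LOGISTIC_TOL = 1e-8
LOGISTIC_MAX_ITER = 100


class FitError(RainplotError, ValueError):
    """A regression could not be fitted (rank deficiency, single class...)."""


@dataclass
class FitDiagnostics:
    n_used: int
    converged: bool = True
    iterations: int = 0


# Framingham-style clinical panel: eight traits/outcomes in the fixed
# clinical display order (demographics, metabolic traits, then incident
# disease). Age and sex are mutual covariates; everything else adjusts for
# both.
DEFAULT_OUTCOMES: list[tuple[str, str]] = [
    ("age", "linear"),
    ("female_sex", "logistic"),
    ("body_mass_index", "linear"),
    ("metabolic_syndrome", "logistic"),
    ("prevalent_diabetes", "logistic"),
    ("incident_diabetes", "logistic"),
    ("framingham_risk_score", "linear"),
    ("incident_hard_cvd", "logistic"),
]


def default_panel() -> list[ModelSpec]:
    """The packaged eight-model clinical panel in display order.

    The age model adjusts for sex, the sex model for age, and every other
    model for both age and sex.
    """
    panel = []
    for i, (outcome, family) in enumerate(DEFAULT_OUTCOMES):
        if outcome == "age":
            cov: tuple[str, ...] = ("female_sex",)
        elif outcome == "female_sex":
            cov = ("age",)
        else:
            cov = ("age", "female_sex")
        panel.append(
            ModelSpec(outcome=outcome, family=family, covariates=cov, display_index=i)
        )
    return panel


def _design(exposure: np.ndarray, covariates: np.ndarray | None) -> np.ndarray:
    n = exposure.shape[0]
    cols = [np.ones(n), np.asarray(exposure, dtype=float)]
    if covariates is not None and covariates.size:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        if cov.shape[0] != n:
            raise FitError(
                f"covariate rows ({cov.shape[0]}) != sample count ({n})"
            )
        cols.extend(cov.T)
    return np.column_stack(cols)


def _check_design(X: np.ndarray) -> None:
    n, k = X.shape
    if n <= k:
        raise FitError(f"too few samples: n={n} <= parameters k={k}")
    if np.linalg.matrix_rank(X) < k:
        raise FitError("design matrix is rank deficient")


def fit_linear(
    y: np.ndarray,
    exposure: np.ndarray,
    covariates: np.ndarray | None = None,
    *,
    metabolite_id: str = "exposure",
    outcome: str = "outcome",
) -> tuple[AssociationRecord, FitDiagnostics]:
    """OLS of a continuous outcome on intercept + exposure + covariates.

    Returns the exposure coefficient with its classical (homoskedastic)
    standard error and a two-sided P value from the t distribution on
    n - k degrees of freedom.
    """
    y = np.asarray(y, dtype=float)
    X = _design(np.asarray(exposure, dtype=float), covariates)
    if y.shape[0] != X.shape[0]:
        raise FitError("outcome and design lengths differ")
    _check_design(X)
    n, k = X.shape

    coef, _, _, _ = linalg.lstsq(X, y)
    resid = y - X @ coef
    df = n - k
    sigma2 = float(resid @ resid) / df
    xtx_inv = linalg.inv(X.T @ X)
    se = float(np.sqrt(max(sigma2 * xtx_inv[1, 1], 0.0)))
    beta = float(coef[1])
    if se == 0.0:
        # perfect (zero-residual) fit: P is 0 in the limit; report the
        # smallest representable positive values to keep invariants intact
        p = np.nextafter(0.0, 1.0)
        se = np.nextafter(0.0, 1.0)
    else:
        t = beta / se
        p = float(2.0 * stats.t.sf(abs(t), df))
        p = max(p, np.nextafter(0.0, 1.0))
    rec = AssociationRecord(metabolite_id, outcome, beta, se, p)
    return rec, FitDiagnostics(n_used=n)


def _logistic_irls(
    y: np.ndarray, X: np.ndarray
) -> tuple[np.ndarray, np.ndarray, bool, int]:
    """IRLS for the logistic MLE.

    Returns (coef, cov, converged, iterations); cov is the inverse observed
    information at the final coefficients.
    """
    n, k = X.shape
    coef = np.zeros(k)
    converged = False
    it = 0
    for it in range(1, LOGISTIC_MAX_ITER + 1):
        eta = X @ coef
        mu = expit(eta)
        w = np.clip(mu * (1.0 - mu), 1e-10, None)
        z = eta + (y - mu) / w
        Xw = X * w[:, None]
        try:
            new = linalg.solve(X.T @ Xw, X.T @ (w * z), assume_a="pos")
        except linalg.LinAlgError as exc:
            raise FitError(f"singular weighted design in IRLS: {exc}") from exc
        step = np.max(np.abs(new - coef))
        coef = new
        if step < LOGISTIC_TOL:
            converged = True
            break
    mu = expit(X @ coef)
    w = np.clip(mu * (1.0 - mu), 1e-10, None)
    info = X.T @ (X * w[:, None])
    try:
        cov = linalg.inv(info)
    except linalg.LinAlgError:
        cov = np.full((k, k), np.nan)
        converged = False
    return coef, cov, converged, it


def fit_logistic(
    y: np.ndarray,
    exposure: np.ndarray,
    covariates: np.ndarray | None = None,
    *,
    metabolite_id: str = "exposure",
    outcome: str = "outcome",
) -> tuple[AssociationRecord, FitDiagnostics]:
    """Logistic regression of a {0,1} outcome on intercept + exposure +
    covariates, fitted by IRLS.

    The standard error comes from the inverse observed information and the
    P value is a two-sided Wald test. Convergence requires the maximum
    absolute coefficient change to fall below 1e-8 within 100 iterations;
    a non-converged fit (e.g., under complete separation) is returned with
    ``converged=False`` and NaN beta/se/p so it can be excluded from plots.
    """
    y = np.asarray(y, dtype=float)
    classes = set(np.unique(y))
    if not classes <= {0.0, 1.0}:
        raise FitError(f"binary outcome must be coded {{0,1}}, got {sorted(classes)}")
    if len(classes) < 2:
        raise FitError("binary outcome has a single class; cannot fit")
    X = _design(np.asarray(exposure, dtype=float), covariates)
    if y.shape[0] != X.shape[0]:
        raise FitError("outcome and design lengths differ")
    _check_design(X)
    n = X.shape[0]

    coef, cov, converged, it = _logistic_irls(y, X)
    diag = FitDiagnostics(n_used=n, converged=converged, iterations=it)
    if not converged or not np.all(np.isfinite(cov)) or cov[1, 1] <= 0:
        logger.warning(
            "logistic fit (%s, %s) did not converge after %d iterations; "
            "possible separation — record flagged and excluded from plots",
            metabolite_id,
            outcome,
            it,
        )
        diag.converged = False
        rec = AssociationRecord(
            metabolite_id, outcome, np.nan, np.nan, np.nan, converged=False
        )
        return rec, diag

    beta = float(coef[1])
    se = float(np.sqrt(cov[1, 1]))
    zval = beta / se
    p = float(2.0 * stats.norm.sf(abs(zval)))
    p = max(p, np.nextafter(0.0, 1.0))
    rec = AssociationRecord(metabolite_id, outcome, beta, se, p)
    return rec, diag


def build_grid(
    matrix: pd.DataFrame | AbundanceMatrix,
    phenotypes: PhenotypeTable,
    panel: list[ModelSpec] | None = None,
    annotations: list[MetaboliteAnnotation] | None = None,
    *,
    skip_failures: bool = False,
) -> AssociationGrid:
    """Fit every (metabolite, outcome) pair and assemble the complete grid.

    ``matrix`` holds standardized log abundances (samples x metabolites).
    Samples are joined to the phenotype table by id (inner join); each model
    is then fitted on its own complete cases — samples missing that model's
    outcome or covariates are dropped for that model only.

    A fit error aborts with the offending pair named unless
    ``skip_failures`` is set, in which case the pair is recorded as a
    non-converged sentinel (NaN beta/se/p) and excluded from plots.
    """
    if isinstance(matrix, AbundanceMatrix):
        matrix = matrix.values
    if matrix.isna().any().any():
        raise SchemaError(
            "abundance matrix passed to build_grid still contains missing "
            "values; run preprocess_pipeline first"
        )
    if panel is None:
        panel = default_panel()
    if not panel:
        raise SchemaError("model panel is empty")

    common = matrix.index.intersection(phenotypes.values.index)
    if len(common) == 0:
        raise SchemaError("no samples shared between abundances and phenotypes")
    X = matrix.loc[common]
    pheno = phenotypes.values.loc[common]

    if annotations is None:
        # placeholder m/z (rank order) when the caller has no annotation table
        annotations = [
            MetaboliteAnnotation(str(m), float(i + 1))
            for i, m in enumerate(matrix.columns)
        ]
    ann_ids = {a.metabolite_id for a in annotations}
    missing_ann = [m for m in matrix.columns if str(m) not in ann_ids]
    if missing_ann:
        raise SchemaError(f"metabolites without annotation: {missing_ann[:5]}")

    records: list[AssociationRecord] = []
    for spec in sorted(panel, key=lambda m: m.display_index):
        needed = [spec.outcome, *spec.covariates]
        unknown = [v for v in needed if v not in pheno.columns]
        if unknown:
            raise SchemaError(
                f"model {spec.outcome!r}: variables not in phenotype table: {unknown}"
            )
        sub = pheno[needed].dropna()
        y = sub[spec.outcome].to_numpy()
        cov = sub[list(spec.covariates)].to_numpy() if spec.covariates else None
        idx = sub.index
        fit = fit_linear if spec.family == "linear" else fit_logistic
        for m in matrix.columns:
            x = X.loc[idx, m].to_numpy()
            try:
                rec, _ = fit(
                    y, x, cov, metabolite_id=str(m), outcome=spec.outcome
                )
            except FitError as exc:
                if not skip_failures:
                    raise FitError(
                        f"fit failed for pair ({m}, {spec.outcome}): {exc}"
                    ) from exc
                logger.warning(
                    "skipping failed fit (%s, %s): %s", m, spec.outcome, exc
                )
                rec = AssociationRecord(
                    str(m), spec.outcome, np.nan, np.nan, np.nan, converged=False
                )
            records.append(rec)

    # row order must follow matrix column order, not fit (outcome-major) order
    order = {str(m): i for i, m in enumerate(matrix.columns)}
    records.sort(key=lambda r: order[r.metabolite_id])
    used = [a for a in annotations if a.metabolite_id in order]
    return AssociationGrid(records, used, panel)
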