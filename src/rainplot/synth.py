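"""Synthetic LC-MS study generator with planted metabolite-outcome effects.

Emulates the shape of a population-cohort bioactive-lipid dataset: several
hundred metabolite features acquired over an m/z range of 225-650, a
Framingham-style phenotype panel (age 66 +/- 9 years, 54% women, eight
traits/outcomes), log-normal raw intensities, and per-metabolite
missing-at-random dropout. Effects are planted on the standardized log
scale so the downstream pipeline (impute -> log -> z-score -> regress)
should recover them directly.

Every draw descends from a single seed through named
``numpy.random.SeedSequence`` children (one stream per metabolite and per
phenotype component), so output is reproducible independently of generation
order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .core_io import (
    AbundanceMatrix,
    MetaboliteAnnotation,
    ModelSpec,
    PhenotypeTable,
    SchemaError,
)
from .association import default_panel

__all__ = ["SyntheticDesign", "generate_study", "fixture_cohort_shape"]

MZ_RANGE_DEFAULT = (225.0, 650.0)

# realistic per-outcome location/scale anchors for the default clinical panel
_CONTINUOUS_BASE = {
    "age": (66.0, 9.0),
    "body_mass_index": (27.5, 4.5),
    "framingham_risk_score": (12.0, 8.0),
}
_BINARY_PREVALENCE = {
    "female_sex": 0.54,
    "metabolic_syndrome": 0.30,
    "prevalent_diabetes": 0.10,
    "incident_diabetes": 0.07,
    "incident_hard_cvd": 0.09,
}


@dataclass
class SyntheticDesign:
    """Parameters of one synthetic study.

    ``missing_rate`` may be a scalar (applied to every metabolite) or a
    vector of per-metabolite rates in [0, 1). ``planted_effects`` are
    (metabolite_id, outcome, beta) triples: for continuous outcomes beta is
    in outcome units per 1-SD log abundance; for binary outcomes it is a
    log-odds ratio per 1-SD. ``missing_mode`` is ``"mcar"`` (completely at
    random) or ``"left"`` (lowest intensities censored, stressing the
    0.25 x min imputation rule).
    """

    n_samples: int = 300
    n_metabolites: int = 100
    mz_range: tuple[float, float] = MZ_RANGE_DEFAULT
    missing_rate: float | Sequence[float] = 0.0
    planted_effects: list[tuple[str, str, float]] = field(default_factory=list)
    noise_sd: float = 1.0
    seed: int = 0
    missing_mode: str = "mcar"
    panel: list[ModelSpec] = field(default_factory=default_panel)

    def __post_init__(self) -> None:
        rates = np.broadcast_to(
            np.asarray(self.missing_rate, dtype=float), (self.n_metabolites,)
        )
        if np.any((rates < 0) | (rates >= 1)):
            raise SchemaError("missing rates must lie in [0, 1)")
        if self.missing_mode not in ("mcar", "left"):
            raise SchemaError(f"unknown missing_mode {self.missing_mode!r}")
        if self.n_samples < 3 or self.n_metabolites < 1:
            raise SchemaError("need >= 3 samples and >= 1 metabolite")

    @property
    def missing_rates(self) -> np.ndarray:
        return np.broadcast_to(
            np.asarray(self.missing_rate, dtype=float), (self.n_metabolites,)
        ).copy()

    def metabolite_ids(self) -> list[str]:
        width = max(4, len(str(self.n_metabolites)))
        return [f"M{i + 1:0{width}d}" for i in range(self.n_metabolites)]


def _planted_matrix(design: SyntheticDesign) -> pd.DataFrame:
    """Outcomes x metabolites matrix of planted betas (zeros elsewhere)."""
    ids = design.metabolite_ids()
    outcomes = [m.outcome for m in design.panel]
    mat = pd.DataFrame(0.0, index=outcomes, columns=ids)
    for mid, out, beta in design.planted_effects:
        if mid not in mat.columns:
            raise SchemaError(f"planted effect references unknown metabolite {mid!r}")
        if out not in mat.index:
            raise SchemaError(f"planted effect references unknown outcome {out!r}")
        mat.loc[out, mid] = float(beta)
    return mat


def generate_study(
    design: SyntheticDesign,
) -> tuple[AbundanceMatrix, PhenotypeTable, list[MetaboliteAnnotation], pd.DataFrame]:
    """Generate (abundances, phenotypes, annotations, truth table).

    Raw intensities are exp of per-metabolite Gaussian log abundances;
    outcomes are built from the standardized (population-scale) log
    abundances via a linear predictor for continuous traits and a logistic
    link for binary ones. The truth table lists the planted (metabolite,
    outcome, beta) triples in long format.
    """
    n, m = design.n_samples, design.n_metabolites
    ids = design.metabolite_ids()
    sample_ids = [f"S{i + 1:05d}" for i in range(n)]

    root = np.random.SeedSequence(design.seed)
    ss_meta, ss_missing, ss_pheno, ss_mz = root.spawn(4)

    # per-metabolite streams: generation order independent
    meta_streams = ss_meta.spawn(m)
    miss_streams = ss_missing.spawn(m)

    Z = np.empty((n, m))
    log_abund = np.empty((n, m))
    rng_mz = np.random.default_rng(ss_mz)
    mu = rng_mz.uniform(10.0, 16.0, size=m)
    sigma = rng_mz.uniform(0.3, 0.8, size=m)
    mz = np.round(rng_mz.uniform(*design.mz_range, size=m), 4)
    for j in range(m):
        z = np.random.default_rng(meta_streams[j]).standard_normal(n)
        Z[:, j] = z
        log_abund[:, j] = mu[j] + sigma[j] * z
    raw = np.exp(log_abund)

    planted = _planted_matrix(design)
    rng_ph = np.random.default_rng(ss_pheno)
    pheno: dict[str, np.ndarray] = {}
    kinds: dict[str, str] = {}
    for spec in sorted(design.panel, key=lambda s: s.display_index):
        eta = Z @ planted.loc[spec.outcome].to_numpy()
        if spec.family == "linear":
            loc, scale = _CONTINUOUS_BASE.get(spec.outcome, (0.0, 1.0))
            noise = rng_ph.standard_normal(n) * scale * design.noise_sd
            pheno[spec.outcome] = loc + eta + noise
            kinds[spec.outcome] = "continuous"
        else:
            prev = _BINARY_PREVALENCE.get(spec.outcome, 0.3)
            prob = expit(logit(prev) + eta)
            pheno[spec.outcome] = (rng_ph.random(n) < prob).astype(float)
            kinds[spec.outcome] = "binary"

    # missingness
    rates = design.missing_rates
    values = pd.DataFrame(raw, index=sample_ids, columns=ids)
    for j in range(m):
        if rates[j] == 0:
            continue
        rng_m = np.random.default_rng(miss_streams[j])
        if design.missing_mode == "mcar":
            mask = rng_m.random(n) < rates[j]
        else:  # left-censoring: lowest intensities fall below detection
            cutoff = np.quantile(raw[:, j], rates[j])
            mask = raw[:, j] <= cutoff
        if mask.all():  # never blank an entire column
            mask[np.argmax(raw[:, j])] = False
        values.iloc[mask, j] = np.nan

    abundance = AbundanceMatrix(values)
    phenotypes = PhenotypeTable(
        pd.DataFrame(pheno, index=sample_ids), kinds=kinds
    )
    annotations = [MetaboliteAnnotation(ids[j], float(mz[j])) for j in range(m)]
    truth = pd.DataFrame(
        [
            {"metabolite_id": mid, "outcome": out, "beta": float(b)}
            for mid, out, b in design.planted_effects
        ],
        columns=["metabolite_id", "outcome", "beta"],
    )
    return abundance, phenotypes, annotations, truth


def fixture_cohort_shape(seed: int = 0) -> SyntheticDesign:
    """A desk-scale study mirroring the cohort dataset's structure.

    500 metabolite features x 300 samples (the cohort's ~1500 samples
    scaled down for test speed), the eight-outcome clinical panel, m/z drawn
    from the 225-650 acquisition range, and a missingness profile in which
    16% of metabolites exceed 10% missing values. A handful of planted
    effects make the top of every ordering non-trivial.
    """
    n_metabolites = 500
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0xF1D0)))
    rates = rng.uniform(0.0, 0.05, size=n_metabolites)
    n_high = int(round(0.16 * n_metabolites))
    high = rng.choice(n_metabolites, size=n_high, replace=False)
    rates[high] = rng.uniform(0.11, 0.30, size=n_high)

    planted = [
        ("M0001", "age", 2.5),
        ("M0001", "female_sex", -0.5),
        ("M0001", "framingham_risk_score", 2.2),
        ("M0001", "incident_hard_cvd", 0.45),
        ("M0002", "metabolic_syndrome", -0.5),
        ("M0002", "prevalent_diabetes", -0.45),
        ("M0003", "framingham_risk_score", 2.0),
        ("M0003", "incident_hard_cvd", 0.5),
        ("M0004", "prevalent_diabetes", 0.5),
        ("M0004", "incident_diabetes", 0.5),
        ("M0020", "female_sex", 1.2),
        ("M0027", "female_sex", -1.2),
        ("M0010", "body_mass_index", 1.5),
        ("M0011", "age", -2.0),
    ]
    return SyntheticDesign(
        n_samples=300,
        n_metabolites=n_metabolites,
        missing_rate=rates,
        planted_effects=planted,
        seed=seed,
    )
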