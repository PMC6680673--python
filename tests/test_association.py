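"""Regression fits against independent oracles, and grid assembly."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from scipy.special import expit

from rainplot import (
    FitError,
    ModelSpec,
    PhenotypeTable,
    build_grid,
    default_panel,
    fit_linear,
    fit_logistic,
)
from rainplot.association import DEFAULT_OUTCOMES


def ols_oracle(y, X):
    """Closed-form normal-equations OLS: beta, classical SE, t-based P."""
    XtX = X.T @ X
    coef = np.linalg.solve(XtX, X.T @ y)
    resid = y - X @ coef
    df = X.shape[0] - X.shape[1]
    sigma2 = resid @ resid / df
    se = np.sqrt(sigma2 * np.linalg.inv(XtX)[1, 1])
    t = coef[1] / se
    p = 2 * stats.t.sf(abs(t), df)
    return coef[1], se, p


def newton_logistic_oracle(y, X, tol=1e-12, max_iter=200):
    """Independent Newton-Raphson maximizer of the Bernoulli log-likelihood."""
    beta = np.zeros(X.shape[1])
    for _ in range(max_iter):
        mu = expit(X @ beta)
        grad = X.T @ (y - mu)
        H = X.T @ (X * (mu * (1 - mu))[:, None])
        step = np.linalg.solve(H, grad)
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    mu = expit(X @ beta)
    cov = np.linalg.inv(X.T @ (X * (mu * (1 - mu))[:, None]))
    return beta, np.sqrt(np.diag(cov))


class TestFitLinear:
    def test_exact_line(self):
        rec, diag = fit_linear(np.array([2.0, 4.0, 6.0, 8.0]), np.array([1.0, 2.0, 3.0, 4.0]))
        assert rec.beta == pytest.approx(2.0, abs=1e-12)
        assert diag.n_used == 4

    def test_matches_closed_form_oracle(self):
        rng = np.random.default_rng(1)
        y = rng.normal(size=60)
        x = rng.normal(size=60)
        cov = rng.normal(size=(60, 2))
        rec, _ = fit_linear(y, x, cov)
        X = np.column_stack([np.ones(60), x, cov])
        beta, se, p = ols_oracle(y, X)
        assert rec.beta == pytest.approx(beta, abs=1e-10)
        assert rec.se == pytest.approx(se, abs=1e-10)
        assert rec.p == pytest.approx(p, abs=1e-10)

    def test_matches_statsmodels(self):
        rng = np.random.default_rng(2)
        y = rng.normal(size=80)
        x = rng.normal(size=80)
        cov = rng.normal(size=(80, 3))
        rec, _ = fit_linear(y, x, cov)
        fit = sm.OLS(y, sm.add_constant(np.column_stack([x, cov]))).fit()
        assert rec.beta == pytest.approx(fit.params[1], abs=1e-10)
        assert rec.se == pytest.approx(fit.bse[1], abs=1e-10)
        assert rec.p == pytest.approx(fit.pvalues[1], abs=1e-10)

    def test_rank_deficiency_error(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=30)
        y = rng.normal(size=30)
        with pytest.raises(FitError, match="rank deficient"):
            fit_linear(y, x, x.copy())

    def test_too_few_samples_error(self):
        with pytest.raises(FitError, match="too few"):
            fit_linear(np.array([1.0, 2.0]), np.array([0.0, 1.0]))

    def test_null_betas_within_3se(self):
        """Under the null, |beta| < 3*SE in >= 99% of seeded replicates."""
        n, reps = 200, 1000
        inside = 0
        rng = np.random.default_rng(12345)
        for _ in range(reps):
            x = rng.standard_normal(n)
            y = rng.standard_normal(n)
            rec, _ = fit_linear(y, x)
            inside += abs(rec.beta) < 3 * rec.se
        assert inside / reps >= 0.99

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 2**31 - 1), n=st.integers(10, 120), k=st.integers(0, 3))
    def test_property_matches_oracle_random_designs(self, seed, n, k):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=n)
        cov = rng.normal(size=(n, k)) if k else None
        y = rng.normal(size=n)
        rec, _ = fit_linear(y, x, cov)
        X = np.column_stack([np.ones(n), x] + ([cov] if k else []))
        beta, se, p = ols_oracle(y, X)
        assert rec.beta == pytest.approx(beta, abs=1e-10)
        assert rec.se == pytest.approx(se, abs=1e-10)


class TestFitLogistic:
    def test_symmetric_design_gives_zero_beta(self):
        # dataset invariant under x -> -x with y unchanged (y even in x):
        # the likelihood satisfies L(a, b) = L(a, -b), so the unique MLE
        # has slope exactly 0
        x = np.array([-2.0, -1.0, 1.0, 2.0] * 5)
        y = np.array([1.0, 0.0, 0.0, 1.0] * 5)
        rec, diag = fit_logistic(y, x)
        assert diag.converged
        assert abs(rec.beta) < 1e-8

    def test_matches_newton_oracle(self):
        rng = np.random.default_rng(7)
        n = 20
        x = rng.normal(size=n)
        eta = 0.3 + 0.8 * x
        y = (rng.random(n) < expit(eta)).astype(float)
        if len(set(y)) < 2:  # pragma: no cover - seed chosen to avoid this
            pytest.skip("degenerate draw")
        rec, _ = fit_logistic(y, x)
        X = np.column_stack([np.ones(n), x])
        beta, se = newton_logistic_oracle(y, X)
        assert rec.beta == pytest.approx(beta[1], abs=1e-6)
        assert rec.se == pytest.approx(se[1], abs=1e-6)

    def test_matches_statsmodels(self):
        rng = np.random.default_rng(8)
        n = 300
        x = rng.normal(size=n)
        cov = rng.normal(size=(n, 2))
        eta = -0.5 + 0.6 * x + cov @ np.array([0.2, -0.3])
        y = (rng.random(n) < expit(eta)).astype(float)
        rec, _ = fit_logistic(y, x, cov)
        fit = sm.Logit(y, sm.add_constant(np.column_stack([x, cov]))).fit(disp=0)
        assert rec.beta == pytest.approx(fit.params[1], abs=1e-6)
        assert rec.se == pytest.approx(fit.bse[1], abs=1e-6)
        assert rec.p == pytest.approx(fit.pvalues[1], rel=1e-5)

    def test_score_gradient_vanishes_at_optimum(self):
        rng = np.random.default_rng(9)
        n = 150
        x = rng.normal(size=n)
        y = (rng.random(n) < expit(0.4 * x)).astype(float)
        rec, diag = fit_logistic(y, x)
        # recompute the score at the returned coefficient
        beta_full, _ = newton_logistic_oracle(y, np.column_stack([np.ones(n), x]))
        X = np.column_stack([np.ones(n), x])
        mu = expit(X @ beta_full)
        grad = X.T @ (y - mu)
        assert np.max(np.abs(grad)) < 1e-6
        assert rec.beta == pytest.approx(beta_full[1], abs=1e-6)

    def test_single_class_error(self):
        with pytest.raises(FitError, match="single class"):
            fit_logistic(np.ones(10), np.arange(10.0))

    def test_non_binary_coding_error(self):
        with pytest.raises(FitError, match="coded"):
            fit_logistic(np.array([0.0, 1.0, 2.0] * 4), np.arange(12.0))

    def test_perfect_separation_flagged(self):
        x = np.linspace(-2, 2, 20)
        y = (x > 0).astype(float)
        rec, diag = fit_logistic(y, x)
        assert not diag.converged
        assert not rec.converged
        assert np.isnan(rec.p)


class TestBuildGrid:
    def test_completeness(self, tiny_grid):
        assert tiny_grid.n_metabolites == 12
        assert tiny_grid.n_outcomes == 8
        assert len(tiny_grid.records) == 96

    def test_default_panel_order(self):
        panel = default_panel()
        assert [m.outcome for m in panel] == [
            "age",
            "female_sex",
            "body_mass_index",
            "metabolic_syndrome",
            "prevalent_diabetes",
            "incident_diabetes",
            "framingham_risk_score",
            "incident_hard_cvd",
        ]
        assert [m.display_index for m in panel] == list(range(8))
        fams = dict(DEFAULT_OUTCOMES)
        assert fams["age"] == "linear" and fams["incident_hard_cvd"] == "logistic"

    def test_sample_permutation_invariance(self, tiny_study):
        from rainplot import preprocess_pipeline

        abundance, phenotypes, annotations, _ = tiny_study
        std, _ = preprocess_pipeline(abundance)
        grid1 = build_grid(std, phenotypes, annotations=annotations)
        rng = np.random.default_rng(0)
        perm = rng.permutation(std.index.to_numpy())
        grid2 = build_grid(std.loc[perm], phenotypes, annotations=annotations)
        b1, b2 = grid1.beta_matrix(), grid2.beta_matrix()
        np.testing.assert_allclose(b1.to_numpy(), b2.to_numpy(), atol=1e-12)
        np.testing.assert_allclose(
            grid1.p_matrix().to_numpy(), grid2.p_matrix().to_numpy(), atol=1e-12
        )

    def test_complete_case_per_model(self):
        """Samples missing one model's outcome are dropped only for it."""
        rng = np.random.default_rng(11)
        n = 80
        std = pd.DataFrame(
            {"m1": rng.standard_normal(n)}, index=[f"s{i}" for i in range(n)]
        )
        age = rng.normal(60, 8, n)
        bmi = rng.normal(27, 4, n)
        bmi[:30] = np.nan
        pheno = PhenotypeTable(
            pd.DataFrame({"age": age, "bmi": bmi}, index=std.index)
        )
        panel = [
            ModelSpec("age", "linear", display_index=0),
            ModelSpec("bmi", "linear", display_index=1),
        ]
        grid = build_grid(std, pheno, panel)
        rec_age = grid.record("m1", "age")
        rec_bmi = grid.record("m1", "bmi")
        # bmi fit used 50 samples; refit manually to confirm
        keep = ~np.isnan(bmi)
        manual, _ = fit_linear(bmi[keep], std["m1"].to_numpy()[keep])
        assert rec_bmi.beta == pytest.approx(manual.beta, abs=1e-12)
        refit_age, _ = fit_linear(age, std["m1"].to_numpy())
        assert rec_age.beta == pytest.approx(refit_age.beta, abs=1e-12)

    def test_parameter_recovery_bias_shrinks_with_n(self):
        """Planted beta is recovered; bias decreases from n=200 to n=2000."""
        from rainplot import SyntheticDesign, generate_study, preprocess_pipeline

        def mean_abs_bias(n, reps=8):
            errs = []
            for s in range(reps):
                design = SyntheticDesign(
                    n_samples=n,
                    n_metabolites=4,
                    planted_effects=[("M0001", "body_mass_index", 2.0)],
                    seed=100 + s,
                )
                ab, ph, ann, _ = generate_study(design)
                std, _ = preprocess_pipeline(ab)
                grid = build_grid(std, ph, annotations=ann)
                errs.append(grid.record("M0001", "body_mass_index").beta - 2.0)
            return abs(np.mean(errs))

        assert mean_abs_bias(2000) < mean_abs_bias(200) + 0.1
        assert mean_abs_bias(2000) < 0.25

    def test_fit_failure_names_pair(self):
        rng = np.random.default_rng(13)
        n = 40
        std = pd.DataFrame(
            {"m1": np.linspace(-2, 2, n)}, index=[f"s{i}" for i in range(n)]
        )
        sep = (std["m1"] > 0).astype(float)  # separation-prone outcome
        pheno = PhenotypeTable(pd.DataFrame({"event": np.ones(n)}, index=std.index))
        panel = [ModelSpec("event", "logistic", display_index=0)]
        with pytest.raises(FitError, match=r"\(m1, event\)"):
            build_grid(std, pheno, panel)
        # with skip_failures the pair becomes a flagged sentinel
        grid = build_grid(std, pheno, panel, skip_failures=True)
        assert np.isnan(grid.record("m1", "event").p)
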