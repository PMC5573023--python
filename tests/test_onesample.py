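"""Observational OLS, sex interaction, 2SLS and the endogeneity test."""

import logging

import numpy as np
import pandas as pd
import pytest

from mrkit import (
    SimulationConfig,
    TwoStageLeastSquares,
    ValidationError,
    observational_models,
    sex_interaction,
    simulate_cohort,
    tsls,
    weighted_allelic_score,
    wu_hausman,
)
from conftest import ols_oracle


def _covariates(n, rng):
    return pd.DataFrame(
        {
            "age": rng.normal(13.8, 0.3, n),
            "confounder": rng.normal(size=n),
            "energy_intake": rng.normal(size=n),
        }
    )


class TestObservationalModels:
    def test_noise_free_slope_recovered_in_every_model(self):
        rng = np.random.default_rng(0)
        n = 200
        cov = _covariates(n, rng)
        x = rng.normal(size=n)
        y = 0.2 * x
        for spec in ("age_only", "age_plus_confounders", "fully_adjusted"):
            est = observational_models(x, y, cov, model_spec=spec)
            assert est.beta == pytest.approx(0.2, abs=1e-10)
            assert est.se < 1e-8

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(1)
        n = 30
        cov = _covariates(n, rng)
        x = rng.normal(size=n)
        y = 0.3 * x + 0.1 * cov["age"].to_numpy() + rng.normal(size=n)
        est = observational_models(x, y, cov, model_spec="age_only")
        design = np.column_stack([np.ones(n), x, cov["age"]])
        beta_o, se_o = ols_oracle(design, y)
        assert est.beta == pytest.approx(beta_o[1], rel=1e-10)
        assert est.se == pytest.approx(se_o[1], rel=1e-10)

    def test_orthogonal_covariate_leaves_slope_unchanged(self):
        rng = np.random.default_rng(2)
        n = 500
        x = rng.normal(size=n)
        y = 0.3 * x + rng.normal(size=n)
        # construct a covariate exactly orthogonal to [1, x, y]
        raw = rng.normal(size=n)
        basis = np.column_stack([np.ones(n), x, y])
        coef, *_ = np.linalg.lstsq(basis, raw, rcond=None)
        orth = raw - basis @ coef
        cov = pd.DataFrame({"age": orth})
        base = observational_models(x, y, cov, model_spec="unadjusted")
        adj = observational_models(x, y, cov, model_spec="age_only")
        assert adj.beta == pytest.approx(base.beta, abs=1e-8)

    def test_absent_covariate_named_in_error(self):
        with pytest.raises(ValidationError, match="energy_intake"):
            observational_models(
                np.arange(10.0), np.arange(10.0),
                pd.DataFrame({"age": np.ones(10), "confounder": np.zeros(10)}),
                model_spec="fully_adjusted",
            )

    def test_stratified_fit_uses_only_the_stratum(self):
        rng = np.random.default_rng(3)
        n = 2000
        sex = rng.integers(0, 2, n)
        x = rng.normal(size=n)
        y = np.where(sex == 0, 0.5 * x, -0.5 * x) + 0.05 * rng.normal(size=n)
        cov = _covariates(n, rng)
        male = observational_models(x, y, cov, "age_only", stratum="male", sex=sex)
        female = observational_models(x, y, cov, "age_only", stratum="female", sex=sex)
        assert male.beta == pytest.approx(0.5, abs=0.02)
        assert female.beta == pytest.approx(-0.5, abs=0.02)


class TestSexInteraction:
    def test_simulated_sex_difference_recovered(self):
        """Male slope 0.19, female slope 0.13 -> interaction ~ -0.06."""
        rng = np.random.default_rng(4)
        n = 50_000
        sex = rng.integers(0, 2, n)
        x = rng.normal(size=n)
        y = np.where(sex == 0, 0.19, 0.13) * x + rng.normal(size=n) * 0.3
        est = sex_interaction(x, y, pd.DataFrame(), sex)
        assert est.beta == pytest.approx(-0.06, abs=0.01)

    def test_null_when_slopes_equal(self):
        rng = np.random.default_rng(5)
        n = 5000
        sex = rng.integers(0, 2, n)
        x = rng.normal(size=n)
        y = 0.2 * x + rng.normal(size=n)
        est = sex_interaction(x, y, pd.DataFrame(), sex)
        assert abs(est.beta) < 4 * est.se

    def test_matches_explicit_product_column_oracle(self):
        rng = np.random.default_rng(6)
        n = 40
        sex = np.array([0, 1] * 20)
        x = rng.normal(size=n)
        y = 0.2 * x + 0.1 * sex * x + rng.normal(size=n)
        est = sex_interaction(x, y, pd.DataFrame(), sex)
        design = np.column_stack([np.ones(n), x, sex, x * sex])
        beta_o, se_o = ols_oracle(design, y)
        assert est.beta == pytest.approx(beta_o[3], rel=1e-10)
        assert est.se == pytest.approx(se_o[3], rel=1e-10)

    def test_single_sex_rejected(self):
        with pytest.raises(ValidationError, match="both sexes"):
            sex_interaction(np.arange(10.0), np.arange(10.0), pd.DataFrame(), np.zeros(10))


class TestTSLS:
    def test_binary_instrument_wald_identity_by_hand(self):
        # group means: Z=0 -> (1, 2); Z=1 -> (3, 6); beta = (6-2)/(3-1) = 2
        z = np.array([0.0, 0.0, 1.0, 1.0])
        x = np.array([0.5, 1.5, 2.5, 3.5])
        y = np.array([1.0, 3.0, 5.0, 7.0])
        fit = TwoStageLeastSquares().fit(x, y, z)
        assert fit.beta_ == pytest.approx(2.0, abs=1e-12)

    def test_outcome_identical_to_exposure(self):
        rng = np.random.default_rng(7)
        z = rng.normal(size=100)
        x = 0.5 * z + rng.normal(size=100)
        fit = TwoStageLeastSquares().fit(x, x, z)
        assert fit.beta_ == pytest.approx(1.0, abs=1e-10)

    def test_perfect_instrument_equals_ols(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=200)
        y = 0.4 * x + rng.normal(size=200)
        fit = TwoStageLeastSquares().fit(x, y, x)
        design = np.column_stack([np.ones(200), x])
        beta_o, _ = ols_oracle(design, y)
        assert fit.beta_ == pytest.approx(beta_o[1], abs=1e-10)

    def test_wald_ratio_identity_on_random_fixture(self):
        """Single instrument: 2SLS equals reduced-form / first-stage slopes."""
        rng = np.random.default_rng(9)
        z = rng.normal(size=300)
        x = 0.7 * z + rng.normal(size=300)
        y = 0.3 * x + rng.normal(size=300)
        fit = TwoStageLeastSquares().fit(x, y, z)
        num = np.cov(z, y, ddof=1)[0, 1] / np.var(z, ddof=1)
        den = np.cov(z, x, ddof=1)[0, 1] / np.var(z, ddof=1)
        assert fit.beta_ == pytest.approx(num / den, rel=1e-10)

    def test_confounded_tsls_unbiased_ols_biased(self, causal_cohort):
        cfg, panel, cohort = causal_cohort
        score = weighted_allelic_score(cohort.dosages, panel)
        est, diag = tsls(cohort.exposure, cohort.outcome, score)
        assert diag.f_stat > 30
        assert est.ci_low < cfg.theta < est.ci_high
        obs = observational_models(
            cohort.exposure, cohort.outcome, cohort.phenotypes, "unadjusted"
        )
        # confounder loadings 0.5/0.5 push OLS well above theta
        assert obs.beta > cfg.theta + 4 * obs.se

    def test_constant_instrument_rejected(self):
        with pytest.raises(ValidationError, match="constant"):
            TwoStageLeastSquares().fit(np.arange(10.0), np.arange(10.0), np.ones(10))

    def test_weak_instrument_warns_but_returns(self, caplog):
        rng = np.random.default_rng(10)
        z = rng.normal(size=100)
        x = 0.05 * z + rng.normal(size=100)
        y = rng.normal(size=100)
        with caplog.at_level(logging.WARNING, logger="mrkit.onesample"):
            fit = TwoStageLeastSquares().fit(x, y, z)
        assert fit.diagnostics_.weak_instrument
        assert any("weak instrument" in r.message for r in caplog.records)

    def test_robust_se_option_differs_but_estimate_identical(self, causal_cohort):
        _, panel, cohort = causal_cohort
        score = weighted_allelic_score(cohort.dosages, panel)
        a = TwoStageLeastSquares(robust=False).fit(cohort.exposure, cohort.outcome, score)
        b = TwoStageLeastSquares(robust=True).fit(cohort.exposure, cohort.outcome, score)
        assert a.beta_ == pytest.approx(b.beta_, rel=1e-12)
        assert a.se_ != b.se_


class TestWuHausman:
    def test_power_under_strong_confounding(self):
        rejections = 0
        for i in range(20):
            cfg = SimulationConfig(
                n=5000, k=48, theta=0.3, target_r2=0.03,
                confounder_effect_x=0.8, confounder_effect_y=0.8, seed=100 + i,
            )
            panel, cohort = simulate_cohort(cfg)
            score = weighted_allelic_score(cohort.dosages, panel)
            p = wu_hausman(cohort.exposure, cohort.outcome, score)
            rejections += p < 0.05
        assert rejections >= 17  # > 80% power

    def test_degenerate_zero_residual_variance_rejected(self):
        z = np.arange(50.0)
        x = 2.0 * z
        y = 3.0 * x
        with pytest.raises(ValidationError, match="degenerate"):
            wu_hausman(x, y, z)
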