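"""Harmonization and the summary-level estimators (IVW, Egger, median, LOO)."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, settings, strategies as st

from mrkit import (
    ValidationError,
    egger,
    harmonize,
    ivw,
    leave_one_out,
    wald_ratios,
    weighted_median,
)
from mrkit.summary import IVWEstimator


def _stats(snp, ea, oa, beta, se=0.01, eaf=0.3):
    return pd.DataFrame(
        {"snp": [snp], "effect_allele": [ea], "other_allele": [oa],
         "eaf": [eaf], "beta": [beta], "se": [se]}
    )


class TestHarmonize:
    def test_allele_flip_changes_sign(self):
        exp = _stats("rs1", "A", "G", 0.1)
        out = _stats("rs1", "G", "A", 0.05)
        h, log = harmonize(exp, out)
        assert h["beta_out"].iloc[0] == pytest.approx(-0.05)
        assert log["action"].iloc[0] == "flipped"

    def test_strand_complement_preserves_sign(self):
        exp = _stats("rs1", "A", "G", 0.1, eaf=0.2)
        out = _stats("rs1", "T", "C", 0.05, eaf=0.2)
        h, log = harmonize(exp, out)
        assert h["beta_out"].iloc[0] == pytest.approx(0.05)
        assert "strand_complement" in log["action"].iloc[0]

    def test_palindrome_at_half_frequency_dropped(self):
        exp = _stats("rs1", "A", "T", 0.1, eaf=0.50)
        out = _stats("rs1", "A", "T", 0.05, eaf=0.50)
        h, log = harmonize(exp, out)
        assert len(h) == 0
        assert log["action"].iloc[0] == "dropped:palindromic_ambiguous"

    def test_unambiguous_palindrome_aligned_by_frequency(self):
        exp = _stats("rs1", "A", "T", 0.1, eaf=0.1)
        out = _stats("rs1", "A", "T", 0.05, eaf=0.85)  # opposite minor side
        h, _ = harmonize(exp, out)
        assert h["beta_out"].iloc[0] == pytest.approx(-0.05)
        assert h["eaf_out"].iloc[0] == pytest.approx(0.15)

    def test_strict_policy_drops_all_palindromes(self):
        exp = _stats("rs1", "C", "G", 0.1, eaf=0.1)
        out = _stats("rs1", "C", "G", 0.05, eaf=0.1)
        h, log = harmonize(exp, out, palindrome_policy="strict")
        assert len(h) == 0
        assert log["action"].iloc[0] == "dropped:palindromic_strict"

    def test_irreconcilable_alleles_dropped_with_reason(self):
        exp = _stats("rs1", "A", "G", 0.1)
        out = _stats("rs1", "A", "C", 0.05)
        h, log = harmonize(exp, out)
        assert len(h) == 0
        assert log["action"].iloc[0] == "dropped:irreconcilable_alleles"

    def test_idempotent_on_already_harmonized_data(self):
        exp = pd.concat(
            [_stats("rs1", "A", "G", 0.1), _stats("rs2", "C", "T", -0.2, eaf=0.4)],
            ignore_index=True,
        )
        out = pd.concat(
            [_stats("rs1", "G", "A", 0.05), _stats("rs2", "G", "A", 0.03, eaf=0.7)],
            ignore_index=True,
        )
        h1, _ = harmonize(exp, out)
        out1 = h1.rename(columns={"eaf_out": "eaf", "beta_out": "beta", "se_out": "se"})[
            ["snp", "effect_allele", "other_allele", "eaf", "beta", "se"]
        ]
        h2, log2 = harmonize(exp, out1)
        pd.testing.assert_frame_equal(h1, h2)
        assert (log2["action"] == "kept").all()


class TestWaldRatios:
    def test_hand_arithmetic(self):
        st_ = pd.DataFrame({"snp": ["a"], "beta_exp": [0.1], "se_exp": [0.01],
                            "beta_out": [0.03], "se_out": [0.01]})
        r = wald_ratios(st_)
        assert r["ratio"].iloc[0] == pytest.approx(0.3)
        assert r["se"].iloc[0] == pytest.approx(0.1)

    def test_zero_outcome_effect(self):
        st_ = pd.DataFrame({"snp": ["a"], "beta_exp": [0.1], "se_exp": [0.01],
                            "beta_out": [0.0], "se_out": [0.01]})
        assert wald_ratios(st_)["ratio"].iloc[0] == 0.0

    def test_joint_sign_flip_invariance(self):
        st_ = pd.DataFrame({"snp": ["a"], "beta_exp": [0.1], "se_exp": [0.01],
                            "beta_out": [0.03], "se_out": [0.01]})
        flipped = st_.assign(beta_exp=-st_["beta_exp"], beta_out=-st_["beta_out"])
        assert wald_ratios(st_)["ratio"].iloc[0] == wald_ratios(flipped)["ratio"].iloc[0]

    def test_tiny_exposure_effect_excluded(self):
        st_ = pd.DataFrame({"snp": ["a", "b"], "beta_exp": [0.1, 0.0],
                            "se_exp": [0.01, 0.01], "beta_out": [0.03, 0.01],
                            "se_out": [0.01, 0.01]})
        with pytest.warns(UserWarning, match="excluding"):
            r = wald_ratios(st_)
        assert len(r) == 1


class TestIVW:
    def test_two_snp_hand_fixture(self):
        st_ = pd.DataFrame({"snp": ["a", "b"], "beta_exp": [0.1, 0.2],
                            "se_exp": [0.01, 0.01], "beta_out": [0.03, 0.06],
                            "se_out": [0.01, 0.01]})
        r = ivw(st_)
        assert r.beta == pytest.approx(0.3, abs=1e-12)
        assert r.q_stat == pytest.approx(0.0, abs=1e-12)
        assert r.q_p == pytest.approx(1.0)

    def test_single_snp_equals_wald_ratio(self):
        st_ = pd.DataFrame({"snp": ["a"], "beta_exp": [0.17], "se_exp": [0.01],
                            "beta_out": [0.04], "se_out": [0.02]})
        assert ivw(st_).beta == pytest.approx(0.04 / 0.17, rel=1e-12)

    def test_matches_weighted_least_squares_oracle(self, harmonized_fixture):
        r = ivw(harmonized_fixture)
        fit = sm.WLS(
            harmonized_fixture["beta_out"],
            harmonized_fixture[["beta_exp"]],
            weights=1.0 / harmonized_fixture["se_out"] ** 2,
        ).fit()
        assert r.beta == pytest.approx(fit.params.iloc[0], rel=1e-10)

    def test_row_order_invariance(self, harmonized_fixture):
        shuffled = harmonized_fixture.sample(frac=1.0, random_state=3).reset_index(drop=True)
        assert ivw(shuffled).beta == pytest.approx(ivw(harmonized_fixture).beta, rel=1e-12)

    def test_random_effects_inflates_se_under_heterogeneity(self):
        rng = np.random.default_rng(1)
        k = 30
        st_ = pd.DataFrame({
            "snp": [f"rs{i}" for i in range(k)],
            "beta_exp": rng.uniform(0.05, 0.2, k), "se_exp": np.full(k, 1e-6),
            "beta_out": rng.normal(0.0, 0.1, k), "se_out": np.full(k, 0.01),
        })
        fixed, random = ivw(st_), ivw(st_, random_effects=True)
        assert random.se > fixed.se
        assert random.beta == pytest.approx(fixed.beta, rel=1e-12)


class TestEgger:
    def test_collinear_hand_fixture(self):
        st_ = pd.DataFrame({"snp": list("abc"), "beta_exp": [0.1, 0.2, 0.3],
                            "se_exp": [0.01] * 3, "beta_out": [0.05, 0.07, 0.09],
                            "se_out": [0.01] * 3})
        r = egger(st_)
        assert r.beta == pytest.approx(0.2, abs=1e-10)
        assert r.intercept == pytest.approx(0.03, abs=1e-10)
        assert r.q_stat == pytest.approx(0.0, abs=1e-10)
        assert r.q_df == 1

    def test_minimum_snp_count_enforced(self):
        st_ = pd.DataFrame({"snp": ["a", "b"], "beta_exp": [0.1, 0.2],
                            "se_exp": [0.01] * 2, "beta_out": [0.03, 0.06],
                            "se_out": [0.01] * 2})
        with pytest.raises(ValidationError, match="at least 3"):
            egger(st_)

    def test_matches_statsmodels_wls_with_intercept(self, harmonized_fixture):
        r = egger(harmonized_fixture)
        fit = sm.WLS(
            harmonized_fixture["beta_out"],
            sm.add_constant(harmonized_fixture["beta_exp"]),
            weights=1.0 / harmonized_fixture["se_out"] ** 2,
        ).fit()
        assert r.beta == pytest.approx(fit.params.iloc[1], rel=1e-10)
        assert r.intercept == pytest.approx(fit.params.iloc[0], rel=1e-8)

    def test_orientation_invariance_to_joint_flips(self, harmonized_fixture):
        flipped = harmonized_fixture.copy()
        flipped.loc[0, ["beta_exp", "beta_out"]] *= -1
        a, b = egger(harmonized_fixture), egger(flipped)
        assert a.beta == pytest.approx(b.beta, rel=1e-12)
        assert a.intercept == pytest.approx(b.intercept, rel=1e-12)


class TestWeightedMedian:
    def test_three_equal_weight_ratios(self):
        st_ = pd.DataFrame({"snp": list("abc"), "beta_exp": [1.0, 1.0, 1.0],
                            "se_exp": [0.01] * 3, "beta_out": [0.1, 0.3, 0.5],
                            "se_out": [0.1] * 3})
        r = weighted_median(st_, n_boot=200, seed=1)
        assert r.beta == pytest.approx(0.3, abs=1e-12)

    def test_identical_ratios_and_shrinking_se(self):
        def make(se):
            return pd.DataFrame({"snp": list("abcd"), "beta_exp": [0.1, 0.2, 0.3, 0.4],
                                 "se_exp": [se] * 4,
                                 "beta_out": [0.03, 0.06, 0.09, 0.12],
                                 "se_out": [se] * 4})
        r_big = weighted_median(make(0.01), n_boot=300, seed=2)
        r_small = weighted_median(make(0.0001), n_boot=300, seed=2)
        assert r_big.beta == pytest.approx(0.3, abs=1e-10)
        assert r_small.se < r_big.se

    def test_bootstrap_seed_reproducibility(self, harmonized_fixture):
        a = weighted_median(harmonized_fixture, n_boot=200, seed=7)
        b = weighted_median(harmonized_fixture, n_boot=200, seed=7)
        assert a.se == b.se

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(st.integers(0, 2**31 - 1))
    def test_row_order_invariance(self, seed):
        rng = np.random.default_rng(seed)
        k = int(rng.integers(3, 12))
        st_ = pd.DataFrame({
            "snp": [f"rs{i}" for i in range(k)],
            "beta_exp": rng.uniform(0.05, 0.3, k), "se_exp": rng.uniform(0.005, 0.02, k),
            "beta_out": rng.normal(0.03, 0.02, k), "se_out": rng.uniform(0.005, 0.02, k),
        })
        shuffled = st_.sample(frac=1.0, random_state=1).reset_index(drop=True)
        a = weighted_median(st_, n_boot=100, seed=3)
        b = weighted_median(shuffled, n_boot=100, seed=3)
        assert a.beta == pytest.approx(b.beta, rel=1e-10)


class TestLeaveOneOut:
    def test_homogeneous_fixture_all_deltas_negligible(self):
        st_ = pd.DataFrame({"snp": list("abcd"), "beta_exp": [0.1, 0.2, 0.3, 0.4],
                            "se_exp": [0.01] * 4,
                            "beta_out": [0.03, 0.06, 0.09, 0.12],
                            "se_out": [0.01] * 4})
        loo = leave_one_out(st_, method="ivw")
        assert (loo["delta"].abs() <= 1e-10).all()

    def test_planted_outlier_ranks_first(self):
        st_ = pd.DataFrame({"snp": [f"rs{i}" for i in range(8)],
                            "beta_exp": [0.1] * 8, "se_exp": [0.01] * 8,
                            "beta_out": [0.03] * 7 + [0.3], "se_out": [0.01] * 8})
        loo = leave_one_out(st_, method="ivw").set_index("snp")
        assert loo.loc["rs7", "rank_delta"] == 1
        assert loo.loc["rs7", "rank_q"] == 1

    def test_q_decomposition_sums_to_total(self):
        rng = np.random.default_rng(2)
        k = 15
        st_ = pd.DataFrame({
            "snp": [f"rs{i}" for i in range(k)],
            "beta_exp": rng.uniform(0.05, 0.3, k), "se_exp": np.full(k, 0.01),
            "beta_out": rng.normal(0.05, 0.03, k), "se_out": rng.uniform(0.005, 0.02, k),
        })
        loo = leave_one_out(st_, method="ivw")
        total_q = IVWEstimator().fit(st_).q_
        assert loo["q_contribution"].sum() == pytest.approx(total_q, abs=1e-8)

    def test_egger_variant_runs_and_respects_minimum(self):
        st_ = pd.DataFrame({"snp": list("abc"), "beta_exp": [0.1, 0.2, 0.3],
                            "se_exp": [0.01] * 3, "beta_out": [0.05, 0.07, 0.09],
                            "se_out": [0.01] * 3})
        with pytest.raises(ValidationError):
            leave_one_out(st_, method="egger")
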