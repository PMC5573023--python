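"""Replicate simulation studies characterising the estimators.

Each study simulates cohorts (or summary statistics) from the package's
generative model under stated conditions, runs the corresponding
estimator, and returns summary operating characteristics: CI coverage,
test calibration, pleiotropy robustness, and split-sample validity.
Problem sizes are chosen so every study runs in minutes on one CPU while
keeping Monte-Carlo error well inside the margins being checked; the
methods note records the sizes and why.

All randomness flows from a single integer seed via
``numpy.random.SeedSequence``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .simulate import SimulationConfig, simulate_cohort, make_summary_stats
from .scores import weighted_allelic_score, score_trait_association
from .onesample import TwoStageLeastSquares, observational_models, wu_hausman
from .summary import IVWEstimator, MREggerEstimator, weighted_median, harmonize
from .splitsample import cross_fit


def _child_seeds(seed: int, n: int) -> np.ndarray:
    """Derive n reproducible sub-seeds (< 2^31) from one master seed."""
    return np.random.SeedSequence(seed).generate_state(n, dtype=np.uint32) % (2**31)


# ---------------------------------------------------------------------------
# instrument strength


def score_strength_study(seed: int = 0, n: int = 10_000, k: int = 96,
                         target_r2: float = 0.03) -> dict:
    """Realized score-exposure R^2 and first-stage F at the study design point."""
    cfg = SimulationConfig(n=n, k=k, target_r2=target_r2, theta=0.3, seed=int(seed))
    panel, cohort = simulate_cohort(cfg)
    score = weighted_allelic_score(cohort.dosages, panel)
    assoc = score_trait_association(score, cohort.exposure)
    fit = TwoStageLeastSquares().fit(cohort.exposure, cohort.outcome, score)
    return {
        "r2": assoc.r2,
        "beta_per_allele": assoc.beta,
        "first_stage_f": fit.diagnostics_.f_stat,
        "n": n,
    }


# ---------------------------------------------------------------------------
# one-sample 2SLS: coverage and calibration


def coverage_study(
    seed: int = 0,
    n_reps: int = 200,
    n: int = 5000,
    k: int = 96,
    theta: float = 0.3,
    confounding: float = 0.5,
    target_r2: float = 0.03,
) -> dict:
    """2SLS vs OLS 95%-CI coverage of theta under shared confounding."""
    seeds = _child_seeds(seed, n_reps)
    tsls_cover = ols_cover = 0
    tsls_betas, ols_betas, fstats = [], [], []
    for s in seeds:
        cfg = SimulationConfig(
            n=n, k=k, theta=theta, target_r2=target_r2,
            confounder_effect_x=confounding, confounder_effect_y=confounding,
            seed=int(s),
        )
        panel, cohort = simulate_cohort(cfg)
        score = weighted_allelic_score(cohort.dosages, panel)
        fit = TwoStageLeastSquares().fit(cohort.exposure, cohort.outcome, score)
        tsls_cover += fit.ci_[0] <= theta <= fit.ci_[1]
        tsls_betas.append(fit.beta_)
        fstats.append(fit.diagnostics_.f_stat)
        obs = observational_models(
            cohort.exposure, cohort.outcome, cohort.phenotypes, model_spec="unadjusted"
        )
        ols_cover += obs.ci_low <= theta <= obs.ci_high
        ols_betas.append(obs.beta)
    return {
        "tsls_coverage": tsls_cover / n_reps,
        "ols_coverage": ols_cover / n_reps,
        "mean_tsls_beta": float(np.mean(tsls_betas)),
        "mean_ols_beta": float(np.mean(ols_betas)),
        "mean_first_stage_f": float(np.mean(fstats)),
        "n_reps": n_reps,
        "n": n,
        "theta": theta,
    }


def wu_hausman_calibration(
    seed: int = 0,
    n_reps: int = 500,
    n: int = 1000,
    k: int = 96,
    theta: float = 0.3,
    confounding: float = 0.0,
    alpha: float = 0.05,
) -> dict:
    """Rejection rate of the endogeneity test; exogenous unless confounded."""
    seeds = _child_seeds(seed, n_reps)
    pvals = np.empty(n_reps)
    for i, s in enumerate(seeds):
        cfg = SimulationConfig(
            n=n, k=k, theta=theta, target_r2=0.03,
            confounder_effect_x=confounding, confounder_effect_y=confounding,
            seed=int(s),
        )
        panel, cohort = simulate_cohort(cfg)
        score = weighted_allelic_score(cohort.dosages, panel)
        pvals[i] = wu_hausman(cohort.exposure, cohort.outcome, score)
    return {
        "rejection_rate": float(np.mean(pvals < alpha)),
        "pvalues": pvals,
        "n_reps": n_reps,
    }


# ---------------------------------------------------------------------------
# summary-level calibration (known SNP-exposure effects, homogeneous model)


def _summary_fixture(rng: np.random.Generator, k: int, theta: float,
                     sy: float = 0.02) -> pd.DataFrame:
    """One homogeneous summary-level draw: beta_out = theta*beta_exp + noise."""
    bx = np.abs(rng.normal(0.0, 0.05, size=k)) + 0.01
    by = theta * bx + rng.normal(0.0, sy, size=k)
    return pd.DataFrame(
        {
            "snp": [f"rs{i + 1}" for i in range(k)],
            "beta_exp": bx,
            "se_exp": np.full(k, 1e-6),
            "beta_out": by,
            "se_out": np.full(k, sy),
        }
    )


def cochran_q_calibration(seed: int = 0, n_reps: int = 500, k: int = 96,
                          theta: float = 0.3, alpha: float = 0.05) -> dict:
    """Cochran's Q rejection rate under homogeneity (all per-SNP effects equal)."""
    rng = np.random.default_rng(seed)
    rej = 0
    for _ in range(n_reps):
        res = IVWEstimator().fit(_summary_fixture(rng, k, theta))
        rej += res.q_p_ < alpha
    return {"rejection_rate": rej / n_reps, "n_reps": n_reps}


def egger_intercept_calibration(seed: int = 0, n_reps: int = 500, k: int = 96,
                                theta: float = 0.3, alpha: float = 0.05) -> dict:
    """Egger intercept test rejection rate with zero directional pleiotropy."""
    rng = np.random.default_rng(seed)
    rej = 0
    for _ in range(n_reps):
        res = MREggerEstimator().fit(_summary_fixture(rng, k, theta))
        rej += res.intercept_p_ < alpha
    return {"rejection_rate": rej / n_reps, "n_reps": n_reps}


# ---------------------------------------------------------------------------
# pleiotropy robustness (two-sample, individual-level generative model)


def _two_sample_stats(cfg: SimulationConfig):
    """Simulate one cohort of 2n and split it into disjoint exposure/outcome halves."""
    panel, cohort = simulate_cohort(cfg)
    half = cfg.n // 2
    mask = np.zeros(cfg.n, dtype=bool)
    mask[:half] = True
    exp_stats, out_stats = make_summary_stats(
        cohort.subset(mask), cohort.subset(~mask), panel
    )
    merged = exp_stats.merge(out_stats, on=["snp", "effect_allele", "other_allele"],
                             suffixes=("_exp", "_out"))
    return merged


def egger_pleiotropy_recovery(
    seed: int = 0,
    n_reps: int = 200,
    k: int = 20,
    theta: float = 0.3,
    pleiotropy_mean: float = 0.02,
    pleiotropy_sd: float = 0.01,
    sy: float = 0.02,
) -> dict:
    """Directional pleiotropy at the summary level: intercept recovery.

    SNP-exposure effects are known (negligible SE), so the NOME condition
    the Egger intercept's consistency requires holds exactly; each SNP's
    outcome effect is theta*beta_exp + alpha_j + noise with
    alpha_j ~ N(pleiotropy_mean, pleiotropy_sd^2) independent of
    instrument strength (InSIDE).  The mean intercept across replicates
    recovers the simulated mean direct effect.
    """
    rng = np.random.default_rng(seed)
    intercepts, ivw_betas, egger_betas = [], [], []
    for _ in range(n_reps):
        bx = np.abs(rng.normal(0.0, 0.05, size=k)) + 0.01
        alpha = rng.normal(pleiotropy_mean, pleiotropy_sd, size=k)
        by = theta * bx + alpha + rng.normal(0.0, sy, size=k)
        stats = pd.DataFrame(
            {
                "snp": [f"rs{i + 1}" for i in range(k)],
                "beta_exp": bx,
                "se_exp": np.full(k, 1e-6),
                "beta_out": by,
                "se_out": np.full(k, sy),
            }
        )
        egger_fit = MREggerEstimator().fit(stats)
        ivw_fit = IVWEstimator().fit(stats)
        intercepts.append(egger_fit.intercept_)
        egger_betas.append(egger_fit.beta_)
        ivw_betas.append(ivw_fit.beta_)
    intercepts = np.asarray(intercepts)
    return {
        "mean_intercept": float(intercepts.mean()),
        "intercept_mc_se": float(intercepts.std(ddof=1) / np.sqrt(n_reps)),
        "true_mean_direct_effect": pleiotropy_mean,
        "mean_egger_beta": float(np.mean(egger_betas)),
        "mean_ivw_beta": float(np.mean(ivw_betas)),
        "n_reps": n_reps,
        "theta": theta,
    }


def pleiotropy_study(
    seed: int = 0,
    n_reps: int = 200,
    k: int = 20,
    n_per_cohort: int = 20_000,
    theta: float = 0.3,
    pleiotropy_mean: float = 0.02,
    pleiotropy_sd: float = 0.01,
) -> dict:
    """Directional pleiotropy: Egger intercept recovery and slope robustness.

    Every SNP carries a direct outcome effect drawn
    N(pleiotropy_mean, pleiotropy_sd^2); the InSIDE condition holds by
    construction (direct effects independent of instrument strengths).
    """
    seeds = _child_seeds(seed, n_reps)
    intercepts, ivw_betas, egger_betas = [], [], []
    egger_closer = 0
    for s in seeds:
        cfg = SimulationConfig(
            n=2 * n_per_cohort, k=k, theta=theta, target_r2=0.03,
            prop_invalid=1.0, pleiotropy_mean=pleiotropy_mean,
            pleiotropy_sd=pleiotropy_sd, seed=int(s),
        )
        stats = _two_sample_stats(cfg)
        ivw_fit = IVWEstimator().fit(stats)
        egger_fit = MREggerEstimator().fit(stats)
        intercepts.append(egger_fit.intercept_)
        ivw_betas.append(ivw_fit.beta_)
        egger_betas.append(egger_fit.beta_)
        egger_closer += abs(egger_fit.beta_ - theta) < abs(ivw_fit.beta_ - theta)
    intercepts = np.asarray(intercepts)
    return {
        "mean_intercept": float(intercepts.mean()),
        "intercept_mc_se": float(intercepts.std(ddof=1) / np.sqrt(n_reps)),
        "true_mean_direct_effect": pleiotropy_mean,
        "mean_ivw_beta": float(np.mean(ivw_betas)),
        "mean_egger_beta": float(np.mean(egger_betas)),
        "frac_egger_closer": egger_closer / n_reps,
        "n_reps": n_reps,
        "theta": theta,
    }


def weighted_median_robustness(
    seed: int = 0,
    n_reps: int = 200,
    k: int = 96,
    n_per_cohort: int = 20_000,
    theta: float = 0.3,
    prop_invalid: float = 0.4,
    pleiotropy_mean: float = 0.1,
) -> dict:
    """40% invalid instruments with strong directional pleiotropy:
    compare absolute bias of the weighted median against IVW."""
    seeds = _child_seeds(seed, n_reps)
    wm_better = 0
    wm_betas, ivw_betas = [], []
    for s in seeds:
        cfg = SimulationConfig(
            n=2 * n_per_cohort, k=k, theta=theta, target_r2=0.03,
            prop_invalid=prop_invalid, pleiotropy_mean=pleiotropy_mean,
            pleiotropy_sd=0.01, seed=int(s),
        )
        stats = _two_sample_stats(cfg)
        ivw_fit = IVWEstimator().fit(stats)
        wm = weighted_median(stats, n_boot=100, seed=int(s))
        wm_betas.append(wm.beta)
        ivw_betas.append(ivw_fit.beta_)
        wm_better += abs(wm.beta - theta) < abs(ivw_fit.beta_ - theta)
    return {
        "frac_median_less_biased": wm_better / n_reps,
        "mean_wm_beta": float(np.mean(wm_betas)),
        "mean_ivw_beta": float(np.mean(ivw_betas)),
        "n_reps": n_reps,
        "theta": theta,
    }


def two_sample_recovery(seed: int = 0, n_per_cohort: int = 100_000, k: int = 96,
                        theta: float = 0.3) -> dict:
    """Single large two-sample draw with valid instruments: all three
    estimators should agree with theta.

    The cohorts are large because per-SNP instrument strength, not total
    score strength, controls the regression-dilution bias of summary-level
    estimators; at smaller n the estimates attenuate by roughly
    ncp/(ncp+1) per SNP."""
    cfg = SimulationConfig(n=2 * n_per_cohort, k=k, theta=theta,
                           target_r2=0.03, seed=int(seed))
    stats = _two_sample_stats(cfg)
    ivw_fit = IVWEstimator().fit(stats)
    egger_fit = MREggerEstimator().fit(stats)
    wm = weighted_median(stats, n_boot=500, seed=int(seed))
    return {
        "ivw_beta": ivw_fit.beta_,
        "egger_beta": egger_fit.beta_,
        "weighted_median_beta": wm.beta,
        "theta": theta,
        "k_snps": int(ivw_fit.k_),
    }


# ---------------------------------------------------------------------------
# split-sample reverse direction


def _reverse_config(s: int, n: int, theta_reverse: float, background_h2: float) -> SimulationConfig:
    return SimulationConfig(
        n=n, k=96, k_background=48,
        theta=0.3, theta_reverse=theta_reverse,
        target_r2=0.03, background_h2=background_h2,
        confounder_effect_x=0.5, confounder_effect_y=0.5,
        seed=int(s),
    )


def splitsample_study(
    seed: int = 0,
    n_reps: int = 100,
    n: int = 5000,
    theta_reverse: float = 0.0,
    background_h2: float = 0.2,
    p_threshold: float = 0.05,
    alpha: float = 0.05,
) -> dict:
    """Cross-fit split-sample MR of the reverse direction.

    The scanned trait is the outcome (its own polygenic component lives on
    background SNPs), the estimated outcome is the follow-up exposure, and
    the exposure-panel SNPs are excluded from score construction to avoid
    direct pleiotropy.  Reports the null rejection rate, sign recovery and
    the mean estimate (whose shortfall against ``theta_reverse`` is the
    winner's-curse attenuation).
    """
    seeds = _child_seeds(seed, n_reps)
    betas, pvals, signs = [], [], []
    r2_in, r2_out = [], []
    for s in seeds:
        cfg = _reverse_config(int(s), n, theta_reverse, background_h2)
        panel, cohort = simulate_cohort(cfg)
        res = cross_fit(
            cohort,
            exposure_name="outcome",
            outcome_name="exposure_followup",
            p_threshold=p_threshold,
            exclusion_list=panel["snp"].tolist(),
            seed=int(s),
        )
        c = res["combined"]
        betas.append(c.beta)
        pvals.append(c.p)
        signs.append(c.beta > 0)
        for key in ("A_to_B", "B_to_A"):
            est = res[key]
            if est is not None:
                r2_in.append(est.notes["r2_in_sample"])
                r2_out.append(est.notes["r2_out_of_sample"])
    betas = np.asarray(betas)
    r2_in, r2_out = np.asarray(r2_in), np.asarray(r2_out)
    r2_diff = r2_in - r2_out
    return {
        "rejection_rate": float(np.mean(np.asarray(pvals) < alpha)),
        "frac_sign_positive": float(np.mean(signs)),
        "mean_estimate": float(betas.mean()),
        "mc_se": float(betas.std(ddof=1) / np.sqrt(n_reps)),
        "mean_r2_in_sample": float(r2_in.mean()),
        "mean_r2_out_of_sample": float(r2_out.mean()),
        "mean_r2_attenuation": float(r2_diff.mean()),
        "r2_attenuation_mc_se": float(r2_diff.std(ddof=1) / np.sqrt(len(r2_diff))),
        "frac_instrument_attenuated": float(np.mean(r2_out < r2_in)),
        "theta_reverse": theta_reverse,
        "n_reps": n_reps,
        "n": n,
    }


def harmonization_idempotence(seed: int = 0, n_panels: int = 1000, k: int = 12) -> dict:
    """Harmonize randomized exposure/outcome panels twice; the second pass
    must be a no-op.  Returns the count of panels where it was."""
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
    ok = 0
    for _ in range(n_panels):
        idx = rng.integers(0, 4, size=k)
        shift = rng.integers(1, 4, size=k)
        ea = bases[idx]
        oa = bases[(idx + shift) % 4]
        eaf = rng.uniform(0.05, 0.95, size=k)
        exp = pd.DataFrame({
            "snp": [f"rs{i}" for i in range(k)],
            "effect_allele": ea, "other_allele": oa, "eaf": eaf,
            "beta": rng.normal(0, 0.1, size=k), "se": rng.uniform(0.01, 0.05, size=k),
        })
        out = exp.copy()
        # randomly recode the outcome side: swap alleles and/or strand-flip
        swap = rng.random(k) < 0.5
        strand = rng.random(k) < 0.5
        ea2, oa2 = out["effect_allele"].copy(), out["other_allele"].copy()
        ea2[swap], oa2[swap] = oa2[swap], ea2[swap].copy()
        out.loc[swap, "beta"] = -out.loc[swap, "beta"]
        out.loc[swap, "eaf"] = 1 - out.loc[swap, "eaf"]
        ea2[strand] = [comp[a] for a in ea2[strand]]
        oa2[strand] = [comp[a] for a in oa2[strand]]
        out["effect_allele"], out["other_allele"] = ea2, oa2
        out["beta"] = out["beta"] + rng.normal(0, 0.02, size=k)

        h1, _ = harmonize(exp, out)
        exp1 = exp[exp["snp"].isin(h1["snp"])]
        out1 = h1.rename(columns={"eaf_out": "eaf", "beta_out": "beta", "se_out": "se"})[
            ["snp", "effect_allele", "other_allele", "eaf", "beta", "se"]
        ]
        h2, _ = harmonize(exp1, out1)
        same = (
            len(h1) == len(h2)
            and np.allclose(h1["beta_out"].to_numpy(), h2["beta_out"].to_numpy())
            and np.allclose(h1["eaf_out"].to_numpy(), h2["eaf_out"].to_numpy())
        )
        ok += same
    return {"n_idempotent": ok, "n_panels": n_panels}
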