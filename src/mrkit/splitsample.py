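"""Split-sample MR for the reverse causal direction.

When no external GWAS exists for the exposure of interest (here the
disordered-eating-style trait), the cohort is randomly split in two:
a genome-wide association scan in one half yields SNP weights for a
prediction score, SNPs already known to affect the *other* trait are
excluded to avoid direct pleiotropy, and the score instruments the
trait in the opposite half via 2SLS.  Both directions (A-scan/B-estimate
and B-scan/A-estimate) are computed and combined by inverse-variance
meta-analysis.  In-sample scan weights carry winner's curse, so the
out-of-half instrument is weaker than the scan suggests and estimates
tend to attenuate toward the null — reported, not corrected.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats as sps

from .types import (
    CausalEstimate,
    PredictionScoreSpec,
    ScoreVector,
    SplitPlan,
    ValidationError,
)
from .simulate import Cohort
from .onesample import TwoStageLeastSquares
from ._scan import per_column_ols

logger = logging.getLogger(__name__)
_Z975 = sps.norm.ppf(0.975)


def split(cohort: Cohort, seed: int = 0) -> SplitPlan:
    """Balanced random A/B partition of the cohort, deterministic in seed."""
    n = cohort.n
    if n < 4:
        raise ValidationError("split requires at least 4 samples")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    assignment = np.empty(n, dtype="<U1")
    half = (n + 1) // 2
    assignment[perm[:half]] = "A"
    assignment[perm[half:]] = "B"
    return SplitPlan(seed=seed, assignment=assignment)


def gwas_scan(
    dosages: pd.DataFrame,
    trait,
    covariates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-SNP OLS of a continuous trait on dosage (+ covariates).

    Returns a one-sided summary-statistics frame (snp, eaf, beta, se,
    pval, n; allele columns are omitted because the scan works on the
    dosage coding directly).  Monomorphic SNPs are excluded with a
    warning.
    """
    y = np.asarray(trait, dtype=float)
    if len(dosages) != len(y):
        raise ValidationError("dosages and trait lengths differ")
    if dosages.shape[1] < 1:
        raise ValidationError("at least one SNP is required")
    g = dosages.to_numpy(float)
    cov = covariates.to_numpy(float) if covariates is not None and covariates.size else None
    res = per_column_ols(g, y, covariates=cov)
    mono = res["monomorphic"]
    if mono.any():
        dropped = [s for s, m in zip(dosages.columns, mono) if m]
        logger.warning("excluding %d monomorphic SNP(s) from scan: %s", len(dropped), dropped[:5])
    out = pd.DataFrame(
        {
            "snp": dosages.columns,
            "eaf": g.mean(axis=0) / 2.0,
            "beta": res["beta"],
            "se": res["se"],
            "pval": res["pval"],
            "n": len(y),
        }
    )
    return out.loc[~mono].reset_index(drop=True)


def build_prediction_score(
    scan: pd.DataFrame,
    p_threshold: float = 1e-5,
    exclusion_list: list[str] | None = None,
    dosages: pd.DataFrame | None = None,
) -> tuple[PredictionScoreSpec, ScoreVector]:
    """Select scan SNPs at ``p <= p_threshold``, drop excluded ids, and score.

    Weights are the scan betas oriented to the trait-increasing allele
    (negative-beta SNPs contribute via the complementary dosage 2 - g),
    and the score uses the same average-trait-increasing-allele formula
    as the exposure score.  Selecting zero SNPs is an explicit error
    advising a threshold change.
    """
    exclusion = list(exclusion_list or [])
    sel = scan.loc[(scan["pval"] <= p_threshold) & ~scan["snp"].isin(exclusion)].copy()
    if len(sel) == 0:
        raise ValidationError(
            f"no SNPs selected at p <= {p_threshold} after exclusions; "
            "consider a more permissive threshold"
        )
    if dosages is None:
        raise ValidationError("a dosage matrix is required to compute the score")
    missing = [s for s in sel["snp"] if s not in dosages.columns]
    if missing:
        raise ValidationError(f"dosage matrix lacks selected SNP(s): {missing[:5]}")
    g = dosages[sel["snp"].tolist()].to_numpy(float)
    beta = sel["beta"].to_numpy(float)
    flip = beta < 0
    g = np.where(flip, 2.0 - g, g)
    w = np.abs(beta)
    total = float(w.sum())
    if total <= 0:
        raise ValidationError("selected SNPs have zero total weight")
    k = len(sel)
    values = k * (g @ w) / total
    sel["weight"] = w
    spec = PredictionScoreSpec(
        selected_snps=sel[["snp", "weight", "pval"]].reset_index(drop=True),
        p_threshold=p_threshold,
        exclusion_list=exclusion,
    )
    return spec, ScoreVector(values=values, n_snps_used=k, normalization_constant=total)


def _direction_estimate(
    cohort: Cohort,
    scan_mask: np.ndarray,
    est_mask: np.ndarray,
    exposure_name: str,
    outcome_name: str,
    p_threshold: float,
    exclusion_list: list[str],
    label: str,
) -> CausalEstimate | None:
    scan_half = cohort.subset(scan_mask)
    est_half = cohort.subset(est_mask)
    scan = gwas_scan(
        scan_half.dosages, scan_half.phenotypes[exposure_name].to_numpy(float)
    )
    try:
        spec, score = build_prediction_score(
            scan, p_threshold, exclusion_list, est_half.dosages
        )
    except ValidationError as err:
        logger.warning("direction %s: %s", label, err)
        return None
    fit = TwoStageLeastSquares(weak_f_threshold=1.0).fit(
        est_half.phenotypes[exposure_name].to_numpy(float),
        est_half.phenotypes[outcome_name].to_numpy(float),
        score,
    )
    est = fit.estimate(stratum="all")
    est.method = "tsls_split"
    # winner's curse diagnostic: the same score's trait R^2 in the scan
    # half (where its weights were fitted) vs in the estimation half
    _, score_in = build_prediction_score(
        scan, p_threshold, exclusion_list, scan_half.dosages
    )
    trait_in = scan_half.phenotypes[exposure_name].to_numpy(float)
    trait_out = est_half.phenotypes[exposure_name].to_numpy(float)
    r2_in = float(np.corrcoef(score_in.values, trait_in)[0, 1] ** 2)
    r2_out = float(np.corrcoef(score.values, trait_out)[0, 1] ** 2)
    est.notes.update(
        {
            "direction": label,
            "n_selected_snps": spec.selected_snps.shape[0],
            "p_threshold": p_threshold,
            "weak_instrument": fit.diagnostics_.weak_instrument,
            "r2_in_sample": r2_in,
            "r2_out_of_sample": r2_out,
        }
    )
    return est


def cross_fit(
    cohort: Cohort,
    exposure_name: str,
    outcome_name: str,
    p_threshold: float = 1e-5,
    exclusion_list: list[str] | None = None,
    seed: int = 0,
) -> dict:
    """Both split-sample direction estimates plus their IVW combination.

    Scans ``exposure_name`` in one half, scores the other half, and runs
    2SLS of ``outcome_name`` on the exposure there; then the halves swap
    roles.  The combined estimate is a fixed-effect inverse-variance
    meta-analysis of the two direction-specific estimates (a design
    choice recorded in the output metadata).  A direction whose
    first-stage F falls below 1 is flagged, never silently dropped.
    """
    exclusion = list(exclusion_list or [])
    plan = split(cohort, seed=seed)
    est_ab = _direction_estimate(
        cohort, plan.mask("A"), plan.mask("B"),
        exposure_name, outcome_name, p_threshold, exclusion, "scanA_estimateB",
    )
    est_ba = _direction_estimate(
        cohort, plan.mask("B"), plan.mask("A"),
        exposure_name, outcome_name, p_threshold, exclusion, "scanB_estimateA",
    )
    available = [e for e in (est_ab, est_ba) if e is not None]
    if not available:
        raise ValidationError("no SNPs selected in either subsample; relax p_threshold")
    w = np.array([1.0 / e.se**2 for e in available])
    beta = float(np.sum(w * [e.beta for e in available]) / w.sum())
    se = float(np.sqrt(1.0 / w.sum()))
    combined = CausalEstimate(
        method="tsls_split_combined",
        beta=beta,
        se=se,
        ci_low=beta - _Z975 * se,
        ci_high=beta + _Z975 * se,
        p=float(2 * sps.norm.sf(abs(beta) / se)),
        n=cohort.n,
        notes={
            "combination": "fixed-effect inverse-variance meta-analysis",
            "directions_used": [e.notes["direction"] for e in available],
            "weak_instrument": any(e.notes.get("weak_instrument") for e in available),
        },
    )
    return {"A_to_B": est_ab, "B_to_A": est_ba, "combined": combined, "plan": plan}
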