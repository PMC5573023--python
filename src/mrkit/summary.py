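"""Summary-statistic MR: harmonization and pleiotropy-robust estimators.

Given per-SNP exposure effects (beta_exp, se_exp) and outcome effects
(beta_out, se_out) on aligned effect alleles, the estimators are

* IVW — weighted regression of beta_out on beta_exp through the origin
  with weights 1/se_out^2 (equivalently the inverse-variance-weighted
  mean of per-SNP Wald ratios), with Cochran's Q on k-1 df;
* MR-Egger — the same regression with a free intercept after orienting
  every beta_exp >= 0; the intercept estimates average directional
  pleiotropy, the slope is the pleiotropy-adjusted causal effect, and
  Rucker's Q' sits on k-2 df;
* weighted median — the weighted median of Wald ratios, consistent when
  under half the instrument weight comes from invalid SNPs, with a
  parametric-bootstrap standard error.

All estimators are invariant to SNP row order and to jointly flipping
the allele coding (sign of both betas) of any SNP.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.base import BaseEstimator

from .types import MRResult, ValidationError, validate_summary_stats

logger = logging.getLogger(__name__)

_Z975 = sps.norm.ppf(0.975)
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

HARMONIZED_COLUMNS = [
    "snp", "effect_allele", "other_allele",
    "eaf_exp", "beta_exp", "se_exp",
    "eaf_out", "beta_out", "se_out",
]


def _is_palindromic(a1: str, a2: str) -> bool:
    return _COMPLEMENT[a1] == a2


def harmonize(
    exposure_stats: pd.DataFrame,
    outcome_stats: pd.DataFrame,
    palindrome_policy: str = "drop",
    ambiguity_bound: float = 0.42,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Align outcome summary statistics to the exposure's effect alleles.

    Inner-joins on SNP id.  When the outcome's effect allele matches the
    exposure's other allele (directly or via strand complement), the
    outcome beta's sign is flipped and its EAF reflected.  Palindromic
    (A/T, G/C) SNPs are strand-ambiguous: under the default ``"drop"``
    policy they are removed when either side's EAF is within the
    ambiguity band (min(eaf, 1-eaf) >= ``ambiguity_bound``) and otherwise
    aligned by allele frequency; the ``"strict"`` policy drops every
    palindrome.  Irreconcilable allele pairs are dropped, never silently.

    Returns the harmonized two-sided frame and a per-SNP action log.
    """
    if palindrome_policy not in ("drop", "strict"):
        raise ValidationError("palindrome_policy must be 'drop' or 'strict'")
    exp = validate_summary_stats(exposure_stats)
    out = validate_summary_stats(outcome_stats)
    merged = exp.merge(out, on="snp", suffixes=("_exp", "_out"))
    rows, log = [], []

    for rec in merged.itertuples(index=False):
        d = rec._asdict()
        ea_x, oa_x = d["effect_allele_exp"], d["other_allele_exp"]
        ea_y, oa_y = d["effect_allele_out"], d["other_allele_out"]
        eaf_x = float(d.get("eaf_exp", np.nan))
        eaf_y = float(d.get("eaf_out", np.nan))
        beta_y, action, keep = float(d["beta_out"]), "kept", True

        if _is_palindromic(ea_x, oa_x):
            if {ea_y, oa_y} != {ea_x, oa_x}:
                keep, action = False, "dropped:irreconcilable_alleles"
            elif palindrome_policy == "strict":
                keep, action = False, "dropped:palindromic_strict"
            else:
                ambiguous = (
                    not np.isfinite(eaf_x)
                    or not np.isfinite(eaf_y)
                    or min(eaf_x, 1 - eaf_x) >= ambiguity_bound
                    or min(eaf_y, 1 - eaf_y) >= ambiguity_bound
                )
                if ambiguous:
                    keep, action = False, "dropped:palindromic_ambiguous"
                elif (eaf_x < 0.5) == (eaf_y < 0.5):
                    action = "kept:palindromic_freq_aligned"
                else:
                    beta_y, eaf_y = -beta_y, 1 - eaf_y
                    action = "flipped:palindromic_freq_aligned"
        else:
            if (ea_y, oa_y) == (ea_x, oa_x):
                action = "kept"
            elif (ea_y, oa_y) == (oa_x, ea_x):
                beta_y, eaf_y = -beta_y, 1 - eaf_y
                action = "flipped"
            elif (_COMPLEMENT[ea_y], _COMPLEMENT[oa_y]) == (ea_x, oa_x):
                action = "kept:strand_complement"
            elif (_COMPLEMENT[ea_y], _COMPLEMENT[oa_y]) == (oa_x, ea_x):
                beta_y, eaf_y = -beta_y, 1 - eaf_y
                action = "flipped:strand_complement"
            else:
                keep, action = False, "dropped:irreconcilable_alleles"

        log.append({"snp": d["snp"], "action": action})
        if keep:
            rows.append(
                {
                    "snp": d["snp"],
                    "effect_allele": ea_x,
                    "other_allele": oa_x,
                    "eaf_exp": eaf_x,
                    "beta_exp": float(d["beta_exp"]),
                    "se_exp": float(d["se_exp"]),
                    "eaf_out": eaf_y,
                    "beta_out": beta_y,
                    "se_out": float(d["se_out"]),
                }
            )
    harmonized = pd.DataFrame(rows, columns=HARMONIZED_COLUMNS)
    log_df = pd.DataFrame(log, columns=["snp", "action"])
    n_dropped = int(log_df["action"].str.startswith("dropped").sum())
    if n_dropped:
        logger.info("harmonization dropped %d of %d merged SNPs", n_dropped, len(log_df))
    return harmonized, log_df


def _check_harmonized(stats: pd.DataFrame, min_k: int, method: str) -> pd.DataFrame:
    for col in ("beta_exp", "se_exp", "beta_out", "se_out"):
        if col not in stats.columns:
            raise ValidationError(f"harmonized summary statistics need column {col!r}")
    if (stats["se_out"] <= 0).any() or (stats["se_exp"] <= 0).any():
        raise ValidationError("standard errors must be strictly positive")
    if len(stats) < min_k:
        raise ValidationError(f"{method} requires at least {min_k} SNPs, got {len(stats)}")
    return stats


def wald_ratios(stats: pd.DataFrame, min_beta_exp: float = 1e-12) -> pd.DataFrame:
    """Per-SNP Wald ratios beta_out/beta_exp with first-order SE se_out/|beta_exp|.

    SNPs whose |beta_exp| falls below ``min_beta_exp`` are excluded with a
    warning (the ratio is unstable there); excluding every SNP is an error.
    """
    stats = _check_harmonized(stats, 1, "wald_ratios")
    bx = stats["beta_exp"].to_numpy(float)
    keep = np.abs(bx) >= min_beta_exp
    if not keep.all():
        warnings.warn(
            f"excluding {int((~keep).sum())} SNP(s) with |beta_exp| < {min_beta_exp}",
            stacklevel=2,
        )
    if not keep.any():
        raise ValidationError("all SNPs excluded: no usable exposure effects")
    sub = stats.loc[keep]
    bx = sub["beta_exp"].to_numpy(float)
    by = sub["beta_out"].to_numpy(float)
    sy = sub["se_out"].to_numpy(float)
    return pd.DataFrame(
        {"snp": sub["snp"].to_numpy(), "ratio": by / bx, "se": sy / np.abs(bx)}
    )


class IVWEstimator(BaseEstimator):
    """Inverse-variance-weighted MR (fixed-effect by default).

    Weighted regression of beta_out on beta_exp through the origin with
    first-order weights 1/se_out^2.  ``random_effects=True`` applies the
    multiplicative random-effects inflation sqrt(Q/(k-1)) when Q exceeds
    its degrees of freedom.  Cochran's Q is always reported.
    """

    def __init__(self, random_effects: bool = False):
        self.random_effects = random_effects

    def fit(self, stats: pd.DataFrame):
        stats = _check_harmonized(stats, 1, "IVW")
        bx = stats["beta_exp"].to_numpy(float)
        by = stats["beta_out"].to_numpy(float)
        sy = stats["se_out"].to_numpy(float)
        w = 1.0 / sy**2
        denom = float(np.sum(w * bx**2))
        if denom <= 0:
            raise ValidationError("IVW undefined: all exposure effects are zero")
        beta = float(np.sum(w * bx * by)) / denom
        se = float(np.sqrt(1.0 / denom))
        k = len(bx)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratios = np.where(bx != 0, by / bx, 0.0)
        wq = w * bx**2
        q = float(np.sum(wq * (ratios - beta) ** 2))
        q_df = k - 1
        q_p = float(sps.chi2.sf(q, q_df)) if q_df > 0 else float("nan")
        if self.random_effects and q_df > 0 and q > q_df:
            se *= float(np.sqrt(q / q_df))
        self.k_ = k
        self.beta_, self.se_ = beta, se
        self.q_, self.q_df_, self.q_p_ = q, q_df, q_p
        self.q_contributions_ = wq * (ratios - beta) ** 2
        self.p_ = float(2 * sps.norm.sf(abs(beta) / se))
        self.result_ = MRResult(
            method="ivw",
            beta=beta,
            se=se,
            ci_low=beta - _Z975 * se,
            ci_high=beta + _Z975 * se,
            p=self.p_,
            k_snps=k,
            q_stat=q,
            q_df=q_df,
            q_p=q_p,
            notes={"weights": "1/se_out^2", "model": "random" if self.random_effects else "fixed"},
        )
        return self


class MREggerEstimator(BaseEstimator):
    """MR-Egger regression: free intercept as a directional-pleiotropy test.

    SNPs are oriented so every beta_exp >= 0 (both betas flipped where
    needed), which the intercept's interpretation requires.  Confidence
    intervals use a t distribution on k-2 df by default
    (``ci_dist="normal"`` for the large-k normal approximation).
    """

    def __init__(self, ci_dist: str = "t"):
        self.ci_dist = ci_dist

    def fit(self, stats: pd.DataFrame):
        stats = _check_harmonized(stats, 3, "MR-Egger")
        bx = stats["beta_exp"].to_numpy(float).copy()
        by = stats["beta_out"].to_numpy(float).copy()
        sy = stats["se_out"].to_numpy(float)
        flip = bx < 0
        bx[flip], by[flip] = -bx[flip], -by[flip]
        w = 1.0 / sy**2
        design = np.column_stack([np.ones_like(bx), bx])
        wd = design * w[:, None]
        xtx = design.T @ wd
        coef = np.linalg.solve(xtx, wd.T @ by)
        resid = by - design @ coef
        k = len(bx)
        q_prime = float(np.sum(w * resid**2))
        q_df = k - 2
        cov = np.linalg.inv(xtx)
        # multiplicative overdispersion, floored at 1 (Rucker model)
        phi = max(q_prime / q_df, 1.0) if q_df > 0 else 1.0
        se_int = float(np.sqrt(phi * cov[0, 0]))
        se_slope = float(np.sqrt(phi * cov[1, 1]))
        if self.ci_dist == "t" and q_df > 0:
            crit = float(sps.t.ppf(0.975, q_df))
            pfun = lambda t: float(2 * sps.t.sf(abs(t), q_df))  # noqa: E731
        else:
            crit = _Z975
            pfun = lambda t: float(2 * sps.norm.sf(abs(t)))  # noqa: E731
        slope, intercept = float(coef[1]), float(coef[0])
        self.k_ = k
        self.beta_, self.se_ = slope, se_slope
        self.intercept_, self.intercept_se_ = intercept, se_int
        self.intercept_p_ = pfun(intercept / se_int) if se_int > 0 else 0.0
        self.p_ = pfun(slope / se_slope) if se_slope > 0 else 0.0
        self.q_, self.q_df_ = q_prime, q_df
        self.q_p_ = float(sps.chi2.sf(q_prime, q_df)) if q_df > 0 else float("nan")
        self.result_ = MRResult(
            method="egger",
            beta=slope,
            se=se_slope,
            ci_low=slope - crit * se_slope,
            ci_high=slope + crit * se_slope,
            p=self.p_,
            k_snps=k,
            intercept=intercept,
            intercept_se=se_int,
            intercept_p=self.intercept_p_,
            q_stat=q_prime,
            q_df=q_df,
            q_p=self.q_p_,
            notes={"orientation": "beta_exp >= 0", "ci_dist": self.ci_dist},
        )
        return self


class WeightedMedianEstimator(BaseEstimator):
    """Weighted median of Wald ratios with a parametric-bootstrap SE.

    Consistent when SNPs carrying at least half the inverse-variance
    weight are valid instruments.  The estimate interpolates the ordered
    ratios at cumulative weight 0.5 using the cumulative-midpoint rule
    p_j = (sum_{k<=j} w_k) - w_j/2 with normalized weights.
    """

    def __init__(self, n_boot: int = 1000, random_state: int | None = None):
        self.n_boot = n_boot
        self.random_state = random_state

    @staticmethod
    def _weighted_median(ratios: np.ndarray, weights: np.ndarray) -> float:
        order = np.argsort(ratios)
        r = ratios[order]
        w = weights[order] / weights.sum()
        mid = np.cumsum(w) - w / 2.0
        return float(np.interp(0.5, mid, r))

    def fit(self, stats: pd.DataFrame):
        stats = _check_harmonized(stats, 2, "weighted median")
        if self.n_boot < 100:
            raise ValidationError("n_boot must be >= 100 for a usable bootstrap SE")
        ratios_df = wald_ratios(stats)
        ratios = ratios_df["ratio"].to_numpy(float)
        weights = 1.0 / ratios_df["se"].to_numpy(float) ** 2
        beta = self._weighted_median(ratios, weights)

        rng = np.random.default_rng(self.random_state)
        bx = stats["beta_exp"].to_numpy(float)
        sx = stats["se_exp"].to_numpy(float)
        by = stats["beta_out"].to_numpy(float)
        sy = stats["se_out"].to_numpy(float)
        boots = np.empty(self.n_boot)
        for b in range(self.n_boot):
            bxb = rng.normal(bx, sx)
            byb = rng.normal(by, sy)
            bxb = np.where(bxb == 0, np.finfo(float).tiny, bxb)
            rb = byb / bxb
            wb = (np.abs(bxb) / sy) ** 2
            boots[b] = self._weighted_median(rb, wb)
        se = float(np.std(boots, ddof=1))
        self.k_ = len(ratios)
        self.beta_, self.se_ = beta, se
        self.p_ = float(2 * sps.norm.sf(abs(beta) / se)) if se > 0 else 0.0
        self.result_ = MRResult(
            method="weighted_median",
            beta=beta,
            se=se,
            ci_low=beta - _Z975 * se,
            ci_high=beta + _Z975 * se,
            p=self.p_,
            k_snps=self.k_,
            notes={"n_boot": self.n_boot},
        )
        return self


def ivw(stats: pd.DataFrame, random_effects: bool = False) -> MRResult:
    """IVW causal estimate with Cochran's Q; see :class:`IVWEstimator`."""
    return IVWEstimator(random_effects=random_effects).fit(stats).result_


def egger(stats: pd.DataFrame, ci_dist: str = "t") -> MRResult:
    """MR-Egger slope/intercept with Rucker's Q'; see :class:`MREggerEstimator`."""
    return MREggerEstimator(ci_dist=ci_dist).fit(stats).result_


def weighted_median(
    stats: pd.DataFrame, n_boot: int = 1000, seed: int | None = None
) -> MRResult:
    """Weighted-median causal estimate; see :class:`WeightedMedianEstimator`."""
    return WeightedMedianEstimator(n_boot=n_boot, random_state=seed).fit(stats).result_


def leave_one_out(stats: pd.DataFrame, method: str = "ivw") -> pd.DataFrame:
    """Influence analysis: re-estimate excluding each SNP in turn.

    Returns one row per SNP with the leave-one-out estimate, its delta
    from the full-sample estimate, the SNP's contribution to the
    full-sample heterogeneity statistic, and ranks by |delta| and by Q
    contribution — a concrete procedure for naming the SNPs driving any
    pleiotropic signal.
    """
    if method == "ivw":
        min_k, fit = 2, lambda s: IVWEstimator().fit(s)
    elif method == "egger":
        min_k, fit = 4, lambda s: MREggerEstimator().fit(s)
    else:
        raise ValidationError("method must be 'ivw' or 'egger'")
    _check_harmonized(stats, min_k, f"leave-one-out {method}")
    full = fit(stats)
    if method == "ivw":
        q_contrib = full.q_contributions_
    else:
        bx = stats["beta_exp"].to_numpy(float).copy()
        by = stats["beta_out"].to_numpy(float).copy()
        flipm = bx < 0
        bx[flipm], by[flipm] = -bx[flipm], -by[flipm]
        resid = by - full.intercept_ - full.beta_ * bx
        q_contrib = resid**2 / stats["se_out"].to_numpy(float) ** 2
    out = []
    for i in range(len(stats)):
        sub = stats.drop(stats.index[i])
        loo = fit(sub)
        out.append(
            {
                "snp": stats["snp"].iloc[i],
                "beta_loo": loo.beta_,
                "delta": loo.beta_ - full.beta_,
                "q_contribution": float(q_contrib[i]),
            }
        )
    df = pd.DataFrame(out)
    df["rank_delta"] = df["delta"].abs().rank(ascending=False).astype(int)
    df["rank_q"] = df["q_contribution"].rank(ascending=False).astype(int)
    return df.sort_values("rank_delta", kind="stable").reset_index(drop=True)
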