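"""Weighted allelic score construction and instrument characterisation.

The score for individual i over k SNPs with external weights w_j and
effect-allele dosages g_ij in [0, 2] is

    S_i = k * (sum_j w_j g_ij) / (sum_j w_j),

i.e. the weighted sum rescaled so it reads as a count of "average
exposure-increasing alleles" carried, living on [0, 2k].  Weights must be
oriented non-negative (the orientation relabels effect alleles, it never
changes the score's information content) and scaling every weight by a
positive constant leaves the score unchanged.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from sklearn.base import BaseEstimator, TransformerMixin

from .types import AssociationRecord, ScoreVector, ValidationError, validate_panel


class WeightedAllelicScore(BaseEstimator, TransformerMixin):
    """sklearn-style transformer mapping a dosage matrix to the score column.

    Parameters
    ----------
    panel : DataFrame
        Variant panel with ``snp``, ``eaf`` and non-negative ``weight``
        columns; only SNPs present in the input dosage frame's columns
        are used (all must be present when the input is a bare array).
    impute_missing : bool
        When True, NaN dosages are imputed per SNP with 2*eaf from the
        panel; otherwise missing dosages raise.
    """

    def __init__(self, panel: pd.DataFrame | None = None, impute_missing: bool = False):
        self.panel = panel
        self.impute_missing = impute_missing

    def fit(self, X, y=None):
        if self.panel is None:
            raise ValidationError("a variant panel is required")
        panel = validate_panel(self.panel, require_nonnegative_weights=True)
        weights = panel["weight"].to_numpy(float)
        total = float(weights.sum())
        if total <= 0:
            raise ValidationError("sum of panel weights must be positive")
        self.panel_ = panel
        self.n_snps_used_ = len(panel)
        self.weight_sum_ = total
        return self

    def transform(self, X) -> np.ndarray:
        if not hasattr(self, "panel_"):
            self.fit(X)
        panel = self.panel_
        if isinstance(X, pd.DataFrame):
            missing = [s for s in panel["snp"] if s not in X.columns]
            if missing:
                raise ValidationError(f"dosage matrix lacks panel SNP(s): {missing[:5]}")
            g = X[panel["snp"].tolist()].to_numpy(float)
        else:
            g = np.asarray(X, dtype=float)
            if g.ndim != 2 or g.shape[1] != len(panel):
                raise ValidationError(
                    f"dosage array must be n x {len(panel)} to match the panel"
                )
        nan_mask = np.isnan(g)
        if nan_mask.any():
            if not self.impute_missing:
                raise ValidationError(
                    "missing dosages present; pass impute_missing=True to mean-impute (2*eaf)"
                )
            fill = 2.0 * panel["eaf"].to_numpy(float)
            g = np.where(nan_mask, np.broadcast_to(fill, g.shape), g)
        if np.any(g < -1e-9) or np.any(g > 2 + 1e-9):
            i, j = np.argwhere((g < -1e-9) | (g > 2 + 1e-9))[0]
            raise ValidationError(
                f"dosage outside [0, 2] at row {i}, SNP {panel['snp'].iloc[j]}"
            )
        w = panel["weight"].to_numpy(float)
        values = self.n_snps_used_ * (g @ w) / self.weight_sum_
        return values[:, None]


def weighted_allelic_score(
    dosages, panel: pd.DataFrame, impute_missing: bool = False
) -> ScoreVector:
    """Compute the weighted allelic score; see :class:`WeightedAllelicScore`."""
    tf = WeightedAllelicScore(panel=panel, impute_missing=impute_missing).fit(dosages)
    values = tf.transform(dosages)[:, 0]
    return ScoreVector(
        values=values,
        n_snps_used=tf.n_snps_used_,
        normalization_constant=tf.weight_sum_,
    )


def _score_values(score) -> np.ndarray:
    if isinstance(score, ScoreVector):
        return score.values
    return np.asarray(score, dtype=float).ravel()


def score_trait_association(
    score,
    trait,
    covariates: pd.DataFrame | None = None,
    variable: str = "trait",
) -> AssociationRecord:
    """OLS of a trait on the score (plus covariates): slope per score allele.

    Reports the slope with a 95% normal CI and two-sided p, the score-only
    R^2 (as conventionally tabulated for instrument strength) and the
    incremental R^2 of the score over the covariate-only model.
    """
    s = _score_values(score)
    y = np.asarray(trait, dtype=float)
    if len(s) != len(y):
        raise ValidationError("score and trait lengths differ")
    if np.var(s) <= 0:
        raise ValidationError("score is constant: no instrument variance")
    if covariates is not None and len(covariates.columns) > 0:
        c = covariates.to_numpy(float)
        design = sm.add_constant(np.column_stack([s, c]))
        base = sm.OLS(y, sm.add_constant(c)).fit()
        base_r2 = base.rsquared
    else:
        design = sm.add_constant(s)
        base_r2 = 0.0
    fit = sm.OLS(y, design).fit()
    beta = float(fit.params[1])
    se = float(fit.bse[1])
    marginal = sm.OLS(y, sm.add_constant(s)).fit()
    return AssociationRecord(
        variable=variable,
        beta=beta,
        ci_low=beta - 1.959963984540054 * se,
        ci_high=beta + 1.959963984540054 * se,
        p=float(fit.pvalues[1]),
        r2=float(marginal.rsquared),
        r2_incremental=float(fit.rsquared - base_r2),
        n=len(y),
    )


def confounder_screen(
    score, covariates: pd.DataFrame, alpha: float = 0.05
) -> list[AssociationRecord]:
    """Regress each candidate confounder on the score; flag p < alpha.

    Flagged covariates are the set a downstream MR re-analysis should
    additionally adjust for.  ``alpha=0`` flags nothing.
    """
    if covariates is None or covariates.shape[1] < 1:
        raise ValidationError("at least one covariate is required")
    s = _score_values(score)
    if np.var(s) <= 0:
        raise ValidationError("score is constant: no instrument variance")
    c = covariates.to_numpy(float)
    # regress covariate ~ score, one simple OLS per column, in closed form
    n = len(s)
    sc = s - s.mean()
    sxx = float(sc @ sc)
    records: list[AssociationRecord] = []
    z975 = sps.norm.ppf(0.975)
    for j, name in enumerate(covariates.columns):
        yj = c[:, j]
        yc = yj - yj.mean()
        beta = float(sc @ yc) / sxx
        rss = float(yc @ yc) - beta**2 * sxx
        df = n - 2
        sigma2 = max(rss, 0.0) / df
        se = float(np.sqrt(sigma2 / sxx))
        if se == 0.0:
            p = 0.0 if beta != 0 else 1.0
        else:
            p = float(2 * sps.t.sf(abs(beta) / se, df))
        syy = float(yc @ yc)
        r2 = beta**2 * sxx / syy if syy > 0 else 0.0
        records.append(
            AssociationRecord(
                variable=str(name),
                beta=beta,
                ci_low=beta - z975 * se,
                ci_high=beta + z975 * se,
                p=p,
                r2=r2,
                n=n,
                flagged=bool(p < alpha),
            )
        )
    return records
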