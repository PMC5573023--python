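"""Observational models and one-sample instrumental-variable estimation.

The causal contrast throughout is the change in the outcome (SD units)
per unit increase in the exposure.  Observational estimates come from
multivariable OLS under three nested adjustment sets; the instrumental
estimate is two-stage least squares (2SLS) with the weighted allelic
score as the instrument, with classical 2SLS standard errors computed
from residuals against the *observed* exposure (a sandwich option is
available).  Exposure endogeneity is tested in control-function form
(Wu-Hausman).  Analyses can be refit within sex strata.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from sklearn.base import BaseEstimator

from .types import CausalEstimate, StageDiagnostics, ValidationError
from .scores import _score_values

logger = logging.getLogger(__name__)

_Z975 = sps.norm.ppf(0.975)

#: Default mapping from model labels to covariate-column subsets, in the
#: spirit of minimally / confounder / fully adjusted observational models.
ADJUSTMENT_SETS: dict[str, tuple[str, ...]] = {
    "unadjusted": (),
    "age_only": ("age",),
    "age_plus_confounders": ("age", "confounder"),
    "fully_adjusted": ("age", "confounder", "energy_intake"),
}


def _stratum_mask(n: int, sex: np.ndarray | None, stratum: str) -> np.ndarray:
    if stratum == "all":
        return np.ones(n, dtype=bool)
    if sex is None:
        raise ValidationError("a sex vector is required for sex-stratified analysis")
    sex = np.asarray(sex)
    if stratum == "male":
        return sex == 0
    if stratum == "female":
        return sex == 1
    raise ValidationError(f"unknown stratum {stratum!r}; use all / male / female")


def _complete_cases(*arrays: np.ndarray) -> np.ndarray:
    ok = np.ones(len(arrays[0]), dtype=bool)
    for a in arrays:
        if a is None:
            continue
        a2 = np.asarray(a, dtype=float)
        ok &= np.all(np.isfinite(np.atleast_2d(a2.T).T), axis=1)
    return ok


def observational_models(
    exposure,
    outcome,
    covariates: pd.DataFrame,
    model_spec: str = "age_only",
    stratum: str = "all",
    sex: np.ndarray | None = None,
    adjustment_sets: dict[str, tuple[str, ...]] | None = None,
) -> CausalEstimate:
    """Multivariable OLS of outcome on exposure under a named adjustment set.

    ``model_spec`` selects a covariate subset from ``adjustment_sets``
    (default :data:`ADJUSTMENT_SETS`); a covariate named there but absent
    from the table raises an error naming it.  Complete-case analysis on
    the union of model variables.
    """
    sets = adjustment_sets or ADJUSTMENT_SETS
    if model_spec not in sets:
        raise ValidationError(f"unknown model_spec {model_spec!r}; options: {sorted(sets)}")
    wanted = sets[model_spec]
    absent = [c for c in wanted if c not in covariates.columns]
    if absent:
        raise ValidationError(f"adjustment covariate(s) absent from table: {absent}")
    x = np.asarray(exposure, dtype=float)
    y = np.asarray(outcome, dtype=float)
    c = covariates[list(wanted)].to_numpy(float) if wanted else np.empty((len(x), 0))
    mask = _stratum_mask(len(x), sex, stratum) & _complete_cases(x, y, c)
    x, y, c = x[mask], y[mask], c[mask]
    design = sm.add_constant(np.column_stack([x, c]) if c.size else x)
    fit = sm.OLS(y, design).fit()
    beta, se = float(fit.params[1]), float(fit.bse[1])
    return CausalEstimate(
        method="ols",
        beta=beta,
        se=se,
        ci_low=beta - _Z975 * se,
        ci_high=beta + _Z975 * se,
        p=float(fit.pvalues[1]),
        n=int(mask.sum()),
        stratum=stratum,
        notes={"model_spec": model_spec, "covariates": list(wanted)},
    )


def sex_interaction(
    exposure, outcome, covariates: pd.DataFrame, sex
) -> CausalEstimate:
    """Exposure-by-sex interaction term from a pooled adjusted OLS model.

    Sex is coded 0 = male (reference) / 1 = female, so the product-term
    slope reads as the female-minus-male difference in the
    exposure-outcome slope.
    """
    x = np.asarray(exposure, dtype=float)
    y = np.asarray(outcome, dtype=float)
    sx = np.asarray(sex, dtype=float)
    if len(np.unique(sx[np.isfinite(sx)])) < 2:
        raise ValidationError("sex-interaction model requires both sexes present")
    c = covariates.to_numpy(float) if covariates is not None and covariates.size else np.empty((len(x), 0))
    mask = _complete_cases(x, y, sx, c)
    x, y, sx, c = x[mask], y[mask], sx[mask], c[mask]
    cols = [x, sx, x * sx] + ([c] if c.size else [])
    design = sm.add_constant(np.column_stack(cols))
    fit = sm.OLS(y, design).fit()
    beta, se = float(fit.params[3]), float(fit.bse[3])
    return CausalEstimate(
        method="ols_interaction",
        beta=beta,
        se=se,
        ci_low=beta - _Z975 * se,
        ci_high=beta + _Z975 * se,
        p=float(fit.pvalues[3]),
        n=int(mask.sum()),
        notes={"term": "exposure_x_sex", "reference": "male"},
    )


class TwoStageLeastSquares(BaseEstimator):
    """Two-stage least squares with a single (score) instrument.

    Stage 1 regresses the exposure on the instrument plus covariates;
    stage 2 regresses the outcome on the stage-1 fitted exposure plus the
    same covariates.  The residual variance for the standard error uses
    residuals formed with the observed exposure, giving the proper 2SLS
    covariance.  ``robust=True`` swaps in the HC0 sandwich.

    Fitted attributes: ``beta_``, ``se_``, ``ci_``, ``p_``,
    ``diagnostics_`` (first-stage F, incremental R^2) and ``estimate_``.
    """

    def __init__(self, robust: bool = False, weak_f_threshold: float = 10.0):
        self.robust = robust
        self.weak_f_threshold = weak_f_threshold

    def fit(self, exposure, outcome, instrument, covariates=None):
        x = np.asarray(exposure, dtype=float)
        y = np.asarray(outcome, dtype=float)
        z = _score_values(instrument)
        if covariates is None:
            c = np.empty((len(x), 0))
        elif isinstance(covariates, pd.DataFrame):
            c = covariates.to_numpy(float)
        else:
            c = np.atleast_2d(np.asarray(covariates, dtype=float).T).T
        if not (len(x) == len(y) == len(z) == len(c)):
            raise ValidationError("exposure, outcome, instrument and covariates lengths differ")
        mask = _complete_cases(x, y, z, c)
        x, y, z, c = x[mask], y[mask], z[mask], c[mask]
        n = len(x)
        if np.var(z) <= 0:
            raise ValidationError("instrument is constant within the analysis sample")

        ones = np.ones((n, 1))
        zmat = np.column_stack([ones, z] + ([c] if c.size else []))
        gamma, *_ = np.linalg.lstsq(zmat, x, rcond=None)
        x_hat = zmat @ gamma

        # first-stage diagnostics: partial F and incremental R^2 of the instrument
        base = np.column_stack([ones] + ([c] if c.size else []))
        bcoef, *_ = np.linalg.lstsq(base, x, rcond=None)
        rss0 = float(np.sum((x - base @ bcoef) ** 2))
        rss1 = float(np.sum((x - x_hat) ** 2))
        df1 = n - zmat.shape[1]
        f_stat = max(rss0 - rss1, 0.0) / (rss1 / df1) if rss1 > 0 else np.inf
        tss = float(np.sum((x - x.mean()) ** 2))
        r2_first = max(rss0 - rss1, 0.0) / tss if tss > 0 else 0.0

        wmat_hat = np.column_stack([ones, x_hat] + ([c] if c.size else []))
        wmat_obs = np.column_stack([ones, x] + ([c] if c.size else []))
        xtx = wmat_hat.T @ wmat_hat
        beta_vec = np.linalg.solve(xtx, wmat_hat.T @ y)
        resid = y - wmat_obs @ beta_vec  # residuals against observed exposure
        p = wmat_hat.shape[1]
        xtx_inv = np.linalg.inv(xtx)
        if self.robust:
            meat = (wmat_hat * resid[:, None]).T @ (wmat_hat * resid[:, None])
            cov = xtx_inv @ meat @ xtx_inv
        else:
            sigma2 = float(resid @ resid) / (n - p)
            cov = sigma2 * xtx_inv
        beta = float(beta_vec[1])
        se = float(np.sqrt(cov[1, 1]))

        weak = f_stat < self.weak_f_threshold
        if weak:
            logger.warning("weak instrument: first-stage F = %.2f < %.1f", f_stat, self.weak_f_threshold)

        self.n_ = n
        self.beta_ = beta
        self.se_ = se
        self.ci_ = (beta - _Z975 * se, beta + _Z975 * se)
        self.p_ = float(2 * sps.norm.sf(abs(beta) / se)) if se > 0 else 0.0
        self.diagnostics_ = StageDiagnostics(
            f_stat=float(f_stat), r2_first=float(r2_first), weak_instrument=bool(weak)
        )
        self.coef_vector_ = beta_vec
        return self

    def estimate(self, stratum: str = "all") -> CausalEstimate:
        return CausalEstimate(
            method="tsls",
            beta=self.beta_,
            se=self.se_,
            ci_low=self.ci_[0],
            ci_high=self.ci_[1],
            p=self.p_,
            n=self.n_,
            stratum=stratum,
            notes={
                "se_type": "hc0" if self.robust else "classical",
                "f_stat": self.diagnostics_.f_stat,
                "r2_first": self.diagnostics_.r2_first,
            },
        )


def tsls(
    exposure,
    outcome,
    instrument,
    covariates=None,
    stratum: str = "all",
    sex=None,
    robust: bool = False,
) -> tuple[CausalEstimate, StageDiagnostics]:
    """Functional wrapper over :class:`TwoStageLeastSquares`, with strata."""
    mask = _stratum_mask(len(np.asarray(exposure)), sex, stratum)
    x = np.asarray(exposure, dtype=float)[mask]
    y = np.asarray(outcome, dtype=float)[mask]
    z = _score_values(instrument)[mask]
    c = None
    if covariates is not None:
        c = covariates.loc[mask] if isinstance(covariates, pd.DataFrame) else np.asarray(covariates)[mask]
    est = TwoStageLeastSquares(robust=robust).fit(x, y, z, c)
    return est.estimate(stratum=stratum), est.diagnostics_


def wu_hausman(exposure, outcome, instrument, covariates=None) -> float:
    """Control-function test of exposure endogeneity.

    Regress the exposure on instrument + covariates, keep the residual
    r-hat, then regress the outcome on exposure + r-hat + covariates; the
    two-sided p of the r-hat coefficient is returned.  Under exogeneity
    (OLS and IV estimate the same quantity) this p is uniform.
    """
    x = np.asarray(exposure, dtype=float)
    y = np.asarray(outcome, dtype=float)
    z = _score_values(instrument)
    if covariates is None:
        c = np.empty((len(x), 0))
    elif isinstance(covariates, pd.DataFrame):
        c = covariates.to_numpy(float)
    else:
        c = np.atleast_2d(np.asarray(covariates, dtype=float).T).T
    mask = _complete_cases(x, y, z, c)
    x, y, z, c = x[mask], y[mask], z[mask], c[mask]
    n = len(x)
    if np.var(z) <= 0:
        raise ValidationError("instrument is constant")
    ones = np.ones((n, 1))
    zmat = np.column_stack([ones, z] + ([c] if c.size else []))
    gamma, *_ = np.linalg.lstsq(zmat, x, rcond=None)
    r_hat = x - zmat @ gamma
    if np.var(r_hat) <= n * np.finfo(float).eps:
        raise ValidationError("degenerate input: exposure has no residual variance given the instrument")
    design = np.column_stack([ones, x, r_hat] + ([c] if c.size else []))
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    dfree = n - design.shape[1]
    if dfree <= 0:
        raise ValidationError("not enough degrees of freedom for the endogeneity test")
    rss = float(resid @ resid)
    if rss <= n * np.finfo(float).eps:
        raise ValidationError("degenerate input: outcome has no residual variance")
    sigma2 = rss / dfree
    cov = sigma2 * np.linalg.inv(design.T @ design)
    t = coef[2] / np.sqrt(cov[2, 2])
    return float(2 * sps.t.sf(abs(t), dfree))
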