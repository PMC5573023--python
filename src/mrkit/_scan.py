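"""Vectorised per-predictor simple OLS, shared by the GWAS-style scans.

For each column g of a predictor matrix, fits ``trait ~ intercept + g
(+ covariates)`` by the Frisch-Waugh route: both trait and predictors are
residualised on the covariates (plus intercept), then a simple regression is
run per column in closed form.  Coefficients, SEs and p-values are exactly
those of the corresponding full OLS fit.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps


def per_column_ols(
    predictors: np.ndarray,
    trait: np.ndarray,
    covariates: np.ndarray | None = None,
) -> dict[str, np.ndarray]:
    """Per-column OLS of ``trait`` on each predictor column.

    Parameters
    ----------
    predictors : (n, k) array
    trait : (n,) array
    covariates : (n, q) array or None
        Adjustment covariates; an intercept is always included.

    Returns
    -------
    dict with arrays ``beta``, ``se``, ``pval``, ``df`` (scalar df) and the
    boolean mask ``monomorphic`` marking zero-variance predictor columns
    (their estimates are NaN).
    """
    g = np.asarray(predictors, dtype=float)
    y = np.asarray(trait, dtype=float)
    n, k = g.shape
    if covariates is None:
        q = 0
        c = np.ones((n, 1))
    else:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        q = cov.shape[1]
        c = np.column_stack([np.ones(n), cov])

    # residualise on [1, covariates]
    coef_y, *_ = np.linalg.lstsq(c, y, rcond=None)
    yr = y - c @ coef_y
    coef_g, *_ = np.linalg.lstsq(c, g, rcond=None)
    gr = g - c @ coef_g

    sxx = np.einsum("ij,ij->j", gr, gr)
    monomorphic = sxx <= n * np.finfo(float).eps * max(1.0, float(np.max(np.abs(g), initial=1.0)))
    sxx_safe = np.where(monomorphic, np.nan, sxx)

    sxy = gr.T @ yr
    beta = sxy / sxx_safe
    syy = float(yr @ yr)
    rss = syy - beta**2 * sxx_safe
    rss = np.clip(rss, 0.0, None)
    df = n - 2 - q
    if df <= 0:
        raise ValueError(f"not enough residual degrees of freedom (n={n}, covariates={q})")
    sigma2 = rss / df
    se = np.sqrt(sigma2 / sxx_safe)
    with np.errstate(divide="ignore", invalid="ignore"):
        tval = beta / se
    pval = 2.0 * sps.t.sf(np.abs(tval), df)
    return {"beta": beta, "se": se, "pval": pval, "df": df, "monomorphic": monomorphic}
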