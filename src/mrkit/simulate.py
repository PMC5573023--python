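"""Synthetic cohorts with the statistical structure one-sample and
two-sample Mendelian-randomization analyses assume.

The generative model is a linear structural equation system over
independent biallelic SNPs in Hardy-Weinberg equilibrium:

    U   ~ N(0, 1)                                   (shared confounder)
    X   = c * S + cx * U + eps_x                    (exposure, e.g. childhood BMI)
    Y   = theta * X + sum_j alpha_j g_j
          + d * sum_b b_b g_b + cy * U + eps_y      (outcome, SD-scaled trait)
    X2  = theta_reverse * Y + c * S + cx * U + eps  (follow-up exposure)

where S = sum_j w_j g_j is the true weighted allele score over the
exposure panel, alpha_j are direct (pleiotropic) SNP effects on the
outcome carried by a ``prop_invalid`` fraction of panel SNPs, and the
optional background SNPs (zero score weight) give the outcome its own
polygenic component with heritability ``background_h2`` — the
architecture a reverse-direction, split-sample analysis exploits.

The scale factor c is solved in closed form so the true score explains
exactly ``target_r2`` of Var(X) in the population; likewise d for the
background heritability.  Everything is deterministic given the single
integer seed: each operation draws from its own seed-derived substream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .types import (
    PANEL_COLUMNS,
    SUMMARY_COLUMNS,
    ValidationError,
    validate_panel,
)
from ._scan import per_column_ols

_BASES = np.array(list("ACGT"))

# fixed substream tags so one global seed drives all operations reproducibly
_STREAM_PANEL = 11
_STREAM_GENO = 13
_STREAM_TRAITS = 17
_STREAM_BG_PANEL = 19
_STREAM_BG_GENO = 23


@dataclass
class SimulationConfig:
    """Full parameterisation of the generative model.

    Defaults mirror the study design the package targets: a 96-SNP
    exposure panel whose weighted score explains 3% of exposure variance,
    SD-scaled residual noise, and no pleiotropy, confounding or reverse
    causation unless switched on.
    """

    n: int = 5000
    k: int = 96
    maf_range: tuple[float, float] = (0.05, 0.5)
    weight_sd: float = 0.1
    theta: float = 0.0
    theta_reverse: float = 0.0
    confounder_effect_x: float = 0.0
    confounder_effect_y: float = 0.0
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    prop_invalid: float = 0.0
    target_r2: float = 0.03
    noise_sd_x: float = 1.0
    noise_sd_y: float = 1.0
    k_background: int = 0
    background_h2: float = 0.0
    fractional_dosages: bool = False
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValidationError("n must be >= 1")
        if self.k < 1:
            raise ValidationError("k must be >= 1")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValidationError("maf_range must satisfy 0 < low <= high <= 0.5")
        if not 0 <= self.prop_invalid <= 1:
            raise ValidationError("prop_invalid must lie in [0, 1]")
        if not 0 <= self.target_r2 < 1:
            raise ValidationError("target_r2 must lie in [0, 1)")
        if not 0 <= self.background_h2 < 1:
            raise ValidationError("background_h2 must lie in [0, 1)")
        if not 0 <= self.missing_rate < 1:
            raise ValidationError("missing_rate must lie in [0, 1)")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["maf_range"] = list(self.maf_range)
        return d


@dataclass
class Cohort:
    """A simulated sample: dosage matrix plus phenotype/covariate table.

    ``dosages`` is samples x SNPs (entries in [0, 2], NaN only when
    missingness was requested); ``phenotypes`` shares the same index and
    carries ``exposure``, ``outcome``, ``exposure_followup`` and the
    covariates ``sex`` (0/1), ``age``, ``confounder``, ``energy_intake``.
    """

    dosages: pd.DataFrame
    phenotypes: pd.DataFrame

    def __post_init__(self) -> None:
        if len(self.dosages) != len(self.phenotypes):
            raise ValidationError("dosages and phenotypes must have the same number of rows")
        if not self.dosages.index.equals(self.phenotypes.index):
            raise ValidationError("dosages and phenotypes must share their sample index")
        vals = self.dosages.to_numpy(float)
        finite = vals[np.isfinite(vals)]
        if finite.size and (finite.min() < -1e-9 or finite.max() > 2 + 1e-9):
            raise ValidationError("dosages must lie in [0, 2]")

    @property
    def n(self) -> int:
        return len(self.phenotypes)

    @property
    def exposure(self) -> np.ndarray:
        return self.phenotypes["exposure"].to_numpy(float)

    @property
    def outcome(self) -> np.ndarray:
        return self.phenotypes["outcome"].to_numpy(float)

    @property
    def sex(self) -> np.ndarray:
        return self.phenotypes["sex"].to_numpy(int)

    def subset(self, mask: np.ndarray) -> "Cohort":
        return Cohort(self.dosages.loc[mask], self.phenotypes.loc[mask])


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), int(stream)])


def simulate_panel(
    k: int,
    maf_range: tuple[float, float] = (0.05, 0.5),
    weight_sd: float = 0.1,
    seed: int = 0,
    prefix: str = "rs",
    stream: int = _STREAM_PANEL,
) -> pd.DataFrame:
    """Draw a panel of ``k`` independent biallelic SNPs with external weights.

    Effect-allele frequencies are uniform on ``maf_range``; weights are
    drawn N(0, weight_sd^2) and then oriented non-negative (flipping a
    weight's sign corresponds to relabelling which allele is the effect
    allele), so the resulting score counts exposure-increasing alleles.
    """
    if k < 1:
        raise ValidationError("k must be >= 1")
    lo, hi = maf_range
    if not (0 < lo <= hi <= 0.5):
        raise ValidationError("maf_range must satisfy 0 < low <= high <= 0.5")
    rng = _rng(seed, stream)
    eaf = rng.uniform(lo, hi, size=k)
    raw_w = rng.normal(0.0, weight_sd, size=k)
    flip = raw_w < 0
    weight = np.abs(raw_w)
    # the effect allele is the exposure-increasing one: a sign flip swaps
    # the allele labels and reflects the frequency
    allele_idx = rng.choice(4, size=(k, 2))
    # make sure the two alleles differ
    clash = allele_idx[:, 0] == allele_idx[:, 1]
    allele_idx[clash, 1] = (allele_idx[clash, 1] + 1 + rng.integers(0, 3, size=clash.sum())) % 4
    ea = _BASES[allele_idx[:, 0]].copy()
    oa = _BASES[allele_idx[:, 1]].copy()
    ea[flip], oa[flip] = oa[flip], ea[flip].copy()
    eaf = np.where(flip, 1.0 - eaf, eaf)
    panel = pd.DataFrame(
        {
            "snp": [f"{prefix}{i + 1}" for i in range(k)],
            "effect_allele": ea,
            "other_allele": oa,
            "eaf": eaf,
            "weight": weight,
        }
    )
    return validate_panel(panel)


def simulate_genotypes(
    panel: pd.DataFrame,
    n: int,
    seed: int = 0,
    fractional: bool = False,
    missing_rate: float = 0.0,
    stream: int = _STREAM_GENO,
) -> pd.DataFrame:
    """Sample a samples-x-SNPs dosage matrix under Hardy-Weinberg equilibrium.

    Each dosage is Binomial(2, eaf_j).  With ``fractional=True`` a small
    truncated Gaussian perturbation emulates imputed dosages; a positive
    ``missing_rate`` blanks entries completely at random.
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    panel = validate_panel(panel)
    rng = _rng(seed, stream)
    eaf = panel["eaf"].to_numpy(float)
    g = rng.binomial(2, eaf, size=(n, len(eaf))).astype(float)
    if fractional:
        g = np.clip(g + rng.normal(0.0, 0.05, size=g.shape), 0.0, 2.0)
    if missing_rate > 0:
        g[rng.random(g.shape) < missing_rate] = np.nan
    idx = pd.Index([f"s{i + 1:06d}" for i in range(n)], name="sample_id")
    return pd.DataFrame(g, index=idx, columns=panel["snp"].tolist())


def _population_score_variance(weights: np.ndarray, eaf: np.ndarray) -> float:
    """Var of sum_j w_j g_j under HWE with independent SNPs."""
    return float(np.sum(weights**2 * 2.0 * eaf * (1.0 - eaf)))


def simulate_traits(
    dosages: pd.DataFrame,
    panel: pd.DataFrame,
    config: SimulationConfig,
    background_panel: pd.DataFrame | None = None,
) -> Cohort:
    """Generate exposure, outcome and follow-up exposure for given genotypes.

    ``dosages`` must contain every panel SNP as a column; columns of
    ``background_panel`` (if any) supply the outcome's own polygenic
    component.  The score scale c is solved so the true weighted score
    explains ``config.target_r2`` of Var(exposure); the background effect
    scale d is solved analogously against the exact population variance of
    the remaining outcome terms.
    """
    panel = validate_panel(panel)
    snps = panel["snp"].tolist()
    missing_cols = [s for s in snps if s not in dosages.columns]
    if missing_cols:
        raise ValidationError(f"dosage matrix lacks panel SNP(s): {missing_cols[:5]}...")
    rng = _rng(config.seed, _STREAM_TRAITS)
    n = len(dosages)
    g = np.nan_to_num(dosages[snps].to_numpy(float), nan=0.0)
    w = panel["weight"].to_numpy(float)
    eaf = panel["eaf"].to_numpy(float)

    var_s = _population_score_variance(w, eaf)
    cx = config.confounder_effect_x
    cy = config.confounder_effect_y
    if config.target_r2 > 0:
        if var_s <= 0:
            raise ValidationError(
                "target_r2 > 0 is infeasible: the panel's true score has zero variance"
            )
        c = np.sqrt(
            config.target_r2 * (cx**2 + config.noise_sd_x**2) / ((1 - config.target_r2) * var_s)
        )
    else:
        c = 0.0

    u = rng.normal(size=n)
    s_true = g @ w
    exposure = c * s_true + cx * u + config.noise_sd_x * rng.normal(size=n)

    k = len(snps)
    n_invalid = int(round(config.prop_invalid * k))
    alpha = np.zeros(k)
    if n_invalid > 0:
        idx = rng.choice(k, size=n_invalid, replace=False)
        alpha[idx] = rng.normal(config.pleiotropy_mean, config.pleiotropy_sd, size=n_invalid)

    outcome = (
        config.theta * exposure
        + g @ alpha
        + cy * u
        + config.noise_sd_y * rng.normal(size=n)
    )

    if background_panel is not None and len(background_panel) > 0 and config.background_h2 > 0:
        bg = validate_panel(background_panel)
        bg_snps = bg["snp"].tolist()
        missing_bg = [s for s in bg_snps if s not in dosages.columns]
        if missing_bg:
            raise ValidationError(f"dosage matrix lacks background SNP(s): {missing_bg[:5]}...")
        gb = np.nan_to_num(dosages[bg_snps].to_numpy(float), nan=0.0)
        b = rng.normal(size=len(bg_snps))
        var_b = _population_score_variance(b, bg["eaf"].to_numpy(float))
        if var_b <= 0:
            raise ValidationError("background_h2 > 0 is infeasible: zero background variance")
        # exact population variance of the outcome terms other than the
        # background component (independent SNPs, HWE)
        var_x = c**2 * var_s + cx**2 + config.noise_sd_x**2
        het = 2.0 * eaf * (1.0 - eaf)
        var_alpha = float(np.sum(alpha**2 * het))
        cov_s_alpha = float(np.sum(w * alpha * het))
        var_rest = (
            config.theta**2 * var_x
            + var_alpha
            + cy**2
            + config.noise_sd_y**2
            + 2.0 * config.theta * (c * cov_s_alpha + cx * cy)
        )
        d = np.sqrt(config.background_h2 / (1 - config.background_h2) * var_rest / var_b)
        outcome = outcome + d * (gb @ b)

    exposure_followup = (
        config.theta_reverse * outcome
        + c * s_true
        + cx * u
        + config.noise_sd_x * rng.normal(size=n)
    )

    sex = rng.integers(0, 2, size=n)
    phenotypes = pd.DataFrame(
        {
            "exposure": exposure,
            "outcome": outcome,
            "exposure_followup": exposure_followup,
            "sex": sex,
            "age": rng.normal(13.8, 0.3, size=n),
            "confounder": u,
            "energy_intake": 0.3 * exposure + rng.normal(size=n),
        },
        index=dosages.index,
    )
    return Cohort(dosages=dosages, phenotypes=phenotypes)


def simulate_cohort(config: SimulationConfig) -> tuple[pd.DataFrame, Cohort]:
    """End-to-end draw: exposure panel (+ optional background SNPs) and cohort.

    Returns the exposure panel (the score/instrument SNPs) and a cohort
    whose dosage matrix also contains any background SNPs (named
    ``bg*``), which carry no score weight.
    """
    panel = simulate_panel(
        config.k, config.maf_range, config.weight_sd, seed=config.seed, prefix="rs"
    )
    dos = simulate_genotypes(
        panel,
        config.n,
        seed=config.seed,
        fractional=config.fractional_dosages,
        missing_rate=config.missing_rate,
    )
    bg_panel = None
    if config.k_background > 0:
        bg_panel = simulate_panel(
            config.k_background,
            config.maf_range,
            config.weight_sd,
            seed=config.seed,
            prefix="bg",
            stream=_STREAM_BG_PANEL,
        )
        bg_dos = simulate_genotypes(
            bg_panel,
            config.n,
            seed=config.seed,
            fractional=config.fractional_dosages,
            missing_rate=config.missing_rate,
            stream=_STREAM_BG_GENO,
        )
        dos = pd.concat([dos, bg_dos], axis=1)
    cohort = simulate_traits(dos, panel, config, background_panel=bg_panel)
    return panel, cohort


def _one_sided_stats(
    cohort: Cohort, panel: pd.DataFrame, trait: np.ndarray
) -> pd.DataFrame:
    snps = panel["snp"].tolist()
    g = cohort.dosages[snps].to_numpy(float)
    res = per_column_ols(g, trait)
    mono = res["monomorphic"]
    if mono.any():
        dropped = [s for s, m in zip(snps, mono) if m]
        warnings.warn(
            f"excluding {len(dropped)} monomorphic SNP(s) from summary statistics: "
            f"{dropped[:5]}",
            stacklevel=3,
        )
    stats = pd.DataFrame(
        {
            "snp": snps,
            "effect_allele": panel["effect_allele"].to_numpy(),
            "other_allele": panel["other_allele"].to_numpy(),
            "eaf": g.mean(axis=0) / 2.0,
            "beta": res["beta"],
            "se": res["se"],
            "pval": res["pval"],
            "n": cohort.n,
        }
    )
    return stats.loc[~mono].reset_index(drop=True)[SUMMARY_COLUMNS]


def make_summary_stats(
    cohort_a: Cohort,
    cohort_b: Cohort,
    panel: pd.DataFrame,
    exposure_name: str = "exposure",
    outcome_name: str = "outcome",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two-sample GWAS summary statistics from two disjoint cohorts.

    Regresses the exposure on each panel SNP in ``cohort_a`` and the
    outcome on each panel SNP in ``cohort_b`` (simple per-SNP OLS),
    returning a pair of one-sided summary-statistic frames.  Monomorphic
    SNPs are excluded with a warning.
    """
    panel = validate_panel(panel)
    exp_stats = _one_sided_stats(
        cohort_a, panel, cohort_a.phenotypes[exposure_name].to_numpy(float)
    )
    out_stats = _one_sided_stats(
        cohort_b, panel, cohort_b.phenotypes[outcome_name].to_numpy(float)
    )
    return exp_stats, out_stats
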