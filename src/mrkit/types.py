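"""Shared dataclasses and validation helpers.

A variant panel is a :class:`pandas.DataFrame` with columns
``snp, effect_allele, other_allele, eaf, weight``; one-sided GWAS summary
statistics use columns ``snp, effect_allele, other_allele, eaf, beta, se,
pval, n``.  Harmonized (two-sided) summary statistics carry an ``_exp`` /
``_out`` suffixed pair of effect columns.  Frames rather than bespoke
containers keep everything trivially serialisable as TSV.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

VALID_BASES = frozenset("ACGT")

PANEL_COLUMNS = ["snp", "effect_allele", "other_allele", "eaf", "weight"]
SUMMARY_COLUMNS = ["snp", "effect_allele", "other_allele", "eaf", "beta", "se", "pval", "n"]


class ValidationError(ValueError):
    """Raised when an input violates a documented invariant."""


def validate_panel(panel: pd.DataFrame, require_nonnegative_weights: bool = False) -> pd.DataFrame:
    """Validate a variant panel frame and return it (column-ordered).

    Checks: required columns present, SNP ids unique, alleles are single
    A/C/G/T bases, effect allele differs from the other allele, and EAF
    lies in [0, 1].
    """
    missing = [c for c in PANEL_COLUMNS if c not in panel.columns]
    if missing:
        raise ValidationError(f"panel is missing required column(s): {missing}")
    if panel["snp"].duplicated().any():
        dups = panel.loc[panel["snp"].duplicated(), "snp"].tolist()
        raise ValidationError(f"duplicate SNP id(s) in panel: {dups}")
    for col in ("effect_allele", "other_allele"):
        bad = ~panel[col].astype(str).str.upper().isin(VALID_BASES)
        if bad.any():
            raise ValidationError(
                f"invalid base(s) in column {col!r}: {panel.loc[bad, col].unique().tolist()}"
            )
    same = panel["effect_allele"].str.upper() == panel["other_allele"].str.upper()
    if same.any():
        raise ValidationError(
            f"effect_allele equals other_allele for SNP(s): {panel.loc[same, 'snp'].tolist()}"
        )
    eaf = panel["eaf"].to_numpy(float)
    if np.any((eaf < 0) | (eaf > 1)) or np.any(~np.isfinite(eaf)):
        raise ValidationError("eaf values must lie in [0, 1]")
    if require_nonnegative_weights and (panel["weight"].to_numpy(float) < 0).any():
        raise ValidationError("panel weights must be non-negative for score construction")
    out = panel.copy()
    out["effect_allele"] = out["effect_allele"].str.upper()
    out["other_allele"] = out["other_allele"].str.upper()
    return out[PANEL_COLUMNS + [c for c in panel.columns if c not in PANEL_COLUMNS]]


def validate_summary_stats(stats: pd.DataFrame) -> pd.DataFrame:
    """Validate a one-sided summary-statistics frame (uppercases alleles)."""
    required = ["snp", "effect_allele", "other_allele", "beta", "se"]
    missing = [c for c in required if c not in stats.columns]
    if missing:
        raise ValidationError(f"summary statistics missing required column(s): {missing}")
    if stats["snp"].duplicated().any():
        dups = stats.loc[stats["snp"].duplicated(), "snp"].tolist()
        raise ValidationError(f"duplicate SNP id(s): {dups}")
    out = stats.copy()
    for col in ("effect_allele", "other_allele"):
        out[col] = out[col].astype(str).str.upper()
        bad = ~out[col].isin(VALID_BASES)
        if bad.any():
            raise ValidationError(
                f"invalid base(s) in column {col!r}: {stats.loc[bad, col].unique().tolist()}"
            )
    se = out["se"].to_numpy(float)
    if np.any(~np.isfinite(se)) or np.any(se <= 0):
        raise ValidationError("standard errors must be strictly positive and finite")
    if "eaf" in out.columns:
        eaf = out["eaf"].to_numpy(float)
        if np.any((eaf < 0) | (eaf > 1)):
            raise ValidationError("eaf values must lie in [0, 1]")
    return out


@dataclass
class ScoreVector:
    """A per-sample weighted allelic score.

    ``values`` lives on the average-effect-allele-count scale [0, 2k]:
    a sample's score is k * (sum_j w_j g_ij) / (sum_j w_j).
    """

    values: np.ndarray
    n_snps_used: int
    normalization_constant: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.n_snps_used < 1:
            raise ValidationError("score must use at least one SNP")
        hi = 2.0 * self.n_snps_used
        if np.any(self.values < -1e-9) or np.any(self.values > hi + 1e-9):
            raise ValidationError(f"score values must lie in [0, {hi}]")

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class AssociationRecord:
    """An OLS association summary for one variable (slope per score allele)."""

    variable: str
    beta: float
    ci_low: float
    ci_high: float
    p: float
    r2: float
    n: int
    r2_incremental: float | None = None
    flagged: bool = False


@dataclass
class CausalEstimate:
    """A point estimate of a causal effect with its uncertainty."""

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    p: float
    n: int
    stratum: str = "all"
    notes: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class StageDiagnostics:
    """First-stage strength and endogeneity diagnostics for 2SLS."""

    f_stat: float
    r2_first: float
    wu_hausman_p: float | None = None
    weak_instrument: bool = False


@dataclass
class MRResult:
    """Result of a summary-level MR estimator.

    The intercept block is populated only by MR-Egger; the heterogeneity
    block (Cochran's Q for IVW, Rucker's Q' for Egger) is populated where
    the estimator defines one.
    """

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    p: float
    k_snps: int
    intercept: float | None = None
    intercept_se: float | None = None
    intercept_p: float | None = None
    q_stat: float | None = None
    q_df: int | None = None
    q_p: float | None = None
    notes: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SplitPlan:
    """A balanced random A/B partition of a cohort."""

    seed: int
    assignment: np.ndarray  # array of "A"/"B", length n

    def __post_init__(self) -> None:
        self.assignment = np.asarray(self.assignment)
        n_a, n_b = self.n_a, self.n_b
        if abs(n_a - n_b) > 1:
            raise ValidationError("split must be balanced to within one sample")

    @property
    def n_a(self) -> int:
        return int(np.sum(self.assignment == "A"))

    @property
    def n_b(self) -> int:
        return int(np.sum(self.assignment == "B"))

    def mask(self, label: str) -> np.ndarray:
        return self.assignment == label


@dataclass
class PredictionScoreSpec:
    """Which SNPs a genome-wide prediction score uses, and with what weights."""

    selected_snps: pd.DataFrame  # columns: snp, weight (scan beta, trait-increasing), pval
    p_threshold: float
    exclusion_list: Sequence[str]

    def __post_init__(self) -> None:
        excl = set(self.exclusion_list)
        overlap = set(self.selected_snps["snp"]) & excl
        if overlap:
            raise ValidationError(f"selected SNPs overlap the exclusion list: {sorted(overlap)}")
        if (self.selected_snps["pval"] > self.p_threshold).any():
            raise ValidationError("a selected SNP exceeds the selection p threshold")
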