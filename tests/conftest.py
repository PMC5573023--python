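import numpy as np
import pandas as pd
import pytest

from mrkit import SimulationConfig, simulate_cohort


@pytest.fixture
def small_panel() -> pd.DataFrame:
    """Five-SNP hand-built panel with non-negative weights."""
    return pd.DataFrame(
        {
            "snp": ["rs1", "rs2", "rs3", "rs4", "rs5"],
            "effect_allele": ["A", "C", "G", "T", "A"],
            "other_allele": ["G", "T", "A", "C", "C"],
            "eaf": [0.1, 0.25, 0.4, 0.5, 0.33],
            "weight": [0.10, 0.30, 0.05, 0.20, 0.15],
        }
    )


@pytest.fixture(scope="session")
def causal_cohort():
    """One moderately sized cohort with a true effect and confounding."""
    cfg = SimulationConfig(
        n=4000,
        k=96,
        theta=0.3,
        target_r2=0.03,
        confounder_effect_x=0.5,
        confounder_effect_y=0.5,
        seed=42,
    )
    panel, cohort = simulate_cohort(cfg)
    return cfg, panel, cohort


@pytest.fixture
def harmonized_fixture() -> pd.DataFrame:
    """Two-sided summary stats lying exactly on a line through the origin."""
    return pd.DataFrame(
        {
            "snp": ["rs1", "rs2", "rs3", "rs4"],
            "beta_exp": [0.1, 0.2, 0.15, 0.05],
            "se_exp": [0.01, 0.01, 0.01, 0.01],
            "beta_out": [0.03, 0.06, 0.045, 0.015],
            "se_out": [0.01, 0.02, 0.015, 0.01],
        }
    )


def ols_oracle(design: np.ndarray, y: np.ndarray):
    """Closed-form normal-equations OLS: coefficients and classical SEs."""
    xtx = design.T @ design
    beta = np.linalg.solve(xtx, design.T @ y)
    resid = y - design @ beta
    sigma2 = resid @ resid / (len(y) - design.shape[1])
    cov = sigma2 * np.linalg.inv(xtx)
    return beta, np.sqrt(np.diag(cov))
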