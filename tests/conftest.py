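import numpy as np
import pandas as pd
import pytest

from dimorphscan.synthetic_data import SimConfig, simulate_sumstats


@pytest.fixture(scope="session")
def small_sim():
    """A small two-study simulation with one planted women-specific SNP."""
    cfg = SimConfig(
        n_studies=2,
        n_men=2000,
        n_women=2500,
        n_snps=300,
        class_counts={"NULL": 299, "SSE_F": 1, "SSE_M": 0, "CED": 0, "OED": 0},
        seed=11,
    )
    return simulate_sumstats(cfg)


@pytest.fixture()
def sumstats_frame():
    """A tiny well-formed summary-statistic table."""
    return pd.DataFrame(
        {
            "SNP": ["rs1", "rs2", "rs3"],
            "CHR": [1, 1, 2],
            "POS": [1000, 2000, 1500],
            "EFFECT_ALLELE": ["A", "C", "G"],
            "OTHER_ALLELE": ["G", "T", "A"],
            "EAF": [0.30, 0.45, 0.10],
            "BETA": [0.10, -0.05, 0.02],
            "SE": [0.05, 0.04, 0.06],
            "P": [0.0455, 0.2113, 0.7389],
            "N": [1000, 1000, 1000],
            "QUALITY": [0.95, 0.80, 0.99],
            "PLATFORM": ["MACH", "MACH", "MACH"],
        }
    )


def make_meta_long(
    rng: np.random.Generator,
    true_m: np.ndarray,
    true_w: np.ndarray,
    se_m: float,
    se_w: float,
    phenotype: str = "WHRadjBMI",
) -> pd.DataFrame:
    """Meta-level long table with independent normal sampling noise."""
    from scipy import stats

    n = true_m.size
    frames = []
    for sex, truth, se in (("M", true_m, se_m), ("W", true_w, se_w)):
        beta = truth + rng.normal(0.0, se, n)
        frames.append(
            pd.DataFrame(
                {
                    "SNP": [f"rs{i}" for i in range(n)],
                    "PHENOTYPE": phenotype,
                    "SEX": sex,
                    "CHR": 1 + (np.arange(n) * 22) // n,
                    "POS": (np.arange(n) + 1) * 500_000,
                    "BETA": beta,
                    "SE": se,
                    "P": 2 * stats.norm.sf(np.abs(beta / se)),
                    "N": 10_000,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
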