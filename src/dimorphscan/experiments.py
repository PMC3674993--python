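"""End-to-end simulation experiments for calibration and power checks.

These functions wire the pipeline stages together under controlled
generative conditions: a global-null calibration of the sex-difference
test, a discovery->follow-up experiment measuring the realized false
confirmation proportion under winner's-curse selection, and a
planted-signal experiment comparing the pipeline's empirical selection
and confirmation frequencies with the analytic power module.

Problem sizes are kept at desk scale (thousands of SNPs, hundreds of
replicates); every function takes a seed and is exactly reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .dimorphism import sexdiff_test
from .meta_analysis import meta_analyze_studies
from .power_bias import PowerDesign, power_scan, power_two_stage
from .screening import followup_confirm, sex_specific_scan

__all__ = [
    "null_sexdiff_pvalues",
    "ConfirmationFdrResult",
    "confirmation_fdr_experiment",
    "PlantedSseResult",
    "planted_sse_experiment",
]


def null_sexdiff_pvalues(n_snps: int = 100_000, seed: int = 0) -> np.ndarray:
    """Two-sided sex-difference p-values under a global null, r = 0.

    Independent per-sex estimates with heterogeneous standard errors and
    no true effects; the returned p-values should be uniform.
    """
    rng = np.random.default_rng(seed)
    se_m = rng.uniform(0.01, 0.05, size=n_snps)
    se_w = rng.uniform(0.01, 0.05, size=n_snps)
    b_m = rng.normal(0.0, se_m)
    b_w = rng.normal(0.0, se_w)
    _, p_two, _ = sexdiff_test(b_m, se_m, b_w, se_w, r=0.0)
    return p_two


@dataclass
class ConfirmationFdrResult:
    n_runs: int
    total_confirmed: int
    false_confirmed: int
    fdp: float  # pooled false-confirmation proportion
    fdp_se: float  # binomial SE of the pooled proportion at rate 0.05
    null_followup_p_two: np.ndarray  # among tested null-difference SNPs


def confirmation_fdr_experiment(
    n_runs: int = 500,
    seed: int = 0,
    fdr: float = 0.05,
    main_effect_p: float = 0.01,
) -> ConfirmationFdrResult:
    """Realized false-confirmation rate under biased discovery selection.

    Each run simulates a pool of SNPs containing women-specific signals
    (true sex-difference), equal-effect signals in both sexes (true
    association, *null* difference) and pure nulls.  Candidates are
    selected the biased way — on the smallest sex-specific discovery
    p-value plus a nominal discovery sex-difference filter, which
    inflates the discovery difference statistics of the selected set —
    and then confirmed with :func:`followup_confirm` on independent
    follow-up draws.  Pooled over runs, the proportion of confirmed
    SNPs whose true sex-difference is null estimates the realized
    confirmation-stage FDR, which Benjamini-Hochberg should hold at or
    below the nominal level.  The follow-up difference p-values of the
    tested null-difference SNPs are also returned: despite the biased
    selection they should be uniform, because the follow-up data are
    independent of discovery.
    """
    rng = np.random.default_rng(seed)
    n_sse, n_ced, n_null = 10, 20, 100
    beta_sse_w, beta_ced = 0.08, 0.06
    se_m_d, se_w_d = 0.016, 0.015  # discovery meta SEs
    se_m_f, se_w_f = 0.016, 0.015  # follow-up meta SEs

    n = n_sse + n_ced + n_null
    true_w = np.concatenate(
        [np.full(n_sse, beta_sse_w), np.full(n_ced, beta_ced), np.zeros(n_null)]
    )
    true_m = np.concatenate(
        [np.zeros(n_sse), np.full(n_ced, beta_ced), np.zeros(n_null)]
    )
    null_diff = true_m == true_w  # CED-equal and pure nulls
    snps = np.array([f"rs{i}" for i in range(n)])

    total_confirmed = 0
    false_confirmed = 0
    null_fu_p: list[np.ndarray] = []
    for _ in range(n_runs):
        bm_d = true_m + rng.normal(0.0, se_m_d, n)
        bw_d = true_w + rng.normal(0.0, se_w_d, n)
        p_m = 2 * stats.norm.sf(np.abs(bm_d / se_m_d))
        p_w = 2 * stats.norm.sf(np.abs(bw_d / se_w_d))
        _, pdiff_d, _ = sexdiff_test(bm_d, se_m_d, bw_d, se_w_d)
        selected = (np.minimum(p_m, p_w) < 1e-4) & (pdiff_d < 0.05)
        if not selected.any():
            continue

        def _long(bm, sm, bw, sw):
            frames = []
            for sex, b, s in (("M", bm, sm), ("W", bw, sw)):
                frames.append(
                    pd.DataFrame(
                        {
                            "SNP": snps,
                            "PHENOTYPE": "WHRadjBMI",
                            "SEX": sex,
                            "CHR": 1,
                            "POS": np.arange(n),
                            "BETA": b,
                            "SE": s,
                            "P": 2 * stats.norm.sf(np.abs(b / s)),
                            "N": 40_000,
                        }
                    )
                )
            return pd.concat(frames, ignore_index=True)

        disc_long = _long(bm_d, np.full(n, se_m_d), bw_d, np.full(n, se_w_d))
        bm_f = true_m + rng.normal(0.0, se_m_f, n)
        bw_f = true_w + rng.normal(0.0, se_w_f, n)
        fu_long = _long(bm_f, np.full(n, se_m_f), bw_f, np.full(n, se_w_f))
        candidates = pd.DataFrame(
            {"SNP": snps[selected], "PHENOTYPE": "WHRadjBMI"}
        )
        report = followup_confirm(
            candidates,
            disc_long,
            fu_long,
            main_effect_p=main_effect_p,
            fdr=fdr,
        )
        confirmed_snps = report.table.loc[report.table["CONFIRMED"], "SNP"]
        is_null = pd.Series(null_diff, index=snps)
        total_confirmed += len(confirmed_snps)
        false_confirmed += int(is_null.loc[confirmed_snps].sum())
        tested_null = report.table.loc[
            is_null.loc[report.table["SNP"]].to_numpy(), "T_DIFF_FU"
        ]
        if len(tested_null):
            null_fu_p.append(2 * stats.norm.sf(np.abs(tested_null.to_numpy())))

    fdp = false_confirmed / total_confirmed if total_confirmed else 0.0
    fdp_se = (
        np.sqrt(fdr * (1 - fdr) / total_confirmed) if total_confirmed else np.nan
    )
    return ConfirmationFdrResult(
        n_runs=n_runs,
        total_confirmed=total_confirmed,
        false_confirmed=false_confirmed,
        fdp=fdp,
        fdp_se=float(fdp_se),
        null_followup_p_two=(
            np.concatenate(null_fu_p) if null_fu_p else np.array([])
        ),
    )


@dataclass
class PlantedSseResult:
    n_seeds: int
    selection_freq: float  # planted SNP among scan candidates
    confirm_freq: float  # planted SNP confirmed (unconditional)
    predicted_selection: float  # analytic, scan power x P-diff filter
    predicted_confirm: float  # analytic two-stage (x selection)
    mc_se_selection: float
    mc_se_confirm: float


# per-study sample sizes for the planted-signal experiment; two studies
# per sex per stage give meta samples of 16,000 men / 10,000 women
_N_MEN_STUDY, _N_WOMEN_STUDY, _N_STUDIES = 8000, 5000, 2
_MAF_PLANTED = 0.42
# women-specific standardized effect sized for ~90% power at the
# concatenated panel's BH cut-off (fdr/m with m = 2 sexes x panel SNPs)
_BETA_PLANTED_W = 0.0786


def _study_tables(
    rng: np.random.Generator,
    true_beta: np.ndarray,
    maf: np.ndarray,
    n_ind: int,
    n_studies: int,
) -> list[pd.DataFrame]:
    n = true_beta.size
    tables = []
    for _ in range(n_studies):
        se = 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * n_ind)
        beta_hat = true_beta + rng.normal(0.0, se)
        tables.append(
            pd.DataFrame(
                {
                    "SNP": [f"rs{i}" for i in range(n)],
                    "CHR": 1 + (np.arange(n) * 22) // n,
                    "POS": (np.arange(n) % (n // 22 + 1) + 1) * 600_000,
                    "BETA": beta_hat,
                    "SE": se,
                    "N": n_ind,
                }
            )
        )
    return tables


def _meta_long(rng, true_m, true_w, maf) -> pd.DataFrame:
    frames = []
    for sex, truth, n_ind in (
        ("M", true_m, _N_MEN_STUDY),
        ("W", true_w, _N_WOMEN_STUDY),
    ):
        meta = meta_analyze_studies(
            _study_tables(rng, truth, maf, n_ind, _N_STUDIES)
        )
        meta["SEX"] = sex
        meta["PHENOTYPE"] = "WHRadjBMI"
        frames.append(meta)
    return pd.concat(frames, ignore_index=True)


def planted_sse_experiment(
    n_seeds: int = 200,
    seed: int = 0,
    n_snps: int = 1000,
    fdr: float = 0.05,
    main_effect_p: float = 0.01,
) -> PlantedSseResult:
    """Recovery of one planted women-specific signal by the full pipeline.

    Each replicate simulates ``n_snps`` SNPs (one planted SSE_F, the
    rest null) across two discovery studies per sex, meta-analyzes,
    runs the sex-specific scan (FDR over the concatenated two-sex
    panel, pruning, nominal sex-difference filter) and confirms the
    candidates in an independently simulated follow-up (main-effect
    filter on follow-up data, one-sided difference test, BH).

    The empirical selection frequency is compared with the analytic
    prediction: scan power at the panel's leading-order BH cut-off
    (fdr/m) times the probability of passing the nominal difference
    filter; confirmation multiplies the two-stage confirmation power.
    Both treat the selection and filter events as independent, which is
    accurate when each marginal probability is near one.
    """
    maf = np.full(n_snps, _MAF_PLANTED)
    true_w = np.zeros(n_snps)
    true_m = np.zeros(n_snps)
    planted = n_snps // 2
    true_w[planted] = _BETA_PLANTED_W
    planted_snp = f"rs{planted}"

    n_men_meta = _N_MEN_STUDY * _N_STUDIES
    n_women_meta = _N_WOMEN_STUDY * _N_STUDIES
    alpha_eff = fdr / (2 * n_snps)
    design_disc = PowerDesign(
        n_men=n_men_meta,
        n_women=n_women_meta,
        maf=_MAF_PLANTED,
        beta_men=0.0,
        beta_women=_BETA_PLANTED_W,
        alpha=alpha_eff,
    )
    p_scan = power_scan(design_disc, "sex_specific")
    p_filter = power_scan(
        PowerDesign(
            n_men_meta, n_women_meta, _MAF_PLANTED, 0.0, _BETA_PLANTED_W,
            alpha=0.05,
        ),
        "sex_difference",
    )
    predicted_selection = p_scan * p_filter
    p_confirm = power_two_stage(
        PowerDesign(
            n_men_meta, n_women_meta, _MAF_PLANTED, 0.0, _BETA_PLANTED_W
        ),
        main_effect_alpha=main_effect_p,
        diff_threshold=fdr,  # BH over a single surviving candidate
    )
    predicted_confirm = predicted_selection * p_confirm

    gmap = pd.DataFrame(
        {
            "CHR": np.repeat(np.arange(1, 23), 2),
            "POS": np.tile([0, 130_000_000], 22),
            "CM": np.tile([0.0, 130.0], 22),
        }
    )

    n_selected = 0
    n_confirmed = 0
    rng = np.random.default_rng(seed)
    for _ in range(n_seeds):
        meta_long = _meta_long(rng, true_m, true_w, maf)
        scan = sex_specific_scan(
            meta_long, gmap, fdr=fdr, pdiff_filter=0.05, r_by_phenotype=0.0
        )
        selected = planted_snp in set(scan.candidates["SNP"])
        if not selected:
            continue
        n_selected += 1
        fu_long = _meta_long(rng, true_m, true_w, maf)
        report = followup_confirm(
            scan.candidates[["SNP", "PHENOTYPE"]],
            meta_long,
            fu_long,
            main_effect_p=main_effect_p,
            fdr=fdr,
            main_effect_stage="followup",
        )
        confirmed = set(report.table.loc[report.table["CONFIRMED"], "SNP"])
        if planted_snp in confirmed:
            n_confirmed += 1

    return PlantedSseResult(
        n_seeds=n_seeds,
        selection_freq=n_selected / n_seeds,
        confirm_freq=n_confirmed / n_seeds,
        predicted_selection=predicted_selection,
        predicted_confirm=predicted_confirm,
        mc_se_selection=float(
            np.sqrt(predicted_selection * (1 - predicted_selection) / n_seeds)
        ),
        mc_se_confirm=float(
            np.sqrt(predicted_confirm * (1 - predicted_confirm) / n_seeds)
        ),
    )
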