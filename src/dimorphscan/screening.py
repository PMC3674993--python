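"""Genome-wide scans, FDR selection, cM pruning and follow-up confirmation.

Two discovery scans are supported:

* the *sex-specific scan* concatenates the per-sex association p-values
  of every SNP across all phenotypes and both sexes and selects at an
  FDR level, then prunes to independent SNPs by genetic distance and
  keeps those with a nominally significant sex-difference;
* the *sex-difference scan* concatenates the between-sex difference
  p-values across phenotypes and selects at the same FDR level.

Because the discovery selection conditions on sex-specific association,
sex-difference estimates in the discovery data are inflated (winner's
curse).  The confirmation stage therefore filters candidates on a
sex-combined "main effect" — a contrast orthogonal to the difference —
and tests the sex-difference in the independent follow-up data alone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .dimorphism import classify_dimorphism, sexdiff_test

logger = logging.getLogger(__name__)

__all__ = [
    "GeneticMap",
    "ScanReport",
    "ConfirmationReport",
    "bh_fdr",
    "interpolate_cm",
    "prune_independent",
    "sex_specific_scan",
    "sex_difference_scan",
    "followup_confirm",
    "confirm_from_pvalues",
    "declare_gws",
]


def bh_fdr(pvalues, alpha: float = 0.05) -> tuple[np.ndarray, int, float | None]:
    """Benjamini-Hochberg step-up selection.

    Rejects the k hypotheses with the smallest p-values, where k is the
    largest index with p_(k) <= k * alpha / m.  Returns
    ``(reject_flags, k, critical_p)`` with critical_p the largest
    rejected p-value (None when k = 0).
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("bh_fdr requires at least one p-value")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0,1)")
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0,1]")
    reject = multipletests(p, alpha=alpha, method="fdr_bh")[0]
    k = int(reject.sum())
    critical = float(p[reject].max()) if k else None
    return reject, k, critical


class GeneticMap:
    """cM lookup by inverse-distance interpolation of map points.

    A query between two map points on the same chromosome receives the
    inverse-distance weighted average of the flanking genetic positions
    (equivalently, linear interpolation in bp).  A query at a map point
    returns that point's cM exactly; a query outside the mapped span
    takes the nearest point's cM with a logged warning.
    """

    def __init__(self, map_df: pd.DataFrame):
        self._by_chrom: dict = {}
        for chrom, grp in map_df.groupby("CHR"):
            grp = grp.sort_values("POS")
            self._by_chrom[chrom] = (
                grp["POS"].to_numpy(dtype=float),
                grp["CM"].to_numpy(dtype=float),
            )

    def interpolate(self, chrom, bp) -> np.ndarray:
        if chrom not in self._by_chrom:
            raise KeyError(f"no map points for chromosome {chrom!r}")
        pos, cm = self._by_chrom[chrom]
        bp = np.atleast_1d(np.asarray(bp, dtype=float))
        out = np.empty_like(bp)
        idx = np.searchsorted(pos, bp)  # side="left"
        exact = (idx < pos.size) & (pos[np.minimum(idx, pos.size - 1)] == bp)
        out[exact] = cm[idx[exact]]
        below = (idx == 0) & ~exact
        above = idx == pos.size
        if below.any() or above.any():
            logger.warning(
                "%d position(s) outside the map span of chromosome %s; "
                "using nearest map point",
                int(below.sum() + above.sum()),
                chrom,
            )
        out[below] = cm[0]
        out[above] = cm[-1]
        interp = ~(exact | below | above)
        ii = idx[interp]
        d_l = bp[interp] - pos[ii - 1]
        d_r = pos[ii] - bp[interp]
        out[interp] = (cm[ii - 1] / d_l + cm[ii] / d_r) / (1.0 / d_l + 1.0 / d_r)
        return out


def interpolate_cm(bp, map_df: pd.DataFrame, chrom=None) -> np.ndarray:
    """Interpolate genetic positions for bp coordinates on one chromosome."""
    if chrom is None:
        chroms = map_df["CHR"].unique()
        if chroms.size != 1:
            raise ValueError("map covers several chromosomes; pass chrom=")
        chrom = chroms[0]
    return GeneticMap(map_df).interpolate(chrom, bp)


def prune_independent(
    candidates: pd.DataFrame, window_cm: float = 0.2
) -> tuple[pd.DataFrame, list[str]]:
    """Greedy pruning of candidate SNPs to an independent set.

    Sweeps candidates in order of increasing p-value; a SNP is deleted
    when it lies within ``window_cm`` (same chromosome) of any
    already-retained SNP.  Requires columns SNP, CHR, CM and P.  Returns
    the retained rows and a log of pruning decisions.
    """
    missing_cm = candidates["CM"].isna()
    if missing_cm.any():
        raise ValueError(
            "missing cM for SNP(s): "
            + ", ".join(candidates.loc[missing_cm, "SNP"].astype(str))
        )
    ordered = candidates.sort_values(
        ["P", "SNP"], kind="mergesort"
    ).reset_index(drop=True)
    retained_idx: list[int] = []
    kept: dict = {}
    log: list[str] = []
    for i in range(len(ordered)):
        chrom = ordered.at[i, "CHR"]
        cm = ordered.at[i, "CM"]
        near = kept.get(chrom)
        if near is not None and np.any(np.abs(np.asarray(near) - cm) < window_cm):
            log.append(
                f"pruned {ordered.at[i, 'SNP']} (chr{chrom} {cm:.3f} cM, "
                f"p={ordered.at[i, 'P']:.3g})"
            )
            continue
        retained_idx.append(i)
        kept.setdefault(chrom, []).append(cm)
    return ordered.loc[retained_idx].reset_index(drop=True), log


@dataclass
class ScanReport:
    """Outcome of one genome-wide selection scan."""

    scan_type: str
    fdr_level: float
    m: int  # concatenated test count
    k: int  # rejected count
    critical_p: float | None
    selected: pd.DataFrame  # all rejected (SNP, phenotype[, sex]) tests
    independent: pd.DataFrame  # after best-assignment and cM pruning
    candidates: pd.DataFrame  # after the P-diff filter (sex-specific scan)
    r_used: dict = field(default_factory=dict)
    pruning_log: list = field(default_factory=list)


def _pivot_sexes(meta_long: pd.DataFrame) -> pd.DataFrame:
    """Wide per-(SNP, phenotype) frame with _M and _W suffixed columns."""
    cols = ["SNP", "PHENOTYPE", "CHR", "POS", "BETA", "SE", "P", "N"]
    men = meta_long.loc[meta_long["SEX"] == "M", cols]
    women = meta_long.loc[meta_long["SEX"] == "W", cols]
    return men.merge(
        women,
        on=["SNP", "PHENOTYPE", "CHR", "POS"],
        suffixes=("_M", "_W"),
        how="inner",
    )


def _estimate_r_per_phenotype(meta_long: pd.DataFrame) -> dict[str, float]:
    from .dimorphism import estimate_beta_correlation

    out: dict[str, float] = {}
    for pheno, grp in _pivot_sexes(meta_long).groupby("PHENOTYPE"):
        est = estimate_beta_correlation(
            grp["BETA_M"], grp["BETA_W"], phenotype=pheno
        )
        out[pheno] = est.r
    return out


def _resolve_r(meta_long, r_by_phenotype) -> dict[str, float]:
    if r_by_phenotype == "auto" or r_by_phenotype is None:
        return _estimate_r_per_phenotype(meta_long)
    if isinstance(r_by_phenotype, dict):
        return r_by_phenotype
    return {p: float(r_by_phenotype) for p in meta_long["PHENOTYPE"].unique()}


def sex_specific_scan(
    meta_long: pd.DataFrame,
    genetic_map: GeneticMap | pd.DataFrame,
    fdr: float = 0.05,
    pdiff_filter: float = 0.05,
    prune_cm: float = 0.2,
    r_by_phenotype="auto",
) -> ScanReport:
    """Scan the per-sex association p-values across all phenotypes.

    Concatenates every (SNP, phenotype, sex) p-value, selects at
    ``fdr`` by Benjamini-Hochberg, assigns each surviving SNP its single
    best (phenotype, sex) pair (other hits recorded as secondary),
    prunes to independent SNPs by genetic distance, and finally keeps
    SNPs whose discovery sex-difference for the assigned phenotype is
    nominally significant (``pdiff_filter``) — a rough guard that
    follow-up effort is spent on plausibly dimorphic signals.

    ``meta_long`` needs columns SNP, PHENOTYPE, SEX, CHR, POS, BETA, SE,
    P, N with SEX coded "M"/"W".
    """
    if isinstance(genetic_map, pd.DataFrame):
        genetic_map = GeneticMap(genetic_map)
    reject, k, critical = bh_fdr(meta_long["P"].to_numpy(), fdr)
    selected = meta_long.loc[reject].copy()
    m = len(meta_long)
    empty = selected.iloc[0:0]
    if selected.empty:
        return ScanReport("sex_specific", fdr, m, 0, None, selected, empty, empty)

    # single best (phenotype, sex) per SNP; the rest become secondary hits
    best = (
        selected.sort_values(["P", "PHENOTYPE", "SEX"], kind="mergesort")
        .groupby("SNP", sort=False)
        .first()
        .reset_index()
    )
    secondary = selected.merge(
        best[["SNP", "PHENOTYPE", "SEX"]],
        on=["SNP", "PHENOTYPE", "SEX"],
        how="left",
        indicator=True,
    )
    best["SECONDARY_HITS"] = (
        secondary.loc[secondary["_merge"] == "left_only"]
        .groupby("SNP")
        .size()
        .reindex(best["SNP"], fill_value=0)
        .to_numpy()
    )
    best = best.sort_values(["CHR", "POS"]).reset_index(drop=True)
    cms = []
    for chrom, grp in best.groupby("CHR", sort=False):
        cms.append(genetic_map.interpolate(chrom, grp["POS"].to_numpy()))
    best["CM"] = np.concatenate(cms) if cms else np.array([])

    independent, log = prune_independent(best, window_cm=prune_cm)

    r_used = _resolve_r(meta_long, r_by_phenotype)
    wide = _pivot_sexes(meta_long)
    cand = independent.merge(
        wide[["SNP", "PHENOTYPE", "BETA_M", "SE_M", "BETA_W", "SE_W"]],
        on=["SNP", "PHENOTYPE"],
        how="left",
    )
    r_vec = cand["PHENOTYPE"].map(r_used).fillna(0.0).to_numpy()
    t = np.full(len(cand), np.nan)
    p_diff = np.full(len(cand), np.nan)
    have = cand["BETA_M"].notna() & cand["BETA_W"].notna()
    if have.any():
        tt, pp, _ = sexdiff_test(
            cand.loc[have, "BETA_M"].to_numpy(),
            cand.loc[have, "SE_M"].to_numpy(),
            cand.loc[have, "BETA_W"].to_numpy(),
            cand.loc[have, "SE_W"].to_numpy(),
            r=np.asarray(r_vec)[have.to_numpy()],
            ref_sign=1.0,
        )
        t[have.to_numpy()] = np.atleast_1d(tt)
        p_diff[have.to_numpy()] = np.atleast_1d(pp)
    cand["T_DIFF"] = t
    cand["P_DIFF"] = p_diff
    candidates = cand.loc[cand["P_DIFF"] < pdiff_filter].reset_index(drop=True)
    return ScanReport(
        scan_type="sex_specific",
        fdr_level=fdr,
        m=m,
        k=k,
        critical_p=critical,
        selected=selected.reset_index(drop=True),
        independent=cand,
        candidates=candidates,
        r_used=r_used,
        pruning_log=log,
    )


def sex_difference_scan(
    meta_long: pd.DataFrame,
    genetic_map: GeneticMap | pd.DataFrame,
    fdr: float = 0.05,
    prune_cm: float = 0.2,
    r_by_phenotype="auto",
) -> ScanReport:
    """Scan the between-sex difference p-values across all phenotypes.

    Computes the correlation-corrected difference test for every
    (SNP, phenotype) with both sexes available, concatenates the
    two-sided p-values over phenotypes, selects at ``fdr`` and prunes.
    This scan is the one with power against opposite-effect-direction
    signals, which the sex-specific scan handles poorly.
    """
    if isinstance(genetic_map, pd.DataFrame):
        genetic_map = GeneticMap(genetic_map)
    r_used = _resolve_r(meta_long, r_by_phenotype)
    wide = _pivot_sexes(meta_long)
    r_vec = wide["PHENOTYPE"].map(r_used).fillna(0.0).to_numpy()
    t, p_two, _ = sexdiff_test(
        wide["BETA_M"].to_numpy(),
        wide["SE_M"].to_numpy(),
        wide["BETA_W"].to_numpy(),
        wide["SE_W"].to_numpy(),
        r=r_vec,
        ref_sign=1.0,
    )
    tests = wide.assign(T_DIFF=np.atleast_1d(t), P=np.atleast_1d(p_two))
    reject, k, critical = bh_fdr(tests["P"].to_numpy(), fdr)
    selected = tests.loc[reject].copy()
    m = len(tests)
    empty = selected.iloc[0:0]
    if selected.empty:
        return ScanReport(
            "sex_difference", fdr, m, 0, None, selected, empty, empty, r_used
        )
    best = (
        selected.sort_values(["P", "PHENOTYPE"], kind="mergesort")
        .groupby("SNP", sort=False)
        .first()
        .reset_index()
        .sort_values(["CHR", "POS"])
        .reset_index(drop=True)
    )
    cms = []
    for chrom, grp in best.groupby("CHR", sort=False):
        cms.append(genetic_map.interpolate(chrom, grp["POS"].to_numpy()))
    best["CM"] = np.concatenate(cms) if cms else np.array([])
    independent, log = prune_independent(best, window_cm=prune_cm)
    return ScanReport(
        scan_type="sex_difference",
        fdr_level=fdr,
        m=m,
        k=k,
        critical_p=critical,
        selected=selected.reset_index(drop=True),
        independent=independent,
        candidates=independent,
        r_used=r_used,
        pruning_log=log,
    )


@dataclass
class ConfirmationReport:
    """Outcome of the unbiased follow-up confirmation stage."""

    m: int  # survivors of the main-effect filter with follow-up data
    k: int  # confirmed at the FDR level
    critical_p: float | None
    table: pd.DataFrame  # per-candidate joint estimates and decisions
    excluded: list = field(default_factory=list)  # no follow-up data
    main_effect_p: float = 0.01
    fdr: float = 0.05


def followup_confirm(
    candidates: pd.DataFrame,
    discovery_long: pd.DataFrame,
    followup_long: pd.DataFrame,
    r_followup: float | dict = 0.0,
    main_effect_p: float = 0.01,
    fdr: float = 0.05,
    main_effect_stage: str = "joint",
) -> ConfirmationReport:
    """Confirm sex-difference for discovery candidates in follow-up data.

    Steps: (1) compute joint (discovery + follow-up) per-sex estimates;
    (2) filter on the sex-combined main-effect p-value (< ``main_effect_p``,
    joint stages by default — ``main_effect_stage="followup"`` restricts
    the filter to follow-up data); (3) test the survivors' sex-difference
    in the *follow-up data alone*, one-sided toward the discovery
    direction; (4) Benjamini-Hochberg at ``fdr`` with m = number of
    survivors that have follow-up data.

    Because candidates were selected on sex-specific discovery
    association, only the follow-up difference test is unbiased; the
    main-effect filter is safe because the sex-combined and
    sex-difference contrasts are orthogonal.

    ``candidates`` needs SNP and PHENOTYPE columns; the long tables need
    SNP, PHENOTYPE, SEX, BETA, SE, P, N.
    """
    disc = _pivot_sexes(discovery_long)
    fu = _pivot_sexes(followup_long)
    cand = candidates[["SNP", "PHENOTYPE"]].drop_duplicates()
    merged = cand.merge(
        disc, on=["SNP", "PHENOTYPE"], how="left", suffixes=("", "")
    ).merge(
        fu,
        on=["SNP", "PHENOTYPE"],
        how="left",
        suffixes=("_DISC", "_FU"),
    )
    merged = merged.rename(
        columns={
            c: f"{c}_DISC"
            for c in ("BETA_M", "SE_M", "P_M", "N_M", "BETA_W", "SE_W", "P_W", "N_W")
            if c in merged.columns
        }
    )
    has_fu = merged["BETA_M_FU"].notna() & merged["BETA_W_FU"].notna()
    excluded = merged.loc[~has_fu, "SNP"].tolist()
    if excluded:
        logger.warning(
            "%d candidate(s) absent from follow-up, excluded from m: %s",
            len(excluded),
            excluded[:10],
        )
    work = merged.loc[has_fu].reset_index(drop=True)

    for sex in ("M", "W"):
        w_d = 1.0 / work[f"SE_{sex}_DISC"] ** 2
        w_f = 1.0 / work[f"SE_{sex}_FU"] ** 2
        work[f"BETA_{sex}_JOINT"] = (
            w_d * work[f"BETA_{sex}_DISC"] + w_f * work[f"BETA_{sex}_FU"]
        ) / (w_d + w_f)
        work[f"SE_{sex}_JOINT"] = 1.0 / np.sqrt(w_d + w_f)
        work[f"P_{sex}_JOINT"] = 2 * stats.norm.sf(
            np.abs(work[f"BETA_{sex}_JOINT"] / work[f"SE_{sex}_JOINT"])
        )

    stage = "JOINT" if main_effect_stage == "joint" else "FU"
    w_m = 1.0 / work[f"SE_M_{stage}"] ** 2
    w_w = 1.0 / work[f"SE_W_{stage}"] ** 2
    beta_c = (w_m * work[f"BETA_M_{stage}"] + w_w * work[f"BETA_W_{stage}"]) / (
        w_m + w_w
    )
    se_c = 1.0 / np.sqrt(w_m + w_w)
    work["P_MAIN"] = 2 * stats.norm.sf(np.abs(beta_c / se_c))

    survivors = work.loc[work["P_MAIN"] < main_effect_p].reset_index(drop=True)
    m = len(survivors)
    if m == 0:
        survivors = survivors.assign(
            T_DIFF_FU=np.nan, P_DIFF_FU=np.nan, CONFIRMED=False,
            PRIMARY_SEX="", CLASS="",
        )
        return ConfirmationReport(
            0, 0, None, survivors, excluded, main_effect_p, fdr
        )

    if isinstance(r_followup, dict):
        r_vec = survivors["PHENOTYPE"].map(r_followup).fillna(0.0).to_numpy()
    else:
        r_vec = float(r_followup)
    # discovery direction as the one-sided reference
    ref = np.sign(
        survivors["BETA_M_DISC"].to_numpy() - survivors["BETA_W_DISC"].to_numpy()
    )
    t_fu, p_two_fu, p_one_fu = sexdiff_test(
        survivors["BETA_M_FU"].to_numpy(),
        survivors["SE_M_FU"].to_numpy(),
        survivors["BETA_W_FU"].to_numpy(),
        survivors["SE_W_FU"].to_numpy(),
        r=r_vec,
        ref_sign=ref,
    )
    survivors["T_DIFF_FU"] = np.atleast_1d(t_fu)
    survivors["P_DIFF_FU"] = np.atleast_1d(p_one_fu)
    reject, k, critical = bh_fdr(survivors["P_DIFF_FU"].to_numpy(), fdr)
    survivors["CONFIRMED"] = reject

    primary_is_w = survivors["P_W_JOINT"] <= survivors["P_M_JOINT"]
    other_p = np.where(primary_is_w, survivors["P_M_JOINT"], survivors["P_W_JOINT"])
    same_sign = np.sign(survivors["BETA_M_JOINT"]) == np.sign(
        survivors["BETA_W_JOINT"]
    )
    survivors["PRIMARY_SEX"] = np.where(primary_is_w, "W", "M")
    survivors["CLASS"] = [
        classify_dimorphism(bool(c), float(op), bool(ss))
        for c, op, ss in zip(reject, other_p, same_sign)
    ]
    return ConfirmationReport(
        m=m,
        k=k,
        critical_p=critical,
        table=survivors,
        excluded=excluded,
        main_effect_p=main_effect_p,
        fdr=fdr,
    )


def confirm_from_pvalues(
    followup_pdiff,
    main_effect_pvalues=None,
    main_effect_p: float = 0.01,
    fdr: float = 0.05,
) -> tuple[np.ndarray, int, float | None]:
    """Confirmation decision from precomputed p-value panels.

    Convenience path for working with published per-SNP p-values rather
    than effect estimates: optionally filters on the main-effect
    p-values, then applies Benjamini-Hochberg to the follow-up
    sex-difference p-values of the survivors.  Returns
    ``(reject_flags, k, critical_p)`` over the surviving panel.
    """
    p = np.asarray(followup_pdiff, dtype=float)
    if main_effect_pvalues is not None:
        keep = np.asarray(main_effect_pvalues, dtype=float) < main_effect_p
        p = p[keep]
    return bh_fdr(p, fdr)


def declare_gws(pvalues, threshold: float = 5e-8) -> np.ndarray:
    """Flag genome-wide significant associations (strict p < threshold)."""
    return np.asarray(pvalues, dtype=float) < threshold
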