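"""Fixed-effect meta-analysis of GWAS summary statistics.

Combines per-study estimates within a sex, across discovery and
follow-up stages, and across the sexes (the "main effect" used by the
confirmation-stage filter).  All combinations use the inverse-variance
weighted fixed-effect model; a sample-size weighted z-score combination
is provided as a sensitivity check.  P-values are two-sided from the
standard normal reference — effective sample sizes are in the thousands,
so the normal and t references are indistinguishable.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .sumstats_io import estimate_lambda, gc_correct

__all__ = [
    "SexSpecificEstimate",
    "inverse_variance_meta",
    "sample_size_z_meta",
    "combine_stages",
    "sex_combined_meta",
    "meta_analyze_studies",
    "double_gc",
]


@dataclass(frozen=True)
class SexSpecificEstimate:
    """One meta-analyzed association result for a (SNP, phenotype, sex)."""

    snp: str
    phenotype: str
    sex: str  # "M", "W" or "combined"
    stage: str  # "discovery", "followup" or "joint"
    beta: float
    se: float
    p: float
    n: int
    n_studies: int = 1

    def __post_init__(self) -> None:
        if self.se <= 0:
            raise ValueError(f"SE must be positive, got {self.se}")

    @property
    def z(self) -> float:
        return self.beta / self.se


def _two_sided_p(z: np.ndarray | float) -> np.ndarray | float:
    return 2.0 * stats.norm.sf(np.abs(z))


def inverse_variance_meta(
    betas: Sequence[float],
    ses: Sequence[float],
    ns: Sequence[float] | None = None,
) -> tuple[float, float, float, int]:
    """Inverse-variance weighted fixed-effect combination.

    Weights are w_i = 1/se_i^2; the combined estimate is
    sum(w_i b_i)/sum(w_i) with SE 1/sqrt(sum(w_i)).  Returns
    ``(beta, se, p, n)`` where n is the summed sample size (0 when
    ``ns`` is not supplied).
    """
    b = np.asarray(betas, dtype=float)
    s = np.asarray(ses, dtype=float)
    if b.size == 0:
        raise ValueError("inverse_variance_meta requires at least one study")
    if np.any(s <= 0):
        raise ValueError("all standard errors must be positive")
    w = 1.0 / s**2
    beta = float(np.sum(w * b) / np.sum(w))
    se = float(1.0 / np.sqrt(np.sum(w)))
    p = float(_two_sided_p(beta / se))
    n = int(np.sum(ns)) if ns is not None else 0
    return beta, se, p, n


def sample_size_z_meta(
    zs: Sequence[float], ns: Sequence[float]
) -> tuple[float, float]:
    """Sample-size weighted z-score combination: z = sum(sqrt(n_i) z_i)/sqrt(sum n_i)."""
    z = np.asarray(zs, dtype=float)
    n = np.asarray(ns, dtype=float)
    if z.size == 0:
        raise ValueError("sample_size_z_meta requires at least one study")
    if np.any(n <= 0):
        raise ValueError("sample sizes must be positive")
    zc = float(np.sum(np.sqrt(n) * z) / np.sqrt(np.sum(n)))
    return zc, float(_two_sided_p(zc))


def combine_stages(
    discovery: SexSpecificEstimate, followup: SexSpecificEstimate | None
) -> SexSpecificEstimate:
    """Joint meta-analysis of the discovery and follow-up stage estimates.

    When the follow-up estimate is missing (SNP not assayed in any
    follow-up study) the discovery estimate is passed through with
    stage "joint".
    """
    if followup is None:
        return replace(discovery, stage="joint")
    for field in ("snp", "phenotype", "sex"):
        if getattr(discovery, field) != getattr(followup, field):
            raise ValueError(
                f"stage estimates disagree on {field}: "
                f"{getattr(discovery, field)!r} vs {getattr(followup, field)!r}"
            )
    beta, se, p, n = inverse_variance_meta(
        [discovery.beta, followup.beta],
        [discovery.se, followup.se],
        [discovery.n, followup.n],
    )
    return SexSpecificEstimate(
        snp=discovery.snp,
        phenotype=discovery.phenotype,
        sex=discovery.sex,
        stage="joint",
        beta=beta,
        se=se,
        p=p,
        n=n,
        n_studies=discovery.n_studies + followup.n_studies,
    )


def sex_combined_meta(
    men: SexSpecificEstimate, women: SexSpecificEstimate
) -> SexSpecificEstimate:
    """Inverse-variance combination across the sexes ("main effect").

    Used by the confirmation-stage filter: because the male and female
    strata contain disjoint individuals, the combined statistic is
    uncorrelated with the male-female difference contrast, so filtering
    on it does not bias the subsequent sex-difference test.
    """
    if men is None or women is None:
        raise ValueError("both sex-specific estimates are required")
    for field in ("snp", "phenotype", "stage"):
        if getattr(men, field) != getattr(women, field):
            raise ValueError(
                f"sex-specific estimates disagree on {field}: "
                f"{getattr(men, field)!r} vs {getattr(women, field)!r}"
            )
    beta, se, p, n = inverse_variance_meta(
        [men.beta, women.beta], [men.se, women.se], [men.n, women.n]
    )
    return SexSpecificEstimate(
        snp=men.snp,
        phenotype=men.phenotype,
        sex="combined",
        stage=men.stage,
        beta=beta,
        se=se,
        p=p,
        n=n,
        n_studies=men.n_studies + women.n_studies,
    )


def meta_analyze_studies(
    tables: Sequence[pd.DataFrame], snp_col: str = "SNP"
) -> pd.DataFrame:
    """Vectorized inverse-variance meta-analysis over study tables.

    Each table must carry SNP, BETA, SE and N columns.  SNPs present in
    only a subset of studies are combined over the studies that report
    them, with the realized total N recorded.  Returns a table with one
    row per SNP: BETA, SE, P, N, N_STUDIES (plus CHR/POS carried over
    from the first study reporting the SNP, when present).
    """
    if len(tables) == 0:
        raise ValueError("no study tables supplied")
    stacked = pd.concat(tables, ignore_index=True)
    w = 1.0 / stacked["SE"] ** 2
    stacked = stacked.assign(_w=w, _wb=w * stacked["BETA"])
    grouped = stacked.groupby(snp_col, sort=False)
    agg = grouped.agg(
        _w=("_w", "sum"),
        _wb=("_wb", "sum"),
        N=("N", "sum"),
        N_STUDIES=("BETA", "size"),
    )
    out = pd.DataFrame(index=agg.index)
    out["BETA"] = agg["_wb"] / agg["_w"]
    out["SE"] = 1.0 / np.sqrt(agg["_w"])
    out["P"] = _two_sided_p(out["BETA"] / out["SE"])
    out["N"] = agg["N"]
    out["N_STUDIES"] = agg["N_STUDIES"]
    for col in ("CHR", "POS"):
        if col in stacked.columns:
            out[col] = grouped[col].first()
    return out.reset_index()


def double_gc(
    study_tables_by_group: dict[str, list[pd.DataFrame]],
    study_lambdas: dict[str, list[float]] | None = None,
    final_gc: bool = False,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Meta-analysis with genomic control applied at successive levels.

    Implements the "double GC" scheme: (1) each study table is GC
    corrected with its supplied lambda (or an estimated one), (2) studies
    are meta-analyzed within each group (e.g. genotyping platform) and
    the group-level result is GC corrected with a lambda estimated from
    its own statistics, (3) group results are combined across groups.
    ``final_gc`` optionally applies a third correction to the cross-group
    combination (off by default).

    Returns the final meta table and an audit trail of the lambdas
    applied at each level.
    """
    audit: dict[str, float] = {}
    group_results = []
    for group, tables in study_tables_by_group.items():
        corrected = []
        for i, table in enumerate(tables):
            lam = None
            if study_lambdas is not None and group in study_lambdas:
                lam = study_lambdas[group][i]
            fixed, applied = gc_correct(table, lam)
            audit[f"study:{group}:{i}"] = applied
            corrected.append(fixed)
        meta = meta_analyze_studies(corrected)
        lam_group = estimate_lambda(meta["BETA"] / meta["SE"])
        meta, applied = gc_correct(meta, lam_group)
        audit[f"group:{group}"] = applied
        group_results.append(meta.drop(columns=["N_STUDIES"]))
    final = meta_analyze_studies(group_results)
    if final_gc:
        lam_final = estimate_lambda(final["BETA"] / final["SE"])
        final, applied = gc_correct(final, lam_final)
        audit["final"] = applied
    return final, audit
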