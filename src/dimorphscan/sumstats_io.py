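"""Reading, harmonizing, QC-filtering and GC-correcting summary statistics.

File format: tab-delimited with header columns SNP, CHR, POS,
EFFECT_ALLELE, OTHER_ALLELE, EAF, BETA, SE, P, N, QUALITY, PLATFORM.
Genetic maps are tab-delimited CHR, POS, CM in the style of HapMap
recombination-rate files.  Positions are 1-based bp on a single genome
build per run; no liftover is attempted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "COLUMNS",
    "PLATFORM_QUALITY_MIN",
    "StudySumStats",
    "read_sumstats",
    "write_sumstats",
    "harmonize_alleles",
    "qc_filter",
    "estimate_lambda",
    "gc_correct",
    "read_genetic_map",
    "write_genetic_map",
]

COLUMNS = [
    "SNP",
    "CHR",
    "POS",
    "EFFECT_ALLELE",
    "OTHER_ALLELE",
    "EAF",
    "BETA",
    "SE",
    "P",
    "N",
    "QUALITY",
    "PLATFORM",
]

#: Minimum imputation-quality metric per genotyping/imputation platform.
#: MACH: r2_hat >= 0.3; BIMBAM: observed/expected dosage variance >= 0.3;
#: IMPUTE: proper_info >= 0.4; PLINK: information >= 0.8.  Directly
#: genotyped SNPs carry no imputation metric and are not quality-filtered.
PLATFORM_QUALITY_MIN = {
    "MACH": 0.3,
    "BIMBAM": 0.3,
    "IMPUTE": 0.4,
    "PLINK": 0.8,
    "GENOTYPED": None,
}

_VALID_ALLELES = {"A", "C", "G", "T"}
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

# Median of the 1-df chi-square distribution, used to estimate the
# genomic-control inflation factor as median(chi2)/this.
CHI2_1DF_MEDIAN = float(stats.chi2.ppf(0.5, 1))  # 0.45494


@dataclass
class StudySumStats:
    """Per-study, per-sex summary statistics plus identifying metadata."""

    study_id: str
    sex: str
    platform: str
    table: pd.DataFrame

    def __post_init__(self) -> None:
        if self.platform not in PLATFORM_QUALITY_MIN:
            raise ValueError(
                f"unknown platform {self.platform!r}; "
                f"expected one of {sorted(PLATFORM_QUALITY_MIN)}"
            )


def _validate_rows(df: pd.DataFrame) -> tuple[pd.DataFrame, list[tuple[int, str]]]:
    """Drop malformed rows; return surviving frame and (line, reason) pairs."""
    rejected: list[tuple[int, str]] = []
    checks = [
        (~df["EFFECT_ALLELE"].isin(_VALID_ALLELES)
         | ~df["OTHER_ALLELE"].isin(_VALID_ALLELES), "invalid allele"),
        ((df["EAF"] < 0) | (df["EAF"] > 1) | df["EAF"].isna(), "EAF outside [0,1]"),
        ((df["SE"] <= 0) | df["SE"].isna(), "non-positive SE"),
        ((df["P"] <= 0) | (df["P"] > 1) | df["P"].isna(), "P outside (0,1]"),
        ((df["N"] <= 0) | df["N"].isna(), "non-positive N"),
    ]
    bad = pd.Series(False, index=df.index)
    for mask, reason in checks:
        newly = mask & ~bad
        for idx in df.index[newly]:
            rejected.append((int(idx) + 2, reason))  # +2: header + 1-based
        bad |= mask
    if rejected:
        logger.warning("rejected %d malformed rows: %s", len(rejected), rejected[:10])
    return df.loc[~bad].reset_index(drop=True), rejected


def read_sumstats(
    path,
    platform: str | None = None,
    study_id: str = "",
    sex: str = "",
) -> StudySumStats:
    """Read a tab-delimited summary-statistic file into a StudySumStats.

    ``platform`` overrides the file's PLATFORM column when given.
    Malformed rows are dropped and reported with line numbers through the
    module logger; a missing mandatory column is a hard failure.
    """
    df = pd.read_csv(path, sep="\t", dtype={"SNP": str})
    missing = [c for c in COLUMNS if c not in df.columns and c != "PLATFORM"]
    if missing:
        raise ValueError(f"missing mandatory column(s): {', '.join(missing)}")
    if platform is None:
        if "PLATFORM" not in df.columns:
            raise ValueError("missing mandatory column(s): PLATFORM")
        platform = str(df["PLATFORM"].iloc[0])
    df["PLATFORM"] = platform
    for col in ("EFFECT_ALLELE", "OTHER_ALLELE"):
        df[col] = df[col].str.upper()
    df, _ = _validate_rows(df)
    logger.info("read %d records from %s", len(df), path)
    return StudySumStats(study_id=study_id, sex=sex, platform=platform, table=df)


def write_sumstats(study: StudySumStats, path) -> None:
    study.table.to_csv(path, sep="\t", index=False, columns=COLUMNS)


@dataclass
class HarmonizeReport:
    n_matched: int = 0
    n_flipped: int = 0
    n_strand_complemented: int = 0
    n_dropped_ambiguous: int = 0
    n_dropped_mismatch: int = 0
    n_eaf_warnings: int = 0


def harmonize_alleles(
    records: pd.DataFrame,
    reference: pd.DataFrame,
    ambiguous_maf_cutoff: float = 0.4,
    eaf_warn_delta: float = 0.2,
) -> tuple[pd.DataFrame, HarmonizeReport]:
    """Align effect alleles to a reference (effect, other) pair per SNP.

    Records whose allele pair matches the reference after swapping get
    beta negated and EAF complemented.  Strand-complement matches are
    resolved by complementing first.  Strand-ambiguous A/T and C/G SNPs
    with MAF above ``ambiguous_maf_cutoff`` are dropped (their strand
    cannot be inferred from frequency), as are SNPs whose allele pair is
    disjoint from the reference even after complementing.  Records whose
    reference allele frequency exists and differs from EAF by more than
    ``eaf_warn_delta`` after alignment are flagged with a warning.
    """
    ref = reference.set_index("SNP")
    report = HarmonizeReport()
    out = records.copy().reset_index(drop=True)
    keep = np.ones(len(out), dtype=bool)
    for i in range(len(out)):
        snp = out.at[i, "SNP"]
        if snp not in ref.index:
            continue
        ea, oa = out.at[i, "EFFECT_ALLELE"], out.at[i, "OTHER_ALLELE"]
        ref_ea, ref_oa = ref.at[snp, "EFFECT_ALLELE"], ref.at[snp, "OTHER_ALLELE"]
        ambiguous = oa == _COMPLEMENT[ea]
        if ambiguous:
            maf = min(out.at[i, "EAF"], 1 - out.at[i, "EAF"])
            if maf > ambiguous_maf_cutoff:
                keep[i] = False
                report.n_dropped_ambiguous += 1
                continue
        if (ea, oa) == (ref_ea, ref_oa):
            report.n_matched += 1
        elif (ea, oa) == (ref_oa, ref_ea):
            out.at[i, "BETA"] = -out.at[i, "BETA"]
            out.at[i, "EAF"] = 1 - out.at[i, "EAF"]
            out.at[i, "EFFECT_ALLELE"], out.at[i, "OTHER_ALLELE"] = ref_ea, ref_oa
            report.n_flipped += 1
        else:
            cea, coa = _COMPLEMENT[ea], _COMPLEMENT[oa]
            if (cea, coa) == (ref_ea, ref_oa):
                out.at[i, "EFFECT_ALLELE"], out.at[i, "OTHER_ALLELE"] = ref_ea, ref_oa
                report.n_strand_complemented += 1
            elif (cea, coa) == (ref_oa, ref_ea):
                out.at[i, "BETA"] = -out.at[i, "BETA"]
                out.at[i, "EAF"] = 1 - out.at[i, "EAF"]
                out.at[i, "EFFECT_ALLELE"], out.at[i, "OTHER_ALLELE"] = ref_ea, ref_oa
                report.n_strand_complemented += 1
                report.n_flipped += 1
            else:
                keep[i] = False
                report.n_dropped_mismatch += 1
                continue
        if "EAF" in ref.columns and not np.isnan(ref.at[snp, "EAF"]):
            if abs(out.at[i, "EAF"] - ref.at[snp, "EAF"]) > eaf_warn_delta:
                report.n_eaf_warnings += 1
    if report.n_dropped_ambiguous or report.n_dropped_mismatch:
        logger.warning(
            "harmonization dropped %d ambiguous and %d mismatched records",
            report.n_dropped_ambiguous,
            report.n_dropped_mismatch,
        )
    return out.loc[keep].reset_index(drop=True), report


def qc_filter(study: StudySumStats) -> tuple[StudySumStats, dict[str, int]]:
    """Apply the standard exclusions; return filtered stats and rule counts.

    Exclusions: monomorphic SNPs (EAF of 0 or 1), SNPs with
    MAF*N <= 3 (too few minor-allele observations), and SNPs below the
    platform-specific imputation-quality minimum.  Surviving records are
    returned unaltered.
    """
    df = study.table
    quality_min = PLATFORM_QUALITY_MIN[study.platform]
    maf = np.minimum(df["EAF"], 1 - df["EAF"])
    rules = {
        "monomorphic": (df["EAF"] <= 0) | (df["EAF"] >= 1),
        "maf_n": maf * df["N"] <= 3,
        "low_quality": (
            df["QUALITY"] < quality_min
            if quality_min is not None
            else pd.Series(False, index=df.index)
        ),
    }
    bad = pd.Series(False, index=df.index)
    report: dict[str, int] = {}
    for name, mask in rules.items():
        report[name] = int((mask & ~bad).sum())
        bad |= mask
    report["total_removed"] = int(bad.sum())
    filtered = StudySumStats(
        study_id=study.study_id,
        sex=study.sex,
        platform=study.platform,
        table=df.loc[~bad].reset_index(drop=True),
    )
    logger.info("qc_filter %s/%s: %s", study.study_id, study.sex, report)
    return filtered, report


def estimate_lambda(z) -> float:
    """Genomic-control inflation factor: median(z^2) / median(chi2_1)."""
    z = np.asarray(z, dtype=float)
    if z.size == 0:
        raise ValueError("cannot estimate lambda from no statistics")
    return float(np.median(z**2) / CHI2_1DF_MEDIAN)


def gc_correct(
    records: pd.DataFrame, lam: float | None = None
) -> tuple[pd.DataFrame, float]:
    """Genomic-control correct a table of association statistics.

    The applied factor is max(lambda, 1) — GC never sharpens evidence.
    SEs are multiplied by sqrt(lambda) and p-values recomputed from the
    shrunken z; betas are unchanged.  When ``lam`` is None it is
    estimated from the table's own z statistics.  Returns the corrected
    table and the factor actually applied.
    """
    if lam is None:
        lam = estimate_lambda(records["BETA"] / records["SE"])
    if lam <= 0:
        raise ValueError(f"lambda must be positive, got {lam}")
    applied = max(lam, 1.0)
    out = records.copy()
    out["SE"] = out["SE"] * np.sqrt(applied)
    z = out["BETA"] / out["SE"]
    out["P"] = 2 * stats.norm.sf(np.abs(z))
    return out, applied


def read_genetic_map(path) -> pd.DataFrame:
    """Read a tab-delimited genetic map with columns CHR, POS, CM."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ("CHR", "POS", "CM") if c not in df.columns]
    if missing:
        raise ValueError(f"genetic map missing column(s): {', '.join(missing)}")
    return df.sort_values(["CHR", "POS"]).reset_index(drop=True)


def write_genetic_map(map_df: pd.DataFrame, path) -> None:
    map_df.to_csv(path, sep="\t", index=False, columns=["CHR", "POS", "CM"])
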