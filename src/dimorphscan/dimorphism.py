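"""Tests and classification of sex (and age) differences in genetic effects.

The core statistic compares the meta-analyzed male- and female-specific
effect estimates of a SNP,

    t = (b_m - b_w) / sqrt(se_m^2 + se_w^2 - 2 r se_m se_w),

where r is the rank correlation between male and female meta-analyzed
betas across all SNPs of the phenotype.  r is non-zero even though the
strata contain disjoint individuals, because shared (sex-concordant)
polygenic effects correlate the estimates; ignoring it makes the test
conservative.  t is referred to the standard normal — the effective
degrees of freedom of the meta-analyzed estimates are in the tens of
thousands.

Significantly dimorphic SNPs are classified by the behaviour of the
non-primary sex: concordant effect direction (CED), single sex effect
(SSE), or opposite effect direction (OED).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "CorrelationEstimate",
    "SexDiffResult",
    "estimate_beta_correlation",
    "sexdiff_test",
    "classify_dimorphism",
    "age_diff_test",
    "binomial_enrichment",
]


@dataclass(frozen=True)
class CorrelationEstimate:
    """Between-stratum rank correlation of per-SNP effect estimates."""

    phenotype: str
    stage: str
    r: float
    n_snps: int


@dataclass(frozen=True)
class SexDiffResult:
    """Outcome of the between-stratum difference test for one SNP."""

    t: float
    p_two: float
    p_one: float
    r: float
    classification: str = "none"  # CED, SSE, OED or none


def estimate_beta_correlation(
    men_betas,
    women_betas,
    phenotype: str = "",
    stage: str = "discovery",
    min_pairs: int = 30,
) -> CorrelationEstimate:
    """Spearman rank correlation of male vs female betas across SNPs.

    Estimated on all QC-passing SNPs of the phenotype (not an LD-pruned
    subset).  Fewer than ``min_pairs`` paired SNPs is rejected — supply r
    manually in that case.
    """
    m = np.asarray(men_betas, dtype=float)
    w = np.asarray(women_betas, dtype=float)
    if m.shape != w.shape:
        raise ValueError("men and women beta vectors must have equal length")
    if m.size < min_pairs:
        raise ValueError(
            f"need >= {min_pairs} paired SNPs to estimate r reliably "
            f"(got {m.size}); supply r manually"
        )
    r = float(stats.spearmanr(m, w).statistic)
    return CorrelationEstimate(phenotype=phenotype, stage=stage, r=r, n_snps=m.size)


def sexdiff_test(b_m, se_m, b_w, se_w, r: float = 0.0, ref_sign=None):
    """Correlation-corrected test for difference between sex-specific betas.

    Parameters
    ----------
    b_m, se_m, b_w, se_w
        Meta-analyzed effect estimates and standard errors per sex;
        scalars or equal-length arrays.
    r
        Between-sex correlation of the estimates (see module docstring).
    ref_sign
        Reference direction for the one-sided p-value, typically the
        sign of the discovery-stage difference.  When None, the observed
        sign is used (p_one = p_two / 2).

    Returns a :class:`SexDiffResult` for scalar input, or a tuple of
    arrays ``(t, p_two, p_one)`` for array input.
    """
    b_m = np.asarray(b_m, dtype=float)
    b_w = np.asarray(b_w, dtype=float)
    se_m = np.asarray(se_m, dtype=float)
    se_w = np.asarray(se_w, dtype=float)
    if np.any(se_m <= 0) or np.any(se_w <= 0):
        raise ValueError("standard errors must be positive")
    var = se_m**2 + se_w**2 - 2.0 * r * se_m * se_w
    if np.any(var <= 0):
        raise ValueError(
            "non-positive difference variance; |r| too close to 1 for "
            "these standard errors"
        )
    t = (b_m - b_w) / np.sqrt(var)
    p_two = 2.0 * stats.norm.sf(np.abs(t))
    if ref_sign is None:
        p_one = p_two / 2.0
    else:
        ref = np.sign(np.asarray(ref_sign, dtype=float))
        agree = np.sign(t) == ref
        p_one = np.where(agree, p_two / 2.0, 1.0 - p_two / 2.0)
        # a zero observed difference is evidence for neither direction
        p_one = np.where(t == 0, 0.5, p_one)
    if t.ndim == 0:
        return SexDiffResult(
            t=float(t), p_two=float(p_two), p_one=float(p_one), r=float(r)
        )
    return t, p_two, p_one


def classify_dimorphism(
    primary_sex_significant: bool,
    other_sex_p: float,
    sign_agreement: bool,
    alpha: float = 0.05,
) -> str:
    """Classify a dimorphic association by the non-primary sex's behaviour.

    Requires the primary-sex significance decision (an upstream FDR
    flag).  CED: the other sex is at least nominally significant in the
    same direction; SSE: the other sex shows no nominal association;
    OED: the other sex is nominally significant in the opposite
    direction.
    """
    if not primary_sex_significant:
        return "none"
    if other_sex_p >= alpha:
        return "SSE"
    return "CED" if sign_agreement else "OED"


def age_diff_test(young, old, r_age: float = 0.0, ref_sign=None):
    """Difference test between age-stratum estimates within one sex.

    Identical contract to :func:`sexdiff_test` with age strata (e.g.
    < 50 vs >= 50 years, a menopause-motivated cut) substituted for the
    sexes.  ``young`` and ``old`` are estimates with ``beta``/``se``
    attributes or (beta, se) pairs.
    """

    def _unpack(est):
        if hasattr(est, "beta"):
            return est.beta, est.se
        return est

    b_y, se_y = _unpack(young)
    b_o, se_o = _unpack(old)
    if hasattr(young, "snp") and hasattr(old, "snp"):
        for f in ("snp", "phenotype", "sex"):
            if getattr(young, f) != getattr(old, f):
                raise ValueError(f"age-stratum estimates disagree on {f}")
    return sexdiff_test(b_y, se_y, b_o, se_o, r=r_age, ref_sign=ref_sign)


def binomial_enrichment(
    n_female_larger: int, n_total: int, rate: float = 0.5
) -> tuple[float, float]:
    """Exact binomial sign test for enrichment of female-larger effects.

    Returns ``(p_one, p_two)``: the one-sided tail P(X >= k | n, rate)
    and the doubled smaller tail capped at 1.  With the default
    rate 1/2 this tests whether effect sizes are larger in one sex more
    often than a fair coin would produce.
    """
    if n_total < 1:
        raise ValueError("n_total must be at least 1")
    if not 0 <= n_female_larger <= n_total:
        raise ValueError("n_female_larger must lie in [0, n_total]")
    upper = float(stats.binom.sf(n_female_larger - 1, n_total, rate))
    lower = float(stats.binom.cdf(n_female_larger, n_total, rate))
    p_two = min(1.0, 2.0 * min(upper, lower))
    return upper, p_two
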