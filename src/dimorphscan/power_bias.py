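"""Analytic power for the scan strategies and the winner's-curse simulation.

All association tests are 1-df chi-square tests; for a design with n
individuals and variance explained R^2, the non-centrality parameter is
n R^2 / (1 - R^2).  Standardized per-allele effects convert to NCPs via
the summary-statistic standard error SE = 1/sqrt(2 maf (1-maf) n) on the
unit-variance trait scale.

Three selection strategies are compared at a common threshold alpha:

* sex-specific scan — select if either sex's association passes alpha;
* sex-difference scan — select if the male-female difference contrast
  passes alpha;
* sex-combined scan — select if the inverse-variance pooled estimate
  passes alpha.

For single-sex and concordant effects the sex-specific scan dominates;
for opposite-direction effects the pooled estimate cancels and only the
difference scan has power.  The two-stage confirmation power multiplies
the main-effect and difference-test powers: with inverse-variance
weights the pooled and difference contrasts have zero covariance, so
the two tests are exactly independent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PowerDesign",
    "ncp_from_design",
    "power_single_test",
    "power_scan",
    "power_two_stage",
    "WinnersCurseResult",
    "winners_curse_sim",
]


@dataclass(frozen=True)
class PowerDesign:
    """A two-sex association design for analytic power queries."""

    n_men: int
    n_women: int
    maf: float
    beta_men: float  # standardized per-allele effect
    beta_women: float
    alpha: float = 2e-5
    r: float = 0.0  # between-sex correlation of the estimates

    def __post_init__(self) -> None:
        if not 0 < self.maf <= 0.5:
            raise ValueError("maf must lie in (0, 0.5]")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0,1)")

    @classmethod
    def from_r2(
        cls,
        n_men: int,
        n_women: int,
        maf: float,
        r2_men: float = 0.0,
        r2_women: float = 0.0,
        sign_men: int = 1,
        sign_women: int = 1,
        **kw,
    ) -> "PowerDesign":
        """Build a design from per-sex variance explained R^2."""
        for r2 in (r2_men, r2_women):
            if not 0 <= r2 < 1:
                raise ValueError("R^2 must lie in [0, 1)")
        scale = np.sqrt(2 * maf * (1 - maf))
        return cls(
            n_men=n_men,
            n_women=n_women,
            maf=maf,
            beta_men=sign_men * np.sqrt(r2_men) / scale,
            beta_women=sign_women * np.sqrt(r2_women) / scale,
            **kw,
        )

    def se(self, sex: str) -> float:
        n = self.n_men if sex == "M" else self.n_women
        return 1.0 / np.sqrt(2 * self.maf * (1 - self.maf) * n)


def ncp_from_design(n: float, r2: float) -> float:
    """1-df association NCP: n * R^2 / (1 - R^2)."""
    if not 0 <= r2 < 1:
        raise ValueError("R^2 must lie in [0, 1)")
    if n <= 0:
        raise ValueError("n must be positive")
    return n * r2 / (1.0 - r2)


def power_single_test(ncp: float, alpha: float) -> float:
    """Power of a 1-df chi-square test at level alpha given the NCP."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0,1)")
    crit = stats.chi2.ppf(1.0 - alpha, df=1)
    return float(stats.ncx2.sf(crit, df=1, nc=ncp))


def power_scan(design: PowerDesign, mode: str) -> float:
    """Probability that a scan strategy selects the SNP at design.alpha.

    ``mode`` is one of "sex_specific", "sex_difference", "sex_combined".
    The sex-specific scan treats the two strata as independent:
    P(select) = 1 - (1 - power_m)(1 - power_w).
    """
    se_m, se_w = design.se("M"), design.se("W")
    a = design.alpha
    if mode == "sex_specific":
        pm = power_single_test((design.beta_men / se_m) ** 2, a)
        pw = power_single_test((design.beta_women / se_w) ** 2, a)
        return 1.0 - (1.0 - pm) * (1.0 - pw)
    if mode == "sex_difference":
        var = se_m**2 + se_w**2 - 2 * design.r * se_m * se_w
        ncp = (design.beta_men - design.beta_women) ** 2 / var
        return power_single_test(ncp, a)
    if mode == "sex_combined":
        w_m, w_w = 1.0 / se_m**2, 1.0 / se_w**2
        beta_c = (w_m * design.beta_men + w_w * design.beta_women) / (w_m + w_w)
        ncp = beta_c**2 * (w_m + w_w)
        return power_single_test(ncp, a)
    raise ValueError(f"unknown scan mode {mode!r}")


def power_two_stage(
    design: PowerDesign,
    main_effect_alpha: float = 0.01,
    diff_threshold: float = 4.2e-3,
    one_sided_diff: bool = True,
) -> float:
    """Power to confirm sex-difference behind a main-effect filter.

    The confirmation succeeds when the sex-combined test passes
    ``main_effect_alpha`` (two-sided) and the difference test passes
    ``diff_threshold`` (one-sided toward the true direction by default).
    The inverse-variance pooled contrast and the difference contrast are
    uncorrelated for any pair of standard errors, so the joint
    probability is the product of the marginal powers.  A degenerate
    ``diff_threshold=1`` reduces to the main-effect power alone.
    """
    p_main = power_scan(
        PowerDesign(
            design.n_men,
            design.n_women,
            design.maf,
            design.beta_men,
            design.beta_women,
            alpha=main_effect_alpha,
            r=design.r,
        ),
        "sex_combined",
    )
    if diff_threshold >= 1:
        return p_main
    se_m, se_w = design.se("M"), design.se("W")
    sd_diff = np.sqrt(se_m**2 + se_w**2 - 2 * design.r * se_m * se_w)
    mu = (design.beta_men - design.beta_women) / sd_diff
    if one_sided_diff:
        shift = abs(mu) if mu != 0 else 0.0
        p_diff = float(stats.norm.sf(stats.norm.ppf(1 - diff_threshold) - shift))
    else:
        p_diff = power_single_test(mu**2, diff_threshold)
    return p_main * p_diff


@dataclass
class WinnersCurseResult:
    """Selected vs unselected sex-difference p-values under the null."""

    pdiff_selected: np.ndarray
    pdiff_unselected: np.ndarray
    qq: pd.DataFrame  # EXPECTED vs OBSERVED quantiles over the selected set
    m: int
    k: int


def winners_curse_sim(
    m: int = 1_000_000,
    k: int = 348,
    seed: int = 0,
    n_unselected: int = 10_000,
) -> WinnersCurseResult:
    """Null simulation of selection-induced sex-difference inflation.

    Simulates m SNPs with independent standard-normal z-scores per sex
    (no association, no sex-difference), selects the k SNPs with the
    most extreme sex-specific association (smallest min of the two
    per-sex p-values), and returns the difference-test p-values of the
    selected set, of a random unselected subsample, and
    expected-vs-observed quantile pairs for a QQ display.  The selected
    p-values are inflated although the global null is true — the reason
    sex-difference must be established in independent follow-up data.
    """
    if k > m:
        raise ValueError("cannot select more SNPs than simulated")
    rng = np.random.default_rng(seed)
    z_m = rng.standard_normal(m)
    z_w = rng.standard_normal(m)
    p_min = 2.0 * stats.norm.sf(np.maximum(np.abs(z_m), np.abs(z_w)))
    order = np.argsort(p_min, kind="stable")
    sel = order[:k]
    pdiff = 2.0 * stats.norm.sf(np.abs(z_m - z_w) / np.sqrt(2.0))
    pdiff_selected = np.sort(pdiff[sel])
    unsel = order[k:]
    take = min(n_unselected, unsel.size)
    pdiff_unselected = pdiff[rng.choice(unsel, size=take, replace=False)]
    expected = (np.arange(1, k + 1) - 0.5) / k
    qq = pd.DataFrame({"EXPECTED": expected, "OBSERVED": pdiff_selected})
    return WinnersCurseResult(
        pdiff_selected=pdiff_selected,
        pdiff_unselected=pdiff_unselected,
        qq=qq,
        m=m,
        k=k,
    )
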