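# Methods

## Statistical model

All inputs are per-study, per-sex GWAS summary statistics for
quantitative traits that were residualized on age and age² (plus BMI for
the BMI-adjusted waist phenotypes) within each sex and then normalized —
rank inverse-normal for all traits except height, which is z-scored.
On this unit-variance scale a per-allele effect β at minor allele
frequency *maf* explains R² = 2·maf·(1−maf)·β² of the trait variance,
and the sampling standard error of a study estimate is approximately
1/√(2·maf·(1−maf)·n). These two identities connect the generator, the
meta-analysis and the power module throughout the package.

### Meta-analysis and genomic control

Within each sex, study estimates are combined with the inverse-variance
fixed-effect model; a sample-size-weighted z-score combination
(z = Σ√n_i z_i / √Σn_i) is provided as a sensitivity check and agrees
with the fixed-effect z exactly when se_i ∝ 1/√n_i. P-values use the
standard normal reference: effective sample sizes are ≥10³, where the
normal and Student-t references are numerically identical.

Genomic control multiplies SEs by √λ (λ = median(χ²)/0.45494 when not
supplied, floored at 1 so evidence is never sharpened) and recomputes
p-values; betas are untouched. `double_gc` applies this at successive
combination levels — supplied per-study λ, then an estimated λ after
meta-analyzing within each platform group, then combines groups; a third
correction of the final combination is available behind a flag but off
by default, since the appropriate depth depends on how stratification
enters the design. SNPs typed in only a subset of studies are combined
over the studies that report them, with the realized N recorded.

### The sex-difference test

The difference of the meta-analyzed per-sex estimates is tested with

    t = (β̂_m − β̂_w) / √(se_m² + se_w² − 2 r se_m se_w)

against the standard normal, where r is the Spearman rank correlation
of male vs female betas across all QC-passing SNPs of the phenotype
(not an LD-pruned subset). The sign convention is men minus women, and
one-sided p-values use a caller-supplied reference direction (in the
confirmation stage, the discovery direction).

The denominator's premise is Cov(β̂_m, β̂_w) = r·se_m·se_w, i.e. that r
reflects correlation of the *estimates*. Under that premise the test is
exactly calibrated, and setting r = 0 is conservative — both properties
are asserted in the test suite. A subtlety worth recording: when the
observed r originates purely from shared *true* effects (disjoint
samples, independent errors), the shared component cancels in the
difference, whose variance is then the full se_m² + se_w²; plugging in
a positive r then makes the test slightly liberal (variance understated
by a factor ≤ 1−r, i.e. at most ~18% for the correlations seen in
anthropometric data). The package follows the published formula; users
who prefer strict conservatism can pass r = 0.

### Scans, FDR and pruning

Both genome-wide scans apply the Benjamini–Hochberg step-up rule to a
concatenated p-value vector (all SNPs × phenotypes × sexes for the
sex-specific scan; × phenotypes for the sex-difference scan). BH is
delegated to `statsmodels.multipletests(fdr_bh)`; the reported critical
p is the largest rejected p-value, so k·α/m reproduces the scan's
effective p-value cut-off. Each surviving SNP is assigned its single
best (phenotype, sex) pair, other significant pairs being recorded as
secondary hits.

Genetic positions are interpolated from a HapMap-style (CHR, POS, CM)
map by inverse-distance weighting of the flanking points (identical to
linear interpolation in bp); a query at a map point returns that
point's cM, and queries outside the mapped span take the nearest
point's value with a logged warning. Pruning is a greedy sweep in
p-order that deletes a SNP within 0.2 cM (same chromosome) of any
already-*retained* SNP — comparing against retained SNPs only, the
standard clumping convention; the alternative reading (any
previously-seen SNP) differs only in chains and every deletion is
logged. Ties in p are broken by SNP id for determinism.

### Unbiased confirmation

Selecting candidates on sex-specific association inflates their
difference statistics in the same data (winner's curse; reproduced by
`winners_curse_sim`). The confirmation stage therefore (i) filters on
the sex-combined main effect, p < 0.01 by default — with
inverse-variance weights the pooled and difference contrasts have zero
covariance for *any* pair of SEs, so this filter cannot bias the
difference test — and (ii) applies BH at 5% FDR to the survivors'
sex-difference p-values computed in follow-up data alone, one-sided
toward the discovery direction, with m equal to the number of survivors
that have follow-up data. The main-effect filter uses the joint
discovery+follow-up combination by default (`main_effect_stage`
switches to follow-up only). Confirmed SNPs are classified by the
non-primary sex's joint behaviour: CED (nominal, same sign), SSE (not
nominal), OED (nominal, opposite sign). Joint single-sex p < 5×10⁻⁸
(strict) declares genome-wide significance, and the exact binomial sign
test quantifies enrichment of female-larger effects among significant
loci.

### Power

For a 1-df association test the non-centrality parameter is
NCP = n·R²/(1−R²), and power at level α is the noncentral χ²₁ tail
beyond the central χ²₁ quantile. Scan power treats the two sex strata
as independent (disjoint individuals): the sex-specific scan selects
with probability 1−(1−power_m)(1−power_w); the difference scan uses
NCP_diff = (β_m−β_w)²/(se_m²+se_w²−2r·se_m·se_w) with r = 0 unless
supplied; the combined scan uses the pooled contrast. Two-stage
confirmation power is the product of the main-effect and difference
powers — exact, by the orthogonality noted above. FDR-derived
thresholds are treated as fixed α values (e.g. 2×10⁻⁵ for the
discovery scan) rather than re-solving the stochastic BH cut-off; this
matches how such power curves are conventionally presented and is
accurate to leading order when a single true signal dominates the
panel (the BH threshold is then k·α/m with k ≈ 1).

## Synthetic data

`simulate_sumstats` draws, for each study, sex and SNP,
β̂ = β_true + e with e ~ N(0, λ_s·SE²) and SE = 1/√(2·maf_s(1−maf_s)·n)
— under inflation the noise uses the inflated SE while the understated
SE is reported, exactly the artefact GC correction must undo. β_true is
a planted class effect (NULL, CED, SSE_F, SSE_M, OED; default magnitude
0.034, the standardized effect of a signal explaining R² = 0.00057 at
MAF 0.42) plus an optional polygenic background drawn bivariate-normal
across the sexes. Per-study MAFs drift around the population MAF by a
logit-normal jitter (sd 0.05), exercising allele harmonization without
strand complexity. Defaults describe a waist-phenotype-like discovery:
eight studies totalling ~34.6k men and ~43.0k women; with the
background enabled at (sd 0.005, ρ 0.35) the induced between-sex
Spearman correlation of meta betas is ~0.10, mid-range of the 0.04–0.18
observed for anthropometric phenotypes. The background defaults to off
so that null z-scores are exactly standard normal under the default
configuration.

Deliberately not simulated: linkage disequilibrium (pruning is
exercised on map positions, not correlation structure), genotype
imputation (only the reported quality metric), family structure
(cohorts are unrelated individuals), and allele-frequency
stratification between populations. Passing tests therefore demonstrate
the statistical machinery — calibration, FDR control, unbiasedness of
the confirmation stage, power agreement — not robustness to LD-induced
dependence of the concatenated p-values, for which BH is known to be
robust under positive dependence but which these tests do not probe.

`simulate_cohort` generates individual-level traits as
intercept_sex + a1·age + a2·age² + dosage·b + noise with documented
coefficients, supporting recovery tests of the transform-then-regress
path. The rank inverse-normal transform uses (rank−0.5)/n quantiles
with average ranks for ties — the simplest symmetric convention — and
rejects strata with fewer than 3 values or constant input.

## Numerical and design choices

- λ estimation uses scipy's exact χ²₁ median (0.454936...).
- Harmonization drops strand-ambiguous A/T / C/G SNPs with MAF > 0.4
  and flags post-alignment allele-frequency discrepancies > 0.2
  (both thresholds exposed as parameters).
- `bh_fdr` rejects p-values outside (0,1]; simulated p-values are
  clipped away from exact 0 at the floating-point tiny.
- Degenerate difference-test denominators (|r| → 1) are rejected
  rather than clamped.
- Positions are 1-based bp on a single genome build per run; no
  liftover.

## Problem sizes

The simulation experiments run at desk scale, chosen to give
Monte-Carlo standard errors small enough for the assertions they feed:
10⁵ SNPs for calibration KS tests and λ estimation checks, 500
discovery→follow-up replicates for the realized-confirmation-FDR bound,
10⁶ SNPs / 348 selected for the winner's-curse simulation, and 200
replicates of a 1,000-SNP panel (two studies per sex per stage, meta
samples of 16k men / 10k women, one planted women-specific SNP sized
for ~90% selection power at the panel's BH cut-off) for the
pipeline-vs-power comparison. The analytic-vs-Monte-Carlo power
comparisons use 2×10⁴ replicates per grid cell, giving 3-SE bands of
about ±1%.

## Known limitations

- The between-sex correlation plug-in is exactly calibrating only for
  estimate-level correlation (see above); with purely effect-level
  correlation it is mildly liberal.
- The analytic selection-power predictions treat the BH cut-off as
  fixed and the scan and filter events as independent; both are
  leading-order approximations, accurate when the marginal
  probabilities are near one (the regimes tested).
- The pruning provenance records deletions but not the transitive
  chains that would distinguish the two readings of "within 0.2 cM of
  any SNP above"; with dense candidate clusters the retained sets can
  differ between conventions.
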