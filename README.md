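# dimorphscan

Sex-stratified GWAS meta-analysis and sexual-dimorphism screening.

Most genome-wide association studies analyze men and women together,
which is optimal for sex-concordant effects but can hide loci whose
effect differs between the sexes — as repeatedly observed for
fat-distribution traits such as waist-to-hip ratio adjusted for BMI.
`dimorphscan` implements, as a reusable and tested pipeline, the
two-stage screening strategy used to find such loci from study-level
summary statistics:

1. **Per-sex fixed-effect meta-analysis.** Study estimates b_i with
   standard errors se_i are combined per sex with inverse-variance
   weights w_i = 1/se_i², after per-study QC (monomorphic SNPs,
   MAF·N ≤ 3, platform-specific imputation-quality cut-offs) and
   genomic-control correction (SE ← SE·√λ, λ floored at 1, applied
   again at each meta-analysis level — "double GC").
2. **Sex-difference test.** For meta-analyzed estimates β̂_m, β̂_w,

       t = (β̂_m − β̂_w) / √(se_m² + se_w² − 2 r se_m se_w),

   referred to the standard normal, where r is the Spearman rank
   correlation between male and female betas across all SNPs of the
   phenotype (small but positive because of shared polygenic effects).
3. **Two genome-wide scans with FDR control.** The *sex-specific scan*
   concatenates per-sex association p-values across all phenotypes and
   both sexes and applies Benjamini–Hochberg; survivors are pruned to
   independent SNPs (greedy, 0.2 cM window on an interpolated genetic
   map) and filtered for nominal sex-difference (P-diff < 0.05). The
   *sex-difference scan* applies BH to the concatenated P-diff values
   and is the variant with power against opposite-direction effects.
4. **Unbiased follow-up confirmation.** Because candidates are selected
   on sex-specific association, their discovery P-diff is inflated
   (winner's curse). Confirmation therefore filters on a sex-combined
   main effect (p < 0.01, a contrast orthogonal to the difference) and
   tests sex-difference in independent follow-up data alone, one-sided
   toward the discovery direction, with BH at 5% FDR. Joint-stage
   single-sex p < 5×10⁻⁸ declares genome-wide significance, and
   confirmed loci are classified as CED (concordant effect direction),
   SSE (single sex effect) or OED (opposite effect direction).
5. **Design analytics.** Closed-form power for the three scan
   strategies (NCP = n·R²/(1−R²) for a 1-df association test), the
   two-stage confirmation power, and a million-SNP null simulation that
   reproduces the selection-induced inflation the follow-up design
   avoids.

A `synthetic_data` module generates multi-study sex-specific summary
statistics (planted NULL/CED/SSE/OED effects, per-study sampling noise
SE = 1/√(2·MAF·(1−MAF)·n), shared polygenic background, optional λ
inflation) plus small individual-level cohorts with the standard
residual + rank-inverse-normal phenotype transform, so the whole
pipeline runs without external data.

## Worked example

```python
import pandas as pd
from dimorphscan import synthetic_data, meta_analysis, screening

cfg = synthetic_data.SimConfig(
    n_studies=4, n_men=4000, n_women=5000, n_snps=500,
    class_counts={"NULL": 499, "SSE_F": 1},
    effects={"SSE_F": (0.08, 0.0)},  # women-only standardized effect
    seed=42,
)
sim = synthetic_data.simulate_sumstats(cfg)

frames = []
for sex in ("M", "W"):
    meta = meta_analysis.meta_analyze_studies(
        [sim.tables[(f"study{s+1}", sex)] for s in range(4)]
    )
    meta["SEX"], meta["PHENOTYPE"] = sex, "WHRadjBMI"
    frames.append(meta)
meta_long = pd.concat(frames, ignore_index=True)

report = screening.sex_specific_scan(
    meta_long, sim.genetic_map, fdr=0.05, r_by_phenotype=0.0
)
planted = sim.truth.loc[sim.truth["CLASS"] == "SSE_F", "SNP"].item()
print(f"tests: {report.m}, rejected: {report.k}, "
      f"critical p: {report.critical_p:.3g}")
print(report.candidates[["SNP", "SEX", "P", "P_DIFF"]])
print("planted SNP selected:", planted in set(report.candidates["SNP"]))
```

Output:

```
tests: 1000, rejected: 1, critical p: 8.31e-06
     SNP SEX         P    P_DIFF
0  rs290   W  0.000008  0.001117
planted SNP selected: True
```

The scan concatenated 500 SNPs × 2 sexes = 1000 association p-values,
rejected one at 5% FDR (the BH critical p is the largest rejected
p-value), assigned it to women, and kept it as a follow-up candidate
because its discovery sex-difference p (1.1×10⁻³) is below the nominal
0.05 filter — correctly recovering the planted women-specific SNP.

The same stages are scriptable from the shell:

```bash
dimorphscan qc study1_women.tsv --platform MACH --out study1_women_qc.tsv
dimorphscan meta study*_women_qc.tsv --sex W --phenotype WHRadjBMI --out meta_W.tsv
dimorphscan scan --meta-table meta_long.tsv --genetic-map map.tsv --out candidates.tsv
dimorphscan followup --candidates candidates.tsv --discovery meta_long.tsv \
    --followup followup_long.tsv --out confirmed.tsv
```

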