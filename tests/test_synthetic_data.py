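"""Tests of the synthetic summary-statistic and cohort generators."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dimorphscan.power_bias import power_single_test
from dimorphscan.synthetic_data import (
    EffectClass,
    SimConfig,
    simulate_cohort,
    simulate_sumstats,
    transform_phenotype,
)


class TestEffectClass:
    @pytest.mark.parametrize(
        "label,bw,bm",
        [
            ("NULL", 0.0, 0.0),
            ("SSE_F", 0.03, 0.0),
            ("SSE_M", 0.0, 0.03),
            ("CED", 0.03, 0.02),
            ("OED", 0.03, -0.03),
        ],
    )
    def test_valid_patterns(self, label, bw, bm):
        EffectClass(label, beta_women=bw, beta_men=bm)

    @pytest.mark.parametrize(
        "label,bw,bm",
        [
            ("NULL", 0.1, 0.0),
            ("SSE_F", 0.03, 0.01),
            ("CED", 0.03, -0.02),
            ("OED", 0.03, 0.03),
        ],
    )
    def test_invalid_patterns_rejected(self, label, bw, bm):
        with pytest.raises(ValueError):
            EffectClass(label, beta_women=bw, beta_men=bm)


class TestSimulateSumstats:
    def test_null_limit_se_formula(self):
        """At n=1e6, maf=0.3 the SE is 1/sqrt(2*0.3*0.7*1e6) and betas ~ 0."""
        cfg = SimConfig(
            n_studies=1,
            n_men=10**6,
            n_women=10**6,
            n_snps=50,
            class_counts={"NULL": 50},
            maf_range=(0.3, 0.3),
            maf_jitter_sd=0.0,
            seed=0,
        )
        sim = simulate_sumstats(cfg)
        table = sim.tables[("study1", "M")]
        expected_se = 1.0 / np.sqrt(2 * 0.3 * 0.7 * 10**6)
        assert np.allclose(table["SE"], expected_se, rtol=1e-12)
        assert expected_se == pytest.approx(1.543e-3, rel=1e-3)
        assert np.abs(table["BETA"]).max() < 6 * expected_se

    def test_same_seed_identical_tables(self):
        cfg = SimConfig(n_studies=2, n_men=100, n_women=100, n_snps=20,
                        class_counts={"NULL": 20}, seed=7)
        a, b = simulate_sumstats(cfg), simulate_sumstats(cfg)
        for key in a.tables:
            pd.testing.assert_frame_equal(a.tables[key], b.tables[key])
        pd.testing.assert_frame_equal(a.genetic_map, b.genetic_map)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(n_men=0, class_counts={"NULL": 1000})
        with pytest.raises(ValueError):
            SimConfig(maf_range=(0.0, 0.5), class_counts={"NULL": 1000})
        with pytest.raises(ValueError):
            SimConfig(n_snps=10, class_counts={"NULL": 5})

    def test_null_z_scores_standard_normal(self):
        """Under the NULL class beta_hat/SE is standard normal (KS)."""
        cfg = SimConfig(
            n_studies=1, n_men=5000, n_women=5000, n_snps=100_000,
            class_counts={"NULL": 100_000}, seed=5,
        )
        sim = simulate_sumstats(cfg)
        t = sim.tables[("study1", "W")]
        z = t["BETA"] / t["SE"]
        assert stats.kstest(z, "norm").pvalue > 0.01

    def test_lambda_inflates_chi2_median(self):
        """Planted inflation shows up as median(chi2)/0.455 ~ lambda."""
        from dimorphscan.sumstats_io import estimate_lambda

        cfg = SimConfig(
            n_studies=1, n_men=5000, n_women=5000, n_snps=100_000,
            class_counts={"NULL": 100_000}, lambda_per_study=(1.2,), seed=5,
        )
        sim = simulate_sumstats(cfg)
        t = sim.tables[("study1", "M")]
        lam = estimate_lambda(t["BETA"] / t["SE"])
        assert 1.15 <= lam <= 1.25

    def test_mc_power_matches_analytic(self):
        """The fraction of SSE_F replicates passing alpha matches the
        analytic chi-square power within 3 Monte-Carlo SEs.

        Single-study design: 42,969 women, MAF 0.42, R^2 = 0.00057 in
        women, alpha = 2e-5; replicates are iid SNPs of the same class.
        """
        n_rep, maf, r2, n_w, alpha = 2000, 0.42, 0.00057, 42_969, 2e-5
        beta_w = np.sqrt(r2 / (2 * maf * (1 - maf)))
        cfg = SimConfig(
            n_studies=1, n_men=1000, n_women=n_w, n_snps=n_rep,
            class_counts={"SSE_F": n_rep},
            effects={"SSE_F": (beta_w, 0.0)},
            maf_range=(maf, maf), maf_jitter_sd=0.0, seed=13,
        )
        sim = simulate_sumstats(cfg)
        p_w = sim.tables[("study1", "W")]["P"]
        frac = float((p_w < alpha).mean())
        power = power_single_test(n_w * r2, alpha)
        mc_se = np.sqrt(power * (1 - power) / n_rep)
        assert abs(frac - power) < 3 * mc_se

    def test_background_induces_between_sex_correlation(self):
        """Shared polygenic background makes meta betas correlate across
        sexes, increasingly so with rho_background."""
        from dimorphscan.dimorphism import estimate_beta_correlation
        from dimorphscan.meta_analysis import meta_analyze_studies

        def observed_r(rho):
            cfg = SimConfig(
                n_studies=4, n_men=4329, n_women=5371, n_snps=5000,
                class_counts={"NULL": 5000}, rho_background=rho,
                background_sd=0.005, seed=21,
            )
            sim = simulate_sumstats(cfg)
            metas = {}
            for sex in ("M", "W"):
                tabs = [sim.tables[(f"study{s+1}", sex)] for s in range(4)]
                metas[sex] = meta_analyze_studies(tabs)
            return estimate_beta_correlation(
                metas["M"]["BETA"], metas["W"]["BETA"]
            ).r

        r_zero, r_high = observed_r(0.0), observed_r(0.8)
        assert r_high > 0.05
        assert r_high > r_zero + 0.05


class TestTransformPhenotype:
    def test_zscore_moments(self):
        rng = np.random.default_rng(0)
        out = transform_phenotype(rng.gamma(2, 3, 500), trait_kind="height")
        assert abs(out.mean()) < 1e-12
        assert abs(out.std() - 1.0) < 1e-12

    def test_rank_closed_form(self):
        """n=3 distinct values map to the (rank-0.5)/n normal quantiles."""
        out = transform_phenotype(np.array([10.0, -4.0, 3.0]))
        expected = stats.norm.ppf([(3 - 0.5) / 3, (1 - 0.5) / 3, (2 - 0.5) / 3])
        assert np.allclose(np.sort(out), np.sort(expected))
        assert np.allclose(out, expected)  # order preserved through ranks

    def test_rank_ties_get_equal_values(self):
        out = transform_phenotype(np.array([1.0, 2.0, 2.0, 5.0]))
        assert out[1] == out[2]

    def test_monotone_invariance(self):
        rng = np.random.default_rng(4)
        x = rng.lognormal(size=60)
        a = transform_phenotype(x)
        b = transform_phenotype(np.exp(x) + 5)  # strictly monotone map
        assert np.allclose(a, b)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            transform_phenotype(np.ones(10))
        with pytest.raises(ValueError):
            transform_phenotype(np.ones(10), trait_kind="height")

    def test_sex_stratified_residuals(self):
        """Covariate effects are removed within each sex stratum."""
        rng = np.random.default_rng(8)
        n = 600
        sex = np.where(rng.random(n) < 0.5, "M", "W")
        age = rng.uniform(25, 75, n)
        raw = np.where(sex == "M", 5.0, -3.0) + 0.2 * age + rng.normal(0, 1, n)
        out = transform_phenotype(raw, age=age, sex=sex)
        for s in ("M", "W"):
            mask = sex == s
            assert abs(np.corrcoef(out[mask], age[mask])[0, 1]) < 0.1
            assert abs(out[mask].mean()) < 0.05


class TestSimulateCohort:
    def test_reproducible_and_bounded(self):
        a = simulate_cohort(200, seed=9)
        b = simulate_cohort(200, seed=9)
        pd.testing.assert_frame_equal(a.traits, b.traits)
        assert a.dosages.min() >= 0 and a.dosages.max() <= 2
        assert (a.age > 0).all()

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            simulate_cohort(5)

    def test_zero_age_coefficient_gives_uncorrelated_trait(self):
        params = {"height": (170.0, 160.0, 0.0, 0.0, 7.0)}
        sim = simulate_cohort(1000, seed=2, trait_params=params)
        r = np.corrcoef(sim.traits["height"], sim.age)[0, 1]
        assert abs(r) < 0.1

    def test_planted_effect_recovered_with_nominal_coverage(self):
        """Per-SNP regression on the transformed trait recovers the
        standardized planted effect within 2 SEs in >=93% of replicates."""
        b_raw, sd, maf, n = 1.0, 7.0, 0.3, 5000
        params = {"height": (170.0, 160.0, 0.1, -0.001, sd)}
        # planted raw effect standardized by the residual-trait scale
        b_true = b_raw / np.sqrt(b_raw**2 * 2 * maf * (1 - maf) + sd**2)
        covered = 0
        n_rep = 100
        for rep in range(n_rep):
            sim = simulate_cohort(
                n, seed=1000 + rep, n_snps=1, maf=maf,
                genotype_effects={"height": np.array([b_raw])},
                trait_params=params,
            )
            y = transform_phenotype(
                sim.traits["height"].to_numpy(), age=sim.age, sex=sim.sex,
                trait_kind="height",
            )
            g = sim.dosages[:, 0]
            X = np.column_stack([np.ones(n), g])
            coef, res, *_ = np.linalg.lstsq(X, y, rcond=None)
            resid = y - X @ coef
            s2 = resid @ resid / (n - 2)
            se = np.sqrt(s2 / ((g - g.mean()) ** 2).sum())
            if abs(coef[1] - b_true) < 2 * se:
                covered += 1
        assert covered >= 93
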