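"""Tests of FDR selection, cM interpolation/pruning, scans and confirmation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dimorphscan import datasets
from dimorphscan.screening import (
    GeneticMap,
    bh_fdr,
    confirm_from_pvalues,
    declare_gws,
    followup_confirm,
    interpolate_cm,
    prune_independent,
    sex_difference_scan,
    sex_specific_scan,
)

from conftest import make_meta_long


def brute_force_bh(p, alpha):
    """Independent hand implementation of the step-up rule."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p)
    k = 0
    for i in range(m, 0, -1):
        if p[order[i - 1]] <= i * alpha / m:
            k = i
            break
    reject = np.zeros(m, dtype=bool)
    reject[order[:k]] = True
    return reject, k, (float(p[order[k - 1]]) if k else None)


class TestBhFdr:
    def test_hand_example_all_rejected(self):
        reject, k, crit = bh_fdr([0.001, 0.02, 0.04], alpha=0.05)
        assert reject.all() and k == 3
        assert crit == pytest.approx(0.04)

    def test_nothing_rejected(self):
        reject, k, crit = bh_fdr([0.9, 0.9, 0.9], alpha=0.05)
        assert not reject.any() and k == 0 and crit is None

    def test_published_followup_panel(self):
        """The seven published one-sided follow-up sex-difference p-values
        among 74 main-effect survivors give exactly 7 rejections with
        critical p 4.22e-3."""
        panel = datasets.followup_pdiff_panel()
        assert panel.size == 74
        reject, k, crit = bh_fdr(panel, alpha=0.05)
        assert k == 7
        assert crit == pytest.approx(4.22e-3, rel=1e-3)
        assert reject[:7].all() and not reject[7:].any()

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(123)
        for _ in range(300):
            m = rng.integers(1, 50)
            p = rng.uniform(1e-6, 1.0, m) ** rng.uniform(0.5, 3.0)
            alpha = rng.uniform(0.01, 0.3)
            got = bh_fdr(p, alpha)
            want = brute_force_bh(p, alpha)
            assert np.array_equal(got[0], want[0])
            assert got[1] == want[1]
            if want[2] is None:
                assert got[2] is None
            else:
                assert got[2] == pytest.approx(want[2])

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([], 0.05)
        with pytest.raises(ValueError):
            bh_fdr([0.5], 1.5)
        with pytest.raises(ValueError):
            bh_fdr([0.0, 0.5], 0.05)


class TestInterpolateCm:
    MAP = pd.DataFrame({"CHR": [1, 1], "POS": [100, 300], "CM": [1.0, 2.0]})

    def test_midpoint(self):
        assert interpolate_cm([200], self.MAP)[0] == pytest.approx(1.5)

    def test_inverse_distance_weighting(self):
        # (1.0/50 + 2.0/150) / (1/50 + 1/150) = 1.25
        assert interpolate_cm([150], self.MAP)[0] == pytest.approx(1.25)

    def test_exact_map_point(self):
        assert interpolate_cm([300], self.MAP)[0] == pytest.approx(2.0)

    def test_outside_span_takes_nearest(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="dimorphscan.screening"):
            out = interpolate_cm([50, 400], self.MAP)
        assert out[0] == pytest.approx(1.0)
        assert out[1] == pytest.approx(2.0)
        assert "outside the map span" in caplog.text

    def test_unknown_chromosome_rejected(self):
        with pytest.raises(KeyError):
            GeneticMap(self.MAP).interpolate(7, [100])


class TestPrune:
    def _frame(self, cms, ps, chroms=None):
        n = len(cms)
        return pd.DataFrame(
            {
                "SNP": [f"rs{i}" for i in range(n)],
                "CHR": chroms if chroms is not None else [1] * n,
                "CM": cms,
                "P": ps,
            }
        )

    def test_hand_sweep(self):
        frame = self._frame([10.00, 10.15, 10.45], [1e-8, 1e-6, 1e-5])
        kept, log = prune_independent(frame)
        assert list(kept["SNP"]) == ["rs0", "rs2"]
        assert len(log) == 1

    def test_dense_cluster_keeps_best_only(self):
        frame = self._frame([5.00, 5.05, 5.08], [1e-4, 1e-9, 1e-6])
        kept, _ = prune_independent(frame)
        assert list(kept["SNP"]) == ["rs1"]

    def test_chromosome_guard(self):
        frame = self._frame([1.00, 1.01], [1e-8, 1e-7], chroms=[1, 2])
        kept, _ = prune_independent(frame)
        assert len(kept) == 2

    def test_missing_cm_is_hard_failure(self):
        frame = self._frame([1.0, np.nan], [1e-8, 1e-7])
        with pytest.raises(ValueError, match="rs1"):
            prune_independent(frame)

    def test_no_retained_pair_within_window(self):
        rng = np.random.default_rng(5)
        frame = self._frame(
            rng.uniform(0, 10, 200),
            rng.uniform(0, 1, 200),
            chroms=rng.integers(1, 4, 200),
        )
        kept, _ = prune_independent(frame, window_cm=0.2)
        for chrom, grp in kept.groupby("CHR"):
            cms = np.sort(grp["CM"].to_numpy())
            assert (np.diff(cms) >= 0.2).all()


def _flat_map():
    return pd.DataFrame(
        {
            "CHR": np.repeat(np.arange(1, 23), 2),
            "POS": np.tile([0, 200_000_000], 22),
            "CM": np.tile([0.0, 200.0], 22),
        }
    )


class TestScans:
    def test_global_null_rarely_selects(self):
        """Under the global null both scans select nothing in >=90% of
        seeds (BH family-wise behaviour under independence)."""
        zeros = np.zeros(2000)
        n_empty_spec = n_empty_diff = 0
        n_seeds = 20
        rng = np.random.default_rng(42)
        for _ in range(n_seeds):
            long = pd.concat(
                [
                    make_meta_long(rng, zeros, zeros, 0.01, 0.01, "WHRadjBMI"),
                    make_meta_long(rng, zeros, zeros, 0.01, 0.01, "height"),
                ],
                ignore_index=True,
            )
            spec = sex_specific_scan(long, _flat_map(), r_by_phenotype=0.0)
            diff = sex_difference_scan(long, _flat_map(), r_by_phenotype=0.0)
            n_empty_spec += spec.k == 0
            n_empty_diff += diff.k == 0
        assert n_empty_spec >= 0.9 * n_seeds
        assert n_empty_diff >= 0.9 * n_seeds

    def test_planted_sse_selected_and_reported(self):
        rng = np.random.default_rng(7)
        true_w = np.zeros(500)
        true_w[100] = 0.08  # z ~ 8 in women
        long = make_meta_long(rng, np.zeros(500), true_w, 0.01, 0.01)
        report = sex_specific_scan(long, _flat_map(), r_by_phenotype=0.0)
        assert report.m == 1000  # 500 SNPs x 2 sexes
        assert "rs100" in set(report.candidates["SNP"])
        row = report.candidates.set_index("SNP").loc["rs100"]
        assert row["SEX"] == "W"
        assert row["P_DIFF"] < 0.05
        assert report.critical_p == pytest.approx(
            report.selected["P"].max()
        )

    def test_planted_ced_removed_by_pdiff_filter(self):
        """A strong concordant equal-effect signal passes FDR in both
        sexes but fails the nominal sex-difference filter."""
        rng = np.random.default_rng(8)
        true = np.zeros(500)
        true[50] = 0.08
        removed = 0
        n_seeds = 40
        for _ in range(n_seeds):
            long = make_meta_long(rng, true, true, 0.01, 0.01)
            report = sex_specific_scan(long, _flat_map(), r_by_phenotype=0.0)
            selected_fdr = "rs50" in set(report.independent["SNP"])
            in_candidates = "rs50" in set(report.candidates["SNP"])
            assert selected_fdr  # power ~ 1 at z ~ 8
            removed += not in_candidates
        # the null-difference filter keeps ~alpha = 5% of seeds
        assert removed >= 0.85 * n_seeds

    def test_planted_oed_found_by_difference_scan(self):
        rng = np.random.default_rng(9)
        true_m = np.zeros(500)
        true_w = np.zeros(500)
        true_m[10], true_w[10] = 0.06, -0.06  # difference z ~ 8.5
        long = make_meta_long(rng, true_m, true_w, 0.01, 0.01)
        report = sex_difference_scan(long, _flat_map(), r_by_phenotype=0.0)
        assert "rs10" in set(report.independent["SNP"])


class TestFollowupConfirm:
    def _longs(self, rng, true_m, true_w, se=0.012):
        disc = make_meta_long(rng, true_m, true_w, se, se)
        fu = make_meta_long(rng, true_m, true_w, se, se)
        return disc, fu

    def test_weak_main_effect_excluded_before_difference_test(self):
        rng = np.random.default_rng(11)
        true_w = np.zeros(50)
        true_w[3] = 0.2  # strong women-only signal
        disc, fu = self._longs(rng, np.zeros(50), true_w)
        candidates = pd.DataFrame(
            {"SNP": ["rs3", "rs20"], "PHENOTYPE": "WHRadjBMI"}
        )
        report = followup_confirm(candidates, disc, fu)
        # rs20 is null: joint combined p >> 0.01, never reaches the BH step
        assert report.m == 1
        assert set(report.table["SNP"]) == {"rs3"}
        assert report.k == 1
        assert report.table.iloc[0]["CLASS"] == "SSE"

    def test_candidate_missing_from_followup_reported(self):
        rng = np.random.default_rng(12)
        true_w = np.zeros(50)
        true_w[3] = 0.2
        disc, fu = self._longs(rng, np.zeros(50), true_w)
        fu = fu[fu["SNP"] != "rs3"]
        candidates = pd.DataFrame({"SNP": ["rs3"], "PHENOTYPE": "WHRadjBMI"})
        report = followup_confirm(candidates, disc, fu)
        assert report.excluded == ["rs3"]
        assert report.m == 0 and report.k == 0

    def test_published_panel_confirms_seven(self):
        reject, k, crit = confirm_from_pvalues(datasets.followup_pdiff_panel())
        assert k == 7
        assert crit == pytest.approx(4.22e-3, rel=1e-3)

    def test_ced_classification_on_shared_signal(self):
        rng = np.random.default_rng(14)
        true_m = np.zeros(50)
        true_w = np.zeros(50)
        true_m[5], true_w[5] = 0.06, 0.2  # women-dominant, men nominal
        disc, fu = self._longs(rng, true_m, true_w)
        candidates = pd.DataFrame({"SNP": ["rs5"], "PHENOTYPE": "WHRadjBMI"})
        report = followup_confirm(candidates, disc, fu)
        assert report.k == 1
        assert report.table.iloc[0]["CLASS"] == "CED"
        assert report.table.iloc[0]["PRIMARY_SEX"] == "W"


class TestDeclareGws:
    def test_published_joint_women_pvalues(self):
        seven = datasets.seven_loci()
        flags = declare_gws(seven["JOINT_P_WOMEN"])
        assert flags.all()  # all seven genome-wide significant in women
        assert not declare_gws(seven["JOINT_P_MEN"]).any()

    def test_strict_boundary(self):
        assert not declare_gws([5e-8])[0]
        assert declare_gws([4.99e-8])[0]
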