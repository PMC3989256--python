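import numpy as np
import pandas as pd
import pytest

from sweepscan.sitefreq_scan import AlleleCounts
from sweepscan.regions import (
    SelectionRegion,
    Threshold,
    autosomal_cutoff,
    build_regions,
    flag_outliers,
    flag_windows,
    merge_regions,
    normal_critical_value,
    overlap_matrix,
    permutation_threshold,
    quantile_value,
)


class TestAutosomalCutoff:
    def test_interpolated_quantile(self):
        thr = autosomal_cutoff(np.arange(1, 101, dtype=float), 0.05, two_sided=False)
        assert thr.upper == pytest.approx(95.05)
        assert thr.lower is None

    def test_two_sided_symmetric(self):
        scores = np.concatenate([-np.arange(1, 201), np.arange(1, 201)])
        thr = autosomal_cutoff(scores, 0.05, two_sided=True)
        assert thr.upper == pytest.approx(-thr.lower)

    def test_fraction_one_flags_everything(self):
        scores = np.arange(1, 201, dtype=float)
        thr = autosomal_cutoff(scores, 1.0, two_sided=False)
        assert thr.upper == pytest.approx(scores.min())

    def test_too_few_scores(self):
        with pytest.raises(ValueError):
            autosomal_cutoff(np.arange(50), 0.05)


class TestNormalCriticalValue:
    def test_two_sided_five_percent(self):
        assert normal_critical_value(0.05) == pytest.approx(1.96, abs=5e-3)


class TestPermutationThreshold:
    def _counts(self, seed=0, S=60, n=40):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, n + 1, size=(2, S))
        return AlleleCounts(x, np.full((2, S), n))

    def test_deterministic_under_seed(self):
        counts = self._counts()
        a = permutation_threshold("fst", counts=counts, n_perm=200, seed=5, n_draws=100)
        b = permutation_threshold("fst", counts=counts, n_perm=200, seed=5, n_draws=100)
        assert a.upper == b.upper

    def test_tajd_two_tailed(self):
        rng = np.random.default_rng(2)
        pos = np.sort(rng.choice(np.arange(1, 4_000_000), 60, replace=False))
        x = rng.integers(0, 41, size=60)
        thr = permutation_threshold("tajd", x=x, n=40, pos_bp=pos,
                                    n_perm=200, seed=3)
        assert thr.lower is not None and thr.upper is not None
        assert thr.lower < thr.upper

    def test_requires_enough_permutations(self):
        with pytest.raises(ValueError):
            permutation_threshold("fst", counts=self._counts(), n_perm=10)


class TestFlagOutliers:
    def _track(self, scores):
        return pd.DataFrame({
            "chrom": "X", "pos_bp": (np.arange(len(scores)) + 1) * 1000,
            "snp_id": [f"s{i}" for i in range(len(scores))],
            "raw_score": scores,
        })

    def test_nothing_beyond_cutoff(self):
        thr = Threshold("m", None, 5.0, "autosome_top_fraction")
        assert flag_outliers(self._track([1.0, 2.0]), thr).empty

    def test_signed_partition_for_xpehh(self):
        thr = Threshold("xpehh", -2.0, 2.0, "autosome_top_fraction")
        out = flag_outliers(self._track([2.5, -2.5, 0.0]), thr,
                            signed_populations=("obs", "ref"))
        assert out["population"].tolist() == ["obs", "ref"]

    def test_exact_tie_not_flagged(self):
        thr = Threshold("m", None, 2.0, "autosome_top_fraction")
        assert flag_outliers(self._track([2.0, 2.0001]), thr)["snp_id"].tolist() == ["s1"]


class TestBuildRegions:
    def _flagged(self, positions, scores=None):
        scores = scores if scores is not None else np.ones(len(positions))
        return pd.DataFrame({
            "chrom": "X", "pos_bp": positions,
            "snp_id": [f"s{i}" for i in range(len(positions))],
            "raw_score": scores,
        })

    def test_single_outlier_800kb_region(self):
        regs = build_regions(self._flagged([10_000_000]), "m", "p")
        assert (regs[0].start, regs[0].end) == (9_600_000, 10_400_000)
        assert regs[0].length_bp == 800_000

    def test_close_outliers_merge(self):
        regs = build_regions(self._flagged([10_000_000, 10_300_000]), "m", "p")
        assert len(regs) == 1
        assert regs[0].length_bp == 1_100_000

    def test_distant_outliers_stay_separate(self):
        regs = build_regions(self._flagged([10_000_000, 10_900_000]), "m", "p")
        assert len(regs) == 2

    def test_clipped_at_chromosome_bounds(self):
        regs = build_regions(self._flagged([100_000]), "m", "p",
                             chrom_length=20_000_000)
        assert regs[0].start == 0

    def test_peak_is_max_absolute_score(self):
        regs = build_regions(self._flagged([1_000_000, 1_200_000], [-3.0, 2.0]),
                             "m", "p")
        assert regs[0].peak_score == -3.0

    def test_merged_regions_disjoint_and_sorted(self):
        rng = np.random.default_rng(0)
        pos = np.sort(rng.choice(np.arange(1, 20_000_000), 40, replace=False))
        regs = build_regions(self._flagged(pos), "m", "p")
        for a, b in zip(regs, regs[1:]):
            assert a.end < b.start

    def test_idempotent_through_merge_regions(self):
        rng = np.random.default_rng(1)
        pos = np.sort(rng.choice(np.arange(1, 20_000_000), 30, replace=False))
        regs = build_regions(self._flagged(pos), "m", "p")
        again = merge_regions(regs, "m", "p")
        assert [(r.start, r.end) for r in again] == [(r.start, r.end) for r in regs]


class TestFlagWindows:
    def _wtrack(self, maxima):
        n = len(maxima)
        return pd.DataFrame({
            "chrom": "X",
            "start": np.arange(n) * 800_000,
            "end": (np.arange(n) + 1) * 800_000,
            "n_snps": 5,
            "value_max": maxima,
            "value_min": maxima,
        })

    def test_single_exceeding_window(self):
        thr = Threshold("fst", None, 0.5, "permutation")
        regs = flag_windows(self._wtrack([0.1, 0.9, 0.2]), thr, "fst", "p")
        assert len(regs) == 1
        assert regs[0].length_bp == 800_000

    def test_adjacent_windows_not_merged(self):
        thr = Threshold("fst", None, 0.5, "permutation")
        regs = flag_windows(self._wtrack([0.9, 0.8]), thr, "fst", "p")
        assert len(regs) == 2
        assert all(r.length_bp == 800_000 for r in regs)

    def test_no_exceedance_empty(self):
        thr = Threshold("fst", None, 0.95, "permutation")
        assert flag_windows(self._wtrack([0.1, 0.2]), thr, "fst", "p") == []


class TestQuantileValue:
    def test_median(self):
        assert quantile_value(3.0, [1, 2, 3, 4, 5]) == pytest.approx(0.6)

    def test_maximum(self):
        assert quantile_value(5.0, [1, 2, 3, 4, 5]) == 1.0

    def test_rank_convention(self):
        assert quantile_value(971, np.arange(1, 1001)) == pytest.approx(0.971)


class TestOverlapMatrix:
    def _regions(self, intervals, method):
        return [SelectionRegion("X", s, e, method, "p", 1.0) for s, e in intervals]

    def test_identical_sets(self):
        a = self._regions([(0, 10_000_000)], "a")
        b = self._regions([(0, 10_000_000)], "b")
        mat = overlap_matrix({"a": a, "b": b})
        assert mat.loc["a", "b"] == mat.loc["a", "a"] == 10.0

    def test_disjoint_sets(self):
        mat = overlap_matrix({
            "a": self._regions([(0, 1_000_000)], "a"),
            "b": self._regions([(2_000_000, 3_000_000)], "b"),
        })
        assert mat.loc["a", "b"] == 0.0

    def test_partial_overlap_hand_value(self):
        mat = overlap_matrix({
            "a": self._regions([(0, 10_000_000)], "a"),
            "b": self._regions([(5_000_000, 12_000_000)], "b"),
        })
        assert mat.loc["a", "b"] == pytest.approx(5.0)
        assert mat.loc["b", "a"] == mat.loc["a", "b"]

    def test_offdiag_bounded_by_diagonals(self):
        rng = np.random.default_rng(6)
        sets = {}
        for m in "abc":
            starts = np.sort(rng.choice(np.arange(0, 19_000_000, 100_000), 5, replace=False))
            sets[m] = self._regions([(int(s), int(s) + 900_000) for s in starts], m)
        mat = overlap_matrix(sets)
        for i in "abc":
            for j in "abc":
                if i != j:
                    assert mat.loc[i, j] <= min(mat.loc[i, i], mat.loc[j, j]) + 1e-12
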