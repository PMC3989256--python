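import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from sweepscan.containers import HaplotypeSet, ScoreTrack
from sweepscan.haplotype_scan import (
    EHHCurve,
    ehh_at,
    ehh_curve,
    ehh_curves,
    ihs_raw,
    ihs_track,
    integrate_ihh,
    standardize_scores,
    xpehh_raw,
)
from .conftest import make_map


def ehh_oracle(matrix, rows, lo, hi):
    """Brute force: enumerate all pairs of carrier haplotypes and count
    exact matches over the [lo, hi] SNP span."""
    rows = list(rows)
    if len(rows) < 2:
        return np.nan
    matches = sum(
        1 for a, b in itertools.combinations(rows, 2)
        if (matrix[a, lo:hi + 1] == matrix[b, lo:hi + 1]).all()
    )
    return matches / (len(rows) * (len(rows) - 1) / 2)


class TestEhhAt:
    def test_identical_extended_haplotypes(self):
        H = np.zeros((4, 3), dtype=np.uint8)
        H[:, 0] = 1
        hs = HaplotypeSet("p", H)
        assert ehh_at(hs, 0, 2, core_allele=1) == 1.0

    def test_partial_sharing_counts_pairs(self):
        # carriers' extended haplotypes {00, 00, 01, 10}: 1 identical pair of 6
        H = np.array([[1, 0, 0], [1, 0, 0], [1, 0, 1], [1, 1, 0]], dtype=np.uint8)
        hs = HaplotypeSet("p", H)
        assert ehh_at(hs, 0, 2, core_allele=1) == pytest.approx(1 / 6)

    def test_all_distinct(self):
        H = np.array([[1, 0, 0], [1, 0, 1], [1, 1, 0], [1, 1, 1]], dtype=np.uint8)
        hs = HaplotypeSet("p", H)
        assert ehh_at(hs, 0, 2, core_allele=1) == 0.0

    def test_single_carrier_undefined(self):
        H = np.array([[1, 0], [0, 0], [0, 1]], dtype=np.uint8)
        hs = HaplotypeSet("p", H)
        assert np.isnan(ehh_at(hs, 0, 1, core_allele=1))

    def test_matches_pair_enumeration_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            n_h = int(rng.integers(2, 13))
            n_s = int(rng.integers(2, 11))
            H = rng.integers(0, 2, size=(n_h, n_s)).astype(np.uint8)
            hs = HaplotypeSet("p", H)
            core = int(rng.integers(0, n_s))
            target = int(rng.integers(0, n_s))
            allele = int(rng.integers(0, 2))
            rows = np.flatnonzero(H[:, core] == allele)
            lo, hi = min(core, target), max(core, target)
            want = ehh_oracle(H, rows, lo, hi)
            got = ehh_at(hs, core, target, core_allele=allele)
            if np.isnan(want):
                assert np.isnan(got)
            else:
                assert got == pytest.approx(want)


class TestEhhCurve:
    def test_core_at_chromosome_end(self):
        rng = np.random.default_rng(0)
        H = rng.integers(0, 2, size=(6, 5)).astype(np.uint8)
        hs = HaplotypeSet("p", H)
        pos_cm = np.arange(5) * 0.1
        left = ehh_curve(hs, pos_cm, 0, side="left")
        assert left.distances_cm.tolist() == [0.0]
        assert left.values.tolist() == [1.0]
        assert left.stop_reason == "chrom_end"

    def test_truncation_keeps_boundary_point(self):
        # construct decay 1 -> high -> below threshold within 3 SNPs
        H = np.array([
            [0, 0, 0, 0], [0, 0, 1, 1], [0, 1, 0, 1],
            [0, 1, 1, 0], [0, 1, 1, 1], [0, 0, 0, 1],
        ], dtype=np.uint8)
        hs = HaplotypeSet("p", H)
        curve = ehh_curve(hs, np.arange(4) * 0.1, 0, core_allele=0,
                          side="right", truncation=0.05)
        assert curve.stop_reason == "truncated"
        assert curve.values[-1] < 0.05  # the first sub-threshold value is kept

    def test_homozygous_population_constant_one(self):
        H = np.tile(np.array([0, 1, 0, 1, 1], dtype=np.uint8), (5, 1))
        hs = HaplotypeSet("p", H)
        curve = ehh_curve(hs, np.arange(5) * 0.5, 2, side="right",
                          max_extend_cm=0.6)
        assert (curve.values == 1.0).all()
        assert curve.stop_reason == "max_extend"

    def test_monotone_non_increasing(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            H = rng.integers(0, 2, size=(12, 15)).astype(np.uint8)
            hs = HaplotypeSet("p", H)
            core = int(rng.integers(0, 15))
            for side in ("left", "right"):
                c = ehh_curve(hs, np.arange(15) * 0.05, core, side=side,
                              truncation=0.0)
                assert (np.diff(c.values) <= 1e-12).all()


class TestIntegrateIhh:
    def test_hand_trapezoid(self):
        left = EHHCurve(0, "left", np.array([0.0]), np.array([1.0]), None, "chrom_end")
        right = EHHCurve(0, "right", np.array([0.0, 0.1, 0.2]),
                         np.array([1.0, 0.5, 0.0]), None, "truncated")
        assert integrate_ihh(left, right) == pytest.approx(0.100)

    def test_core_only_is_zero(self):
        point = lambda side: EHHCurve(0, side, np.array([0.0]), np.array([1.0]), None, "chrom_end")
        assert integrate_ihh(point("left"), point("right")) == 0.0

    def test_linear_in_distance_scale(self):
        d = np.array([0.0, 0.2, 0.5])
        v = np.array([1.0, 0.6, 0.1])
        one = EHHCurve(0, "right", d, v, None, "truncated")
        two = EHHCurve(0, "right", 2 * d, v, None, "truncated")
        point = EHHCurve(0, "left", np.array([0.0]), np.array([1.0]), None, "chrom_end")
        assert integrate_ihh(point, two) == pytest.approx(2 * integrate_ihh(point, one))


class TestRawScores:
    def test_equal_integrals_zero(self):
        assert xpehh_raw(0.2, 0.2) == 0.0
        assert ihs_raw(0.3, 0.3) == 0.0

    def test_log_identity(self):
        assert xpehh_raw(0.2 * np.e, 0.2) == pytest.approx(1.0)

    def test_negative_points_at_reference_population(self):
        assert xpehh_raw(0.1, 0.4) < 0

    def test_zero_integral_flagged_missing(self):
        assert np.isnan(xpehh_raw(0.0, 0.2))
        assert np.isnan(ihs_raw(0.5, 0.0))

    @given(a=st.floats(1e-6, 1e3), b=st.floats(1e-6, 1e3))
    @settings(max_examples=100, deadline=None)
    def test_xpehh_antisymmetry(self, a, b):
        assert xpehh_raw(a, b) == pytest.approx(-xpehh_raw(b, a), abs=1e-12)

    def test_ihs_sign_flips_with_polarization(self):
        rng = np.random.default_rng(5)
        H = rng.integers(0, 2, size=(20, 11)).astype(np.uint8)
        hs = HaplotypeSet("p", H)
        pos_cm = np.arange(11) * 0.1
        ihh_by_allele = {}
        for allele in (0, 1):
            l, r = ehh_curves(hs, pos_cm, 5, core_allele=allele)
            ihh_by_allele[allele] = integrate_ihh(l, r)
        fwd = ihs_raw(ihh_by_allele[0], ihh_by_allele[1])
        rev = ihs_raw(ihh_by_allele[1], ihh_by_allele[0])
        assert fwd == pytest.approx(-rev)

    def test_constructed_sweep_gives_negative_ihs(self):
        # derived carriers share one long haplotype; ancestral ones are diverse
        rng = np.random.default_rng(0)
        H = rng.integers(0, 2, size=(40, 21)).astype(np.uint8)
        H[0:20] = H[0]
        H[0:20, 10] = 1
        H[20:, 10] = 0
        hs = HaplotypeSet("p", H, np.ones(21, dtype=bool))
        track = ihs_track(hs, make_map(21)).data
        assert track.loc[track.snp_id == "X_s11", "raw_score"].iloc[0] < -1


class TestStandardize:
    def _track(self, raw, daf=None):
        df = pd.DataFrame({
            "chrom": "X", "pos_bp": np.arange(len(raw)) + 1,
            "snp_id": [f"s{i}" for i in range(len(raw))],
            "raw_score": raw,
        })
        if daf is not None:
            df["daf"] = daf
        return ScoreTrack("ihs", "p", df)

    def test_global_mode_is_classic_zscore(self):
        raw = np.array([1.0, 2.0, 3.0, 4.0])
        out = standardize_scores(self._track(raw), mode="global").data
        assert out["std_score"].mean() == pytest.approx(0.0, abs=1e-12)
        assert out["std_score"].std(ddof=0) == pytest.approx(1.0)

    def test_freq_bins_zero_mean_unit_sd_within_bins(self):
        rng = np.random.default_rng(2)
        raw = rng.normal(size=200)
        daf = rng.uniform(0.05, 0.95, size=200)
        out = standardize_scores(self._track(raw, daf), mode="freq_bins",
                                 bin_width=0.25, min_bin_count=20).data
        bins = np.floor(out["daf"] / 0.25).astype(int)
        for b in np.unique(bins):
            grp = out.loc[bins == b, "std_score"]
            if len(grp) >= 20:
                assert abs(grp.mean()) < 0.3  # bins may have merged neighbours

    def test_small_bins_merge(self):
        raw = np.arange(30, dtype=float)
        daf = np.concatenate([np.full(28, 0.5), [0.05, 0.95]])  # two singleton bins
        out = standardize_scores(self._track(raw, daf), mode="freq_bins").data
        assert not out["std_score"].isna().any()

    def test_zero_variance_bin_errors(self):
        with pytest.raises(ValueError, match="zero variance"):
            standardize_scores(self._track(np.ones(10)), mode="global")

    def test_reference_standardization(self):
        # standardizing against an external reference leaves input rows scaled
        # by the reference's moments
        ref = self._track(np.array([0.0, 2.0] * 50)).data
        out = standardize_scores(self._track(np.array([1.0, 3.0])), mode="global",
                                 reference=ref).data
        # reference mean ~1.0, sd ~1.0 (combined with the 2 input rows)
        assert out["std_score"].iloc[1] > out["std_score"].iloc[0]
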