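import math

import numpy as np
import pytest
from scipy.stats import binom, norm

from sweepscan.containers import HaplotypeSet
from sweepscan.xpclr_scan import (
    XpclrModel,
    estimate_omega,
    ld_weights,
    neutral_loglik,
    sweep_loglik,
    xpclr_scan,
    xpclr_window,
)
from .conftest import make_map


def drift_sim(p_ref, omega, n_snps, rng):
    """Binomial-free drift oracle: truncated-normal frequency change with
    boundary absorption, the generating model of the neutral density."""
    sd = np.sqrt(omega * p_ref * (1 - p_ref))
    q = rng.normal(p_ref, sd)
    return np.clip(q, 0, 1)


class TestEstimateOmega:
    def test_identical_populations_error(self):
        p = np.random.default_rng(0).uniform(0.1, 0.9, 300)
        with pytest.raises(ValueError, match="identical"):
            estimate_omega(p, p)

    def test_recovers_known_omega(self):
        rng = np.random.default_rng(8)
        omega = 0.05
        p_ref = rng.uniform(0.1, 0.9, 2000)
        q = drift_sim(p_ref, omega, 2000, rng)
        ok = (q > 0) & (q < 1)
        est = estimate_omega(p_ref[ok], q[ok])
        assert est == pytest.approx(omega, rel=0.2)

    def test_doubling_drift_doubles_omega(self):
        rng = np.random.default_rng(9)
        p_ref = rng.uniform(0.2, 0.8, 2000)
        est = []
        for omega in (0.02, 0.04):
            q = drift_sim(p_ref, omega, 2000, rng)
            ok = (q > 0) & (q < 1)
            est.append(estimate_omega(p_ref[ok], q[ok]))
        assert est[1] / est[0] == pytest.approx(2.0, rel=0.25)

    def test_too_few_snps(self):
        with pytest.raises(ValueError, match="need >="):
            estimate_omega([0.5] * 10, [0.6] * 10)


class TestNeutralLoglik:
    def test_small_omega_tends_to_binomial(self):
        ll = neutral_loglik(7, 20, 0.35, omega=1e-12)
        assert ll == pytest.approx(binom.logpmf(7, 20, 0.35), abs=1e-6)

    def test_mirror_symmetry(self):
        a = neutral_loglik(3, 25, 0.2, 0.08)
        b = neutral_loglik(22, 25, 0.8, 0.08)
        assert a == pytest.approx(b, rel=1e-9)

    def test_quadrature_self_convergence(self):
        coarse = neutral_loglik(12, 40, 0.4, 0.05, n_quad=201)
        fine = neutral_loglik(12, 40, 0.4, 0.05, n_quad=402)
        assert abs(fine - coarse) < 1e-4

    def test_against_numerical_oracle(self):
        # independent quadrature with scipy's truncnorm + explicit atoms
        count, n, p, omega = 5, 30, 0.3, 0.06
        sd = math.sqrt(omega * p * (1 - p))
        qs = np.linspace(1e-12, 1 - 1e-12, 20001)
        dens = norm.pdf(qs, p, sd)
        lik = np.trapezoid(binom.pmf(count, n, qs) * dens, qs)
        lik += norm.cdf(0, p, sd) * (count == 0) + norm.sf(1, p, sd) * (count == n)
        assert neutral_loglik(count, n, p, omega) == pytest.approx(math.log(lik), abs=1e-4)


class TestSweepLoglik:
    def test_s_zero_embeds_neutral(self):
        for count in (0, 5, 20):
            assert sweep_loglik(count, 20, 0.3, 0.05, s=0.0, r_cm=0.2) == pytest.approx(
                neutral_loglik(count, 20, 0.3, 0.05))

    def test_r_zero_large_s_boundary_dominated(self):
        # at the sweep centre a fixed count is far more likely than under drift
        ll_fixed = sweep_loglik(20, 20, 0.3, 0.01, s=0.5, r_cm=0.0)
        ll_neutral_fixed = neutral_loglik(20, 20, 0.3, 0.01)
        assert ll_fixed > ll_neutral_fixed

    def test_escape_monotone_in_r_and_s(self):
        rho = math.log(200.0)
        c = lambda r, s: 1 - math.exp(-rho * (r / 100) / s)
        rs = [0.01, 0.1, 0.5, 2.0]
        assert all(c(a, 0.05) < c(b, 0.05) for a, b in zip(rs, rs[1:]))
        ss = [0.01, 0.05, 0.2]
        assert all(c(0.5, a) > c(0.5, b) for a, b in zip(ss, ss[1:]))


class TestLdWeights:
    def _hapset(self, cols):
        return HaplotypeSet("ref", np.array(cols, dtype=np.uint8).T)

    def test_independent_snps_weight_one(self):
        rng = np.random.default_rng(3)
        H = rng.integers(0, 2, size=(400, 5)).astype(np.uint8)
        w = ld_weights(HaplotypeSet("r", H), np.arange(5), r2_cutoff=0.95)
        assert (w == 1.0).all()

    def test_perfectly_correlated_triplet(self):
        base = np.random.default_rng(0).integers(0, 2, 30)
        H = np.column_stack([base, base, base, 1 - base[::-1]]).astype(np.uint8)
        w = ld_weights(HaplotypeSet("r", H), np.arange(4))
        assert w[:3].tolist() == [pytest.approx(1 / 3)] * 3

    def test_weight_sum_equals_group_count(self):
        rng = np.random.default_rng(5)
        base = rng.integers(0, 2, 50)
        other = rng.integers(0, 2, 50)
        H = np.column_stack([base, base, other]).astype(np.uint8)
        w = ld_weights(HaplotypeSet("r", H), np.arange(3))
        assert w.sum() == pytest.approx(2.0)


class TestXpclrWindow:
    def test_null_grid_gives_zero(self):
        rng = np.random.default_rng(1)
        model = XpclrModel(omega=0.05, s_grid=np.array([0.0]))
        counts = rng.integers(0, 41, size=8)
        clr, s_hat = xpclr_window(counts, 40, rng.uniform(0.2, 0.8, 8),
                                  rng.uniform(0, 0.25, 8), np.ones(8), model)
        assert clr == 0.0
        assert s_hat == 0.0

    def test_clr_never_negative(self):
        rng = np.random.default_rng(2)
        model = XpclrModel(omega=0.08)
        for _ in range(20):
            k = int(rng.integers(3, 12))
            clr, _ = xpclr_window(
                rng.integers(0, 41, size=k), 40, rng.uniform(0.05, 0.95, k),
                rng.uniform(0, 0.25, k), np.ones(k), model)
            assert clr >= 0.0

    def test_too_few_informative_snps_flagged(self):
        model = XpclrModel(omega=0.05)
        clr, s_hat = xpclr_window(np.array([1, 2]), 40, np.array([0.5, 0.5]),
                                  np.array([0.1, 0.2]), np.ones(2), model)
        assert np.isnan(clr) and np.isnan(s_hat)

    def test_grid_contains_zero_required(self):
        with pytest.raises(ValueError, match="contain 0"):
            XpclrModel(omega=0.05, s_grid=np.array([0.01, 0.1]))


class TestXpclrScanProperties:
    def test_label_flip_invariance(self):
        from sweepscan.simulate import simulate_dataset
        from .conftest import small_sim_config
        res = simulate_dataset(small_sim_config(seed=14))
        mm = res.marker_map
        h1, h2 = res.samples["X"]["pop1"], res.samples["X"]["pop2"]
        model = XpclrModel(omega=0.05)
        a = xpclr_scan(h1, h2, mm, model)
        flip = lambda h: HaplotypeSet(h.population, 1 - h.haplotypes,
                                      h.ancestral_known, h.snp_ids)
        b = xpclr_scan(flip(h1), flip(h2), mm, model)
        np.testing.assert_allclose(a["clr"], b["clr"], rtol=1e-8)

    def test_sweep_signal_decays_with_distance(self):
        # median CLR over replicates is higher at the sweep than on far flanks
        from sweepscan.simulate import SweepSpec, simulate_dataset
        from .conftest import small_sim_config
        near, far = [], []
        for seed in range(8):
            cfg = small_sim_config(
                seed=100 + seed, generations_split=120,
                sweep=SweepSpec(enabled=True, position_bp=3_000_000, s=0.1,
                                population="pop1"),
            )
            res = simulate_dataset(cfg)
            sb = res.truth["sweep"]["pos_bp"]
            df = xpclr_scan(res.samples["X"]["pop1"], res.samples["X"]["pop2"],
                            res.marker_map)
            d = np.abs(df["grid_pos_bp"] - sb)
            near.extend(df.loc[d < 5e5, "clr"].dropna())
            far.extend(df.loc[d > 2e6, "clr"].dropna())
        assert np.median(near) > np.median(far)
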