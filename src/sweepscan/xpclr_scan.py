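"""Cross-population composite-likelihood sweep scan (XPCLR-style).

For each grid window the observed population's allele counts are scored
under two models conditioned on the reference population's frequencies:

* neutral drift — the observed frequency ``q`` spreads around the
  reference frequency ``p`` with variance ``omega * p * (1 - p)``
  (truncated normal on (0,1) plus point masses absorbed at the
  boundaries), and the sample count is binomial given ``q``;
* hitchhiking — each SNP escapes the sweep with probability
  ``c = 1 - exp(-rho_scale * r / s)`` (``r`` its genetic distance from the
  window centre, ``s`` the selection coefficient) and otherwise its
  frequency is dragged to the boundary of whichever allele class rode the
  sweep.

The composite log-likelihood sums LD-downweighted per-SNP terms; the
window score is ``CLR = 2 [max_s sum_i w_i ll_sweep(s) - sum_i w_i
ll_neutral]``, non-negative because ``s = 0`` (which collapses the sweep
model onto the neutral one) is always on the grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import betaln, gammaln
from scipy.stats import norm

from .containers import HaplotypeSet, MarkerMap

__all__ = [
    "XpclrModel",
    "default_s_grid",
    "estimate_omega",
    "neutral_loglik",
    "sweep_loglik",
    "ld_weights",
    "xpclr_window",
    "xpclr_scan",
]


def default_s_grid() -> np.ndarray:
    """0 plus 12 log-spaced selection coefficients in [1e-4, 0.5]."""
    return np.concatenate([[0.0], np.logspace(-4, np.log10(0.5), 12)])


@dataclass
class XpclrModel:
    """Tunable parameters of the composite-likelihood scan.

    ``omega`` is the genome-wide drift intensity (variance scale of the
    neutral frequency change), usually estimated from the data by
    :func:`estimate_omega`.  ``rho_scale`` scales the sweep-escape rate;
    the default ``ln(2N)`` with N = 100 reflects the expected fixation
    time scale of a hard sweep.  ``boundary_conc`` is the concentration of
    the smoothed boundary component of the hitchhiking model (a Beta(a,1)
    / Beta(1,a) pair next to the point masses).
    """

    omega: float = 0.05
    s_grid: np.ndarray = field(default_factory=default_s_grid)
    rho_scale: float = math.log(200.0)
    window_cm: float = 0.5
    max_snps_per_window: int = 100
    ld_r2_cutoff: float = 0.95
    n_quad: int = 201
    boundary_atom_weight: float = 0.5
    boundary_conc: float = 50.0

    def __post_init__(self) -> None:
        self.s_grid = np.asarray(self.s_grid, dtype=float)
        if not np.any(self.s_grid == 0):
            raise ValueError("s_grid must contain 0 (the neutral model)")
        if self.omega <= 0:
            raise ValueError("omega must be positive")


def estimate_omega(ref_freqs, obs_freqs, min_snps: int = 100) -> float:
    """Method-of-moments drift intensity.

    Fits ``Var(p_obs - p_ref) = omega * p_ref * (1 - p_ref)`` over SNPs
    segregating in both populations.  Sampling noise in the observed
    frequencies inflates the estimate slightly; treat it as an upper
    bound on pure drift.
    """
    p_ref = np.asarray(ref_freqs, dtype=float)
    p_obs = np.asarray(obs_freqs, dtype=float)
    ok = (p_ref > 0) & (p_ref < 1) & (p_obs > 0) & (p_obs < 1)
    if ok.sum() < min_snps:
        raise ValueError(
            f"need >= {min_snps} SNPs segregating in both populations, got {int(ok.sum())}"
        )
    ratio = (p_obs[ok] - p_ref[ok]) ** 2 / (p_ref[ok] * (1 - p_ref[ok]))
    omega = float(ratio.mean())
    if omega <= 0:
        raise ValueError("populations are identical: drift intensity is 0")
    return omega


def _log_binom(count: int, n: int, q: np.ndarray) -> np.ndarray:
    q = np.asarray(q, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = (
            gammaln(n + 1) - gammaln(count + 1) - gammaln(n - count + 1)
            + np.where(count > 0, count * np.log(q), 0.0)
            + np.where(n - count > 0, (n - count) * np.log1p(-q), 0.0)
        )
    out = np.where((q <= 0) & (count > 0), -np.inf, out)
    out = np.where((q >= 1) & (count < n), -np.inf, out)
    return out


def neutral_loglik(
    p_obs_count: int, n: int, p_ref: float, omega: float, n_quad: int = 201
) -> float:
    """Log-likelihood of an observed allele count under neutral drift.

    Numerically integrates Binomial(count | n, q) against the drift
    density of ``q``: a normal centred at ``p_ref`` with variance
    ``omega * p_ref * (1 - p_ref)``, truncated to (0,1), its tail masses
    sitting as atoms at 0 and 1.  Quadrature nodes adapt to the density's
    scale so both tight (small omega) and broad regimes converge.
    """
    if not 0 <= p_obs_count <= n:
        raise ValueError("need 0 <= count <= n")
    if not 0 < p_ref < 1:
        raise ValueError("p_ref must lie strictly inside (0, 1)")
    sd = math.sqrt(omega * p_ref * (1 - p_ref))
    if sd < 1e-9:
        return float(_log_binom(p_obs_count, n, np.array([p_ref]))[0])
    lo = max(1e-12, p_ref - 8 * sd)
    hi = min(1 - 1e-12, p_ref + 8 * sd)
    qs = np.linspace(lo, hi, n_quad)
    dens = norm.pdf(qs, loc=p_ref, scale=sd)
    lik_cont = np.trapezoid(np.exp(_log_binom(p_obs_count, n, qs)) * dens, qs)
    mass0 = norm.cdf(0.0, loc=p_ref, scale=sd)
    mass1 = norm.sf(1.0, loc=p_ref, scale=sd)
    lik = lik_cont
    if p_obs_count == 0:
        lik += mass0
    if p_obs_count == n:
        lik += mass1
    return float(np.log(max(lik, 1e-300)))


def _boundary_loglik(count: int, n: int, p_ref: float, atom_w: float, conc: float) -> float:
    """Likelihood under the swept (boundary-concentrated) frequency class.

    With probability ``p_ref`` the A allele hitchhikes (frequency pushed to
    1), otherwise the alternative allele does (frequency pushed to 0); each
    class is an atom at the boundary plus a Beta(conc,1)/Beta(1,conc) slab.
    Binomial-Beta integrals are closed-form.
    """
    log_choose = gammaln(n + 1) - gammaln(count + 1) - gammaln(n - count + 1)
    # Beta(conc, 1) component (mass near 1)
    beta_hi = math.exp(log_choose + betaln(count + conc, n - count + 1) - betaln(conc, 1.0))
    beta_lo = math.exp(log_choose + betaln(count + 1, n - count + conc) - betaln(1.0, conc))
    lik_hi = atom_w * (1.0 if count == n else 0.0) + (1 - atom_w) * beta_hi
    lik_lo = atom_w * (1.0 if count == 0 else 0.0) + (1 - atom_w) * beta_lo
    return p_ref * lik_hi + (1 - p_ref) * lik_lo


def sweep_loglik(
    p_obs_count: int,
    n: int,
    p_ref: float,
    omega: float,
    s: float,
    r_cm: float,
    rho_scale: float = math.log(200.0),
    n_quad: int = 201,
    boundary_atom_weight: float = 0.5,
    boundary_conc: float = 50.0,
) -> float:
    """Log-likelihood under the hitchhiking model.

    ``s = 0`` forces escape probability c = 1 and reduces exactly to
    :func:`neutral_loglik`.
    """
    if s < 0 or r_cm < 0:
        raise ValueError("s and r_cm must be non-negative")
    if s == 0:
        return neutral_loglik(p_obs_count, n, p_ref, omega, n_quad)
    c = 1.0 - math.exp(-rho_scale * (r_cm / 100.0) / s)  # r in morgans
    c = min(max(c, 0.0), 1.0)
    lik_neutral = math.exp(neutral_loglik(p_obs_count, n, p_ref, omega, n_quad))
    lik_bnd = _boundary_loglik(p_obs_count, n, p_ref, boundary_atom_weight, boundary_conc)
    return float(np.log(max(c * lik_neutral + (1 - c) * lik_bnd, 1e-300)))


def ld_weights(hap_ref: HaplotypeSet, window_cols, r2_cutoff: float = 0.95) -> np.ndarray:
    """Down-weight SNPs in tight LD in the reference population.

    SNP pairs with r^2 above the cutoff share a group (transitively);
    every SNP gets weight 1 / group-size, so each LD group contributes one
    effective observation.
    """
    cols = np.asarray(window_cols, dtype=int)
    k = cols.size
    if k == 0:
        raise ValueError("window has no SNPs")
    G = hap_ref.haplotypes[:, cols].astype(float)
    sd = G.std(axis=0)
    parent = np.arange(k)

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    centered = G - G.mean(axis=0)
    for i in range(k):
        if sd[i] == 0:
            continue
        for j in range(i + 1, k):
            if sd[j] == 0:
                continue
            r = (centered[:, i] @ centered[:, j]) / (G.shape[0] * sd[i] * sd[j])
            if r * r > r2_cutoff:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[rj] = ri
    roots = np.array([find(i) for i in range(k)])
    sizes = {r: int((roots == r).sum()) for r in set(roots.tolist())}
    return np.array([1.0 / sizes[r] for r in roots])


def xpclr_window(
    obs_counts: np.ndarray,
    n_obs: int,
    p_ref: np.ndarray,
    r_cm: np.ndarray,
    weights: np.ndarray,
    model: XpclrModel,
) -> tuple[float, float]:
    """Composite likelihood ratio and argmax selection coefficient for one
    window; returns (nan, nan) with fewer than 3 informative SNPs."""
    obs_counts = np.asarray(obs_counts, dtype=int)
    p_ref = np.asarray(p_ref, dtype=float)
    r_cm = np.asarray(r_cm, dtype=float)
    weights = np.asarray(weights, dtype=float)
    ok = (p_ref > 0) & (p_ref < 1)
    if ok.sum() < 3:
        return np.nan, np.nan
    obs_counts, p_ref, r_cm, weights = (
        obs_counts[ok], p_ref[ok], r_cm[ok], weights[ok]
    )
    ll_neutral = np.array(
        [neutral_loglik(int(x), n_obs, p, model.omega, model.n_quad)
         for x, p in zip(obs_counts, p_ref)]
    )
    base = float(weights @ ll_neutral)
    best_ll, best_s = base, 0.0
    lik_neutral = np.exp(ll_neutral)
    lik_bnd = np.array(
        [_boundary_loglik(int(x), n_obs, p, model.boundary_atom_weight, model.boundary_conc)
         for x, p in zip(obs_counts, p_ref)]
    )
    for s in model.s_grid:
        if s == 0:
            continue
        c = 1.0 - np.exp(-model.rho_scale * (r_cm / 100.0) / s)
        mix = np.clip(c, 0, 1) * lik_neutral + (1 - np.clip(c, 0, 1)) * lik_bnd
        ll = float(weights @ np.log(np.maximum(mix, 1e-300)))
        if ll > best_ll:
            best_ll, best_s = ll, float(s)
    return 2.0 * (best_ll - base), best_s


def xpclr_scan(
    hap_obs: HaplotypeSet,
    hap_ref: HaplotypeSet,
    marker_map: MarkerMap,
    model: XpclrModel | None = None,
    cm_per_mb: float = 1.0,
    chrom=None,
) -> pd.DataFrame:
    """Sliding-grid XPCLR scan of the observed population.

    The chromosome is tiled into ``window_cm`` grid windows; each window
    scores the contained SNPs (capped at ``max_snps_per_window`` nearest
    the centre) with LD weights from the reference population.  When
    ``model`` is None, ``omega`` is estimated from the SNP set itself and
    all other parameters take their defaults.
    """
    if hap_obs.n_snps != hap_ref.n_snps:
        raise ValueError("populations must share the SNP set (use common_snps)")
    pos_cm = marker_map.pos_cm_or_default(cm_per_mb)
    pos_bp = marker_map.pos_bp
    # uniform-prior posterior-mean frequencies keep the drift density defined
    # even at SNPs fixed in the finite reference sample
    x_ref = hap_ref.haplotypes.sum(axis=0).astype(int)
    n_ref = hap_ref.n_haplotypes
    p_ref_all = (x_ref + 1) / (n_ref + 2)
    if model is None:
        seg = (x_ref > 0) & (x_ref < n_ref)
        p_obs_shrunk = (hap_obs.haplotypes.sum(axis=0) + 1) / (hap_obs.n_haplotypes + 2)
        omega = estimate_omega(
            p_ref_all[seg], p_obs_shrunk[seg],
            min_snps=min(100, max(10, int(seg.sum()))),
        )
        model = XpclrModel(omega=omega)
    x_obs = hap_obs.haplotypes.sum(axis=0).astype(int)
    n_obs = hap_obs.n_haplotypes
    if chrom is None:
        chrom = marker_map.df["chrom"].iloc[0]

    w = model.window_cm
    first = int(np.floor(pos_cm.min() / w))
    last = int(np.floor(pos_cm.max() / w))
    rows = []
    for k in range(first, last + 1):
        centre = (k + 0.5) * w
        inside = np.flatnonzero((pos_cm >= k * w) & (pos_cm < (k + 1) * w))
        info = inside[(p_ref_all[inside] > 0) & (p_ref_all[inside] < 1)]
        if info.size > model.max_snps_per_window:
            order = np.argsort(np.abs(pos_cm[info] - centre))
            info = np.sort(info[order][: model.max_snps_per_window])
        grid_bp = int(np.interp(centre, pos_cm, pos_bp.astype(float)))
        if info.size < 3:
            rows.append({"chrom": chrom, "grid_pos_bp": grid_bp, "n_snps": int(info.size),
                         "clr": np.nan, "s_hat": np.nan, "flag": "too_few_snps"})
            continue
        weights = ld_weights(hap_ref, info, model.ld_r2_cutoff)
        clr, s_hat = xpclr_window(
            x_obs[info], n_obs, p_ref_all[info],
            np.abs(pos_cm[info] - centre), weights, model,
        )
        rows.append({"chrom": chrom, "grid_pos_bp": grid_bp, "n_snps": int(info.size),
                     "clr": clr, "s_hat": s_hat, "flag": "ok"})
    return pd.DataFrame(rows)
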