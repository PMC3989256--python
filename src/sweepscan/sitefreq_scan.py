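"""Site-frequency selection statistics: Bayesian Fst and windowed Tajima's D.

Fst follows a two-step sampling scheme: per SNP and population, allele
frequencies get a Beta posterior under a uniform prior (``Beta(x+1,
n-x+1)`` for ``x`` copies of allele A among ``n`` observed alleles); joint
posterior draws are turned into Fst draws through the Wright-style ratio

    Fst = [ sum_r (p_r - pbar)^2 / R ] / [ pbar (1 - pbar) ]

whose posterior mean is the per-SNP statistic.  The ratio is 0 for
identical population frequencies and 1 for populations fixed for alternate
alleles.

Tajima's D contrasts mean pairwise diversity with the segregating-site
estimate of theta inside non-overlapping windows; pi is computed from
per-site allele counts as ``sum_sites 2 x (n - x) / (n (n - 1))``, which
is exactly the average pairwise difference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "AlleleCounts",
    "FstPosterior",
    "allele_freq_posterior",
    "fst_draw",
    "fst_from_freqs",
    "fst_posterior_track",
    "tajima_constants",
    "tajimas_d",
    "tile_windows",
    "window_scan",
    "tajimas_d_windows",
]


@dataclass
class AlleleCounts:
    """Allele-A counts per population x SNP.

    ``x[r, i]`` copies of allele A out of ``n[r, i]`` observed alleles in
    population ``r`` at SNP ``i``.
    """

    x: np.ndarray
    n: np.ndarray
    snp_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.x = np.atleast_2d(np.asarray(self.x, dtype=int))
        self.n = np.atleast_2d(np.asarray(self.n, dtype=int))
        if self.x.shape != self.n.shape:
            raise ValueError("x and n must share a shape")
        if np.any(self.x < 0) or np.any(self.x > self.n):
            raise ValueError("need 0 <= x <= n")

    @property
    def n_populations(self) -> int:
        return self.x.shape[0]

    @property
    def n_snps(self) -> int:
        return self.x.shape[1]


@dataclass
class FstPosterior:
    snp_id: object
    draws: np.ndarray

    def __post_init__(self) -> None:
        self.draws = np.asarray(self.draws, dtype=float)
        if np.any((self.draws < 0) | (self.draws > 1)):
            raise ValueError("Fst draws must lie in [0, 1]")

    @property
    def posterior_mean(self) -> float:
        return float(self.draws.mean())


def allele_freq_posterior(x: int, n: int, n_draws: int, seed=None) -> np.ndarray:
    """Posterior draws of an allele frequency under a uniform prior.

    ``Beta(x + 1, n - x + 1)``; posterior mean ``(x + 1) / (n + 2)``.
    """
    if n < 1:
        raise ValueError("need at least one observed allele (n >= 1)")
    if not 0 <= x <= n:
        raise ValueError("need 0 <= x <= n")
    rng = np.random.default_rng(seed)
    return rng.beta(x + 1, n - x + 1, size=n_draws)


def fst_from_freqs(p: np.ndarray) -> np.ndarray:
    """Vectorized Wright-style Fst over the first axis (populations).

    ``p`` has shape (R, ...); returns Fst per trailing index, defined as 0
    when the pooled mean frequency is 0 or 1 (no variation to apportion).
    """
    p = np.asarray(p, dtype=float)
    pbar = p.mean(axis=0)
    denom = pbar * (1 - pbar)
    num = np.mean((p - pbar) ** 2, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(denom > 0, num / np.where(denom > 0, denom, 1.0), 0.0)
    return np.clip(out, 0.0, 1.0)


def fst_draw(freqs) -> float:
    """Per-locus Fst from one vector of population frequencies."""
    p = np.asarray(freqs, dtype=float)
    if p.ndim != 1 or p.size < 2:
        raise ValueError("need frequencies for at least two populations")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("frequencies must lie in [0, 1]")
    return float(fst_from_freqs(p[:, None])[0])


def fst_posterior_track(
    counts: AlleleCounts, n_draws: int = 1000, seed=None
) -> tuple[np.ndarray, list[FstPosterior]]:
    """Posterior-mean Fst per SNP from joint Beta frequency draws.

    Returns the per-SNP posterior means and the full draw sets.
    Deterministic under ``seed``.
    """
    if counts.n_populations < 2:
        raise ValueError("need at least two populations")
    rng = np.random.default_rng(seed)
    draws = rng.beta(
        counts.x + 1, counts.n - counts.x + 1,
        size=(n_draws, counts.n_populations, counts.n_snps),
    )  # (D, R, S)
    fst = fst_from_freqs(np.moveaxis(draws, 1, 0))  # (D, S)
    means = fst.mean(axis=0)
    ids = counts.snp_ids if counts.snp_ids is not None else np.arange(counts.n_snps)
    posteriors = [FstPosterior(ids[i], fst[:, i]) for i in range(counts.n_snps)]
    return means, posteriors


# ---------------------------------------------------------------------------
# Tajima's D
# ---------------------------------------------------------------------------

def tajima_constants(n: int) -> dict:
    """The standard variance constants of the D statistic (functions of the
    haplotype sample size n only)."""
    if n < 2:
        raise ValueError("need n >= 2 sequences")
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2, "c1": c1, "c2": c2, "e1": e1, "e2": e2}


def tajimas_d(allele_counts, n: int) -> float:
    """Tajima's D from per-site allele counts of one window.

    ``allele_counts`` are copies (0..n) of one allele per site among ``n``
    haplotypes; monomorphic sites are ignored.  Returns NaN when no site
    segregates.  Negative D marks an excess of rare variants (recent
    sweep), positive D an excess of intermediate frequencies (balancing
    selection); the neutral expectation is ~0.
    """
    if n < 4:
        raise ValueError("need at least 4 haplotypes")
    x = np.asarray(allele_counts, dtype=float)
    if np.any((x < 0) | (x > n)):
        raise ValueError("allele counts must lie in [0, n]")
    seg = (x > 0) & (x < n)
    S = int(seg.sum())
    if S == 0:
        return np.nan
    pi = float(np.sum(2 * x[seg] * (n - x[seg]) / (n * (n - 1))))
    k = tajima_constants(n)
    theta_w = S / k["a1"]
    var = k["e1"] * S + k["e2"] * S * (S - 1)
    return float((pi - theta_w) / np.sqrt(var))


# ---------------------------------------------------------------------------
# windowing
# ---------------------------------------------------------------------------

def tile_windows(chrom_length: int, window_bp: int = 800_000) -> np.ndarray:
    """Half-open [k*w, (k+1)*w) windows tiling [0, chrom_length)."""
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    n_win = int(np.ceil(chrom_length / window_bp))
    starts = np.arange(n_win) * window_bp
    return np.column_stack([starts, starts + window_bp])


def _window_index(pos_bp: np.ndarray, window_bp: int) -> np.ndarray:
    # half-open windows: a SNP at bp k*w falls into window k, not k-1
    return (np.asarray(pos_bp) // window_bp).astype(int)


def window_scan(
    pos_bp: np.ndarray,
    values: np.ndarray,
    window_bp: int = 800_000,
    chrom_length: int | None = None,
    chrom="X",
) -> pd.DataFrame:
    """Assign per-SNP values to consecutive windows.

    Returns one row per window (empty ones included, flagged ``empty``)
    with the min/max of contained values — the per-window summaries the
    window-flagging step consumes.
    """
    pos_bp = np.asarray(pos_bp)
    values = np.asarray(values, dtype=float)
    if chrom_length is None:
        chrom_length = int(pos_bp.max()) + 1 if pos_bp.size else window_bp
    idx = _window_index(pos_bp, window_bp)
    n_needed = (int(idx.max()) + 1) * window_bp if idx.size else 0
    wins = tile_windows(max(chrom_length, n_needed), window_bp)
    rows = []
    for k, (start, end) in enumerate(wins):
        sel = idx == k
        vals = values[sel]
        vals = vals[~np.isnan(vals)]
        rows.append(
            {
                "chrom": chrom,
                "start": int(start),
                "end": int(end),
                "n_snps": int(sel.sum()),
                "value_max": vals.max() if vals.size else np.nan,
                "value_min": vals.min() if vals.size else np.nan,
                "flag": "ok" if vals.size else "empty",
            }
        )
    return pd.DataFrame(rows)


def tajimas_d_windows(
    allele_counts: np.ndarray,
    n: int,
    pos_bp: np.ndarray,
    window_bp: int = 800_000,
    chrom_length: int | None = None,
    chrom="X",
) -> pd.DataFrame:
    """Tajima's D per consecutive window from per-SNP allele counts."""
    pos_bp = np.asarray(pos_bp)
    x = np.asarray(allele_counts)
    if chrom_length is None:
        chrom_length = int(pos_bp.max()) + 1 if pos_bp.size else window_bp
    idx = _window_index(pos_bp, window_bp)
    n_needed = (int(idx.max()) + 1) * window_bp if idx.size else 0
    wins = tile_windows(max(chrom_length, n_needed), window_bp)
    rows = []
    for k, (start, end) in enumerate(wins):
        sel = idx == k
        d = tajimas_d(x[sel], n) if sel.any() else np.nan
        rows.append(
            {
                "chrom": chrom,
                "start": int(start),
                "end": int(end),
                "n_snps": int(sel.sum()),
                "value_max": d,
                "value_min": d,
                "statistic": d,
                "flag": "ok" if not np.isnan(d) else "empty",
            }
        )
    return pd.DataFrame(rows)
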