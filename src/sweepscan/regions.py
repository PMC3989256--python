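"""Significance calls and selection-region construction.

Two empirical significance procedures are offered:

* autosomal cutoffs — the top 5% (configurable) of a genome-wide autosomal
  score distribution, one- or two-sided, with linear-interpolation
  quantiles;
* permutation nulls — each population's per-SNP allele-frequency vector is
  shuffled independently across the fixed SNP positions and the statistic
  recomputed (per SNP for Fst, per window for Tajima's D); the pooled
  permuted values supply the alpha-level cutoffs.

Scores strictly beyond a cutoff are outliers ("footprints"); exact ties
are not flagged.  SNP-level footprints extend +/-400 kb and merge into
regions; window-level statistics flag whole fixed-length windows instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .sitefreq_scan import AlleleCounts, fst_from_freqs, tajimas_d, _window_index

__all__ = [
    "Threshold",
    "SelectionRegion",
    "normal_critical_value",
    "autosomal_cutoff",
    "permutation_threshold",
    "flag_outliers",
    "build_regions",
    "flag_windows",
    "quantile_value",
    "overlap_matrix",
    "merge_intervals",
    "regions_to_bed",
]


@dataclass
class Threshold:
    method: str
    lower: float | None
    upper: float | None
    provenance: str  # "autosome_top_fraction" | "permutation" | "analytic"
    alpha: float | None = None
    n_permutations: int | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.lower is not None and self.upper is not None and not self.lower < self.upper:
            raise ValueError("lower cutoff must be below upper cutoff")


@dataclass
class SelectionRegion:
    """Contiguous interval flagged as under selection (0-based half-open)."""

    chrom: object
    start: int
    end: int
    method: str
    population: str
    peak_score: float
    peak_snp: object = None
    n_snps: int = 0
    quantile_value: float | None = None

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError("region start must be below end")

    @property
    def length_bp(self) -> int:
        return self.end - self.start


def normal_critical_value(alpha: float = 0.05, two_sided: bool = True) -> float:
    """Standard-normal critical value, e.g. 1.96 for a two-sided 5% test —
    the reference cutoff for a statistic standardized to N(0,1)."""
    q = 1 - alpha / 2 if two_sided else 1 - alpha
    return float(norm.ppf(q))


def autosomal_cutoff(
    autosome_scores, fraction: float = 0.05, two_sided: bool = False, method: str = "",
    min_scores: int = 100,
) -> Threshold:
    """Empirical cutoff(s) from a genome-wide autosomal score distribution.

    One-sided: upper = (1 - fraction) quantile.  Two-sided: fraction/2 in
    each tail.  Quantiles use linear interpolation of the empirical CDF.
    ``min_scores`` guards against meaninglessly small reference sets.
    """
    scores = np.asarray(autosome_scores, dtype=float)
    scores = scores[~np.isnan(scores)]
    if scores.size < min_scores:
        raise ValueError(
            f"need at least {min_scores} autosomal scores for an empirical cutoff"
        )
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    if two_sided:
        lower = float(np.quantile(scores, fraction / 2))
        upper = float(np.quantile(scores, 1 - fraction / 2))
    else:
        lower = None
        upper = float(np.quantile(scores, 1 - fraction))
    return Threshold(method, lower, upper, "autosome_top_fraction", alpha=fraction)


def permutation_threshold(
    statistic: str,
    counts: AlleleCounts | None = None,
    x: np.ndarray | None = None,
    n: int | None = None,
    pos_bp: np.ndarray | None = None,
    window_bp: int = 800_000,
    n_perm: int = 5000,
    alpha: float = 0.05,
    seed: int | None = None,
    n_draws: int = 1000,
    method: str | None = None,
) -> Threshold:
    """Empirical threshold from permutations of allele frequencies.

    Each permutation independently shuffles every population's per-SNP
    frequency information across the fixed SNP positions and recomputes the
    statistic; pooled permuted values give the (1 - alpha) quantile (and,
    for Tajima's D, the alpha quantile as the lower cutoff).

    ``statistic="fst"`` needs ``counts`` (the posterior-mean Fst is
    recomputed per permutation by re-pairing pre-drawn Beta posterior
    samples — exactly a shuffle of the frequency posteriors).
    ``statistic="tajd"`` needs ``x`` (per-SNP allele counts), ``n``
    (haplotype sample size) and ``pos_bp``; D is recomputed per window.
    """
    if n_perm < 100:
        raise ValueError("need at least 100 permutations")
    rng = np.random.default_rng(seed)

    if statistic == "fst":
        if counts is None:
            raise ValueError("fst permutation needs AlleleCounts")
        R, S = counts.n_populations, counts.n_snps
        draws = rng.beta(
            counts.x + 1, counts.n - counts.x + 1, size=(n_draws, R, S)
        )  # (D, R, S)
        pooled = np.empty((n_perm, S))
        perm_draws = np.empty_like(draws)
        for b in range(n_perm):
            for r in range(R):
                perm_draws[:, r, :] = draws[:, r, rng.permutation(S)]
            pooled[b] = fst_from_freqs(np.moveaxis(perm_draws, 1, 0)).mean(axis=0)
        vals = pooled.ravel()
        upper = float(np.quantile(vals, 1 - alpha))
        return Threshold(method or "fst", None, upper, "permutation",
                         alpha=alpha, n_permutations=n_perm, seed=seed)

    if statistic == "tajd":
        if x is None or n is None or pos_bp is None:
            raise ValueError("tajd permutation needs x, n and pos_bp")
        x = np.asarray(x)
        idx = _window_index(np.asarray(pos_bp), window_bp)
        vals = []
        for _ in range(n_perm):
            xp = x[rng.permutation(x.size)]
            for k in np.unique(idx):
                d = tajimas_d(xp[idx == k], n)
                if not np.isnan(d):
                    vals.append(d)
        vals = np.asarray(vals)
        lower = float(np.quantile(vals, alpha))
        upper = float(np.quantile(vals, 1 - alpha))
        return Threshold(method or "tajd", lower, upper, "permutation",
                         alpha=alpha, n_permutations=n_perm, seed=seed)

    raise ValueError(f"unknown permutation statistic {statistic!r}")


def flag_outliers(
    track_df: pd.DataFrame, threshold: Threshold, score_col: str = "raw_score",
    signed_populations: tuple[str, str] | None = None,
) -> pd.DataFrame:
    """SNPs strictly beyond the cutoffs.

    ``signed_populations=(observed, reference)`` partitions signed scores
    (XPEHH): positive outliers are attributed to the observed population,
    negative ones to the reference population, via a ``population`` column.
    """
    scores = track_df[score_col].to_numpy(dtype=float)
    mask = np.zeros(len(track_df), dtype=bool)
    if threshold.upper is not None:
        mask |= scores > threshold.upper
    if threshold.lower is not None:
        mask |= scores < threshold.lower
    out = track_df.loc[mask].copy()
    if signed_populations is not None:
        obs, ref = signed_populations
        out["population"] = np.where(out[score_col] > 0, obs, ref)
    return out


def merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping or book-ended half-open intervals."""
    merged: list[list[int]] = []
    for start, end in sorted(intervals):
        if merged and start <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append([start, end])
    return [(s, e) for s, e in merged]


def build_regions(
    flagged: pd.DataFrame,
    method: str,
    population: str,
    extend_bp: int = 400_000,
    chrom_length: int | None = None,
    score_col: str = "raw_score",
) -> list[SelectionRegion]:
    """Extend each flagged SNP +/- ``extend_bp`` and merge overlaps.

    Idempotent on its own output: merged regions are pairwise disjoint and
    sorted.  ``peak_score`` is the largest |score| inside each region.
    """
    regions: list[SelectionRegion] = []
    for chrom, sub in flagged.groupby("chrom", sort=False):
        pos = sub["pos_bp"].to_numpy()
        scores = sub[score_col].to_numpy(dtype=float)
        ivals = []
        for p in pos:
            start = max(0, int(p) - extend_bp)
            end = int(p) + extend_bp
            if chrom_length is not None:
                end = min(end, chrom_length)
            ivals.append((start, end))
        for start, end in merge_intervals(ivals):
            inside = (pos >= start) & (pos < end)
            k = int(np.argmax(np.abs(scores[inside])))
            peak = float(scores[inside][k])
            peak_snp = sub["snp_id"].to_numpy()[inside][k] if "snp_id" in sub else None
            regions.append(
                SelectionRegion(chrom, start, end, method, population,
                                peak, peak_snp, int(inside.sum()))
            )
    regions.sort(key=lambda r: (str(r.chrom), r.start))
    return regions


def flag_windows(
    wtrack: pd.DataFrame, threshold: Threshold, method: str, population: str
) -> list[SelectionRegion]:
    """Whole windows containing at least one value strictly beyond the
    threshold become fixed-length regions (no merging)."""
    regions = []
    for _, row in wtrack.iterrows():
        hit = False
        peak = np.nan
        if threshold.upper is not None and not np.isnan(row["value_max"]):
            if row["value_max"] > threshold.upper:
                hit, peak = True, row["value_max"]
        if threshold.lower is not None and not np.isnan(row["value_min"]):
            if row["value_min"] < threshold.lower:
                hit = True
                peak = row["value_min"] if np.isnan(peak) else peak
        if hit:
            regions.append(
                SelectionRegion(row["chrom"], int(row["start"]), int(row["end"]),
                                method, population, float(peak),
                                n_snps=int(row["n_snps"]))
            )
    return regions


def quantile_value(score: float, reference_scores) -> float:
    """Empirical CDF rank of a score: (# reference values <= score) / N."""
    ref = np.asarray(reference_scores, dtype=float)
    ref = ref[~np.isnan(ref)]
    if ref.size == 0:
        raise ValueError("reference scores must be non-empty")
    return float((ref <= score).sum() / ref.size)


def overlap_matrix(regions_by_method: dict[str, list[SelectionRegion]]) -> pd.DataFrame:
    """Pairwise overlap lengths (Mb) between methods' merged region sets.

    Diagonal entries are each method's total merged length; the matrix is
    symmetric and every off-diagonal entry is bounded by the smaller of
    the two diagonals.
    """
    methods = list(regions_by_method)
    merged = {}
    for m in methods:
        by_chrom: dict[object, list[tuple[int, int]]] = {}
        for r in regions_by_method[m]:
            by_chrom.setdefault(r.chrom, []).append((r.start, r.end))
        merged[m] = {c: merge_intervals(iv) for c, iv in by_chrom.items()}

    def total(iv_by_chrom):
        return sum(e - s for iv in iv_by_chrom.values() for s, e in iv)

    def intersection(a, b):
        tot = 0
        for chrom in set(a) & set(b):
            for s1, e1 in a[chrom]:
                for s2, e2 in b[chrom]:
                    tot += max(0, min(e1, e2) - max(s1, s2))
        return tot

    mat = np.zeros((len(methods), len(methods)))
    for i, mi in enumerate(methods):
        mat[i, i] = total(merged[mi])
        for j in range(i + 1, len(methods)):
            ov = intersection(merged[mi], merged[methods[j]])
            mat[i, j] = mat[j, i] = ov
    return pd.DataFrame(mat / 1e6, index=methods, columns=methods)


def merge_regions(regions: list[SelectionRegion], method: str, population: str) -> list[SelectionRegion]:
    """Merge region lists (e.g. the same population's regions from several
    population pairs) into disjoint intervals; the peak keeps the largest
    absolute contributing score and SNP counts add within merged spans."""
    out = []
    by_chrom: dict[object, list[SelectionRegion]] = {}
    for r in regions:
        by_chrom.setdefault(r.chrom, []).append(r)
    for chrom, rs in by_chrom.items():
        for start, end in merge_intervals([(r.start, r.end) for r in rs]):
            inside = [r for r in rs if r.start < end and r.end > start]
            peak = max(inside, key=lambda r: abs(r.peak_score))
            out.append(SelectionRegion(
                chrom, start, end, method, population,
                peak.peak_score, peak.peak_snp,
                int(sum(r.n_snps for r in inside)),
            ))
    out.sort(key=lambda r: (str(r.chrom), r.start))
    return out


def regions_to_bed(regions: list[SelectionRegion], path) -> None:
    """BED output: chrom, start, end, name=method:population, score=peak."""
    with open(path, "w") as fh:
        for r in sorted(regions, key=lambda r: (str(r.chrom), r.start)):
            fh.write(
                f"{r.chrom}\t{r.start}\t{r.end}\t{r.method}:{r.population}\t{r.peak_score:.4f}\n"
            )
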