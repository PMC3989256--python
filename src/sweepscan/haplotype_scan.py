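"""Haplotype-homozygosity selection statistics: EHH, iHH, iHS and XPEHH.

EHH at a target SNP is the probability that two haplotypes drawn at random
from the carriers of the core allele are identical over the whole stretch
from the core to the target:

    EHH = sum_h C(e_h, 2) / C(c, 2)

with ``c`` carriers of the core allele and ``e_h`` copies of each distinct
extended haplotype.  iHH integrates the EHH curve over genetic distance
(cM) on both sides of the core.  iHS is ln(iHH_ancestral / iHH_derived),
standardized within derived-allele-frequency bins; XPEHH is
ln(iHH_observed / iHH_reference) with the core EHH pooled over all
haplotypes of each population.  A negative XPEHH points at selection in
the reference population, a positive one at the observed population.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import HaplotypeSet, MarkerMap, ScoreTrack

logger = logging.getLogger(__name__)

__all__ = [
    "EHHCurve",
    "ehh_at",
    "ehh_curve",
    "ehh_curves",
    "integrate_ihh",
    "xpehh_raw",
    "ihs_raw",
    "ihs_track",
    "xpehh_track",
    "standardize_scores",
]


@dataclass
class EHHCurve:
    """One side of an EHH decay curve around a core SNP.

    ``distances_cm`` are absolute genetic distances from the core (first
    entry 0), ``values`` the EHH at each point (first entry 1.0).
    ``stop_reason`` is one of ``truncated``, ``chrom_end``, ``max_extend``.
    """

    core_index: int
    side: str  # "left" | "right"
    distances_cm: np.ndarray
    values: np.ndarray
    core_allele: int | None
    stop_reason: str

    @property
    def edge_truncated(self) -> bool:
        return self.stop_reason == "chrom_end" and self.values[-1] >= 0.05


def _pair_homozygosity(labels: np.ndarray) -> float:
    """Fraction of identical pairs among labelled haplotypes."""
    c = labels.size
    if c < 2:
        return np.nan
    counts = np.bincount(labels)
    return float((counts * (counts - 1)).sum() / (c * (c - 1)))


def _carriers(hapset: HaplotypeSet, core_index: int, core_allele) -> np.ndarray:
    if core_allele is None:
        return np.arange(hapset.n_haplotypes)
    return np.flatnonzero(hapset.haplotypes[:, core_index] == core_allele)


def ehh_at(hapset: HaplotypeSet, core_index: int, target_index: int, core_allele=None) -> float:
    """EHH between core and target SNP among carriers of ``core_allele``.

    ``core_allele=None`` pools all haplotypes (the cross-population core
    definition).  Returns NaN with fewer than two carriers.
    """
    rows = _carriers(hapset, core_index, core_allele)
    if rows.size < 2:
        return np.nan
    lo, hi = sorted((core_index, target_index))
    sub = hapset.haplotypes[np.ix_(rows, np.arange(lo, hi + 1))]
    _, labels = np.unique(sub, axis=0, return_inverse=True)
    return _pair_homozygosity(labels)


def ehh_curve(
    hapset: HaplotypeSet,
    pos_cm: np.ndarray,
    core_index: int,
    core_allele=None,
    side: str = "right",
    truncation: float = 0.05,
    max_extend_cm: float | None = None,
) -> EHHCurve:
    """Walk outward from the core, refining haplotype classes SNP by SNP.

    The walk stops at the first SNP with EHH below ``truncation`` (the
    boundary point is kept), at the chromosome end, or once the genetic
    distance exceeds ``max_extend_cm``.
    """
    rows = _carriers(hapset, core_index, core_allele)
    step = 1 if side == "right" else -1
    distances = [0.0]
    values = [1.0]
    if rows.size < 2:
        return EHHCurve(core_index, side, np.array(distances), np.array(values),
                        core_allele, "few_carriers")
    H = hapset.haplotypes
    labels = np.zeros(rows.size, dtype=np.int64)
    n_snps = hapset.n_snps
    j = core_index
    reason = "chrom_end"
    while True:
        j += step
        if j < 0 or j >= n_snps:
            reason = "chrom_end"
            break
        d = abs(pos_cm[j] - pos_cm[core_index])
        if max_extend_cm is not None and d > max_extend_cm:
            reason = "max_extend"
            break
        # refine the partition with the new SNP's alleles
        combo = labels * 2 + H[rows, j]
        _, labels = np.unique(combo, return_inverse=True)
        value = _pair_homozygosity(labels)
        distances.append(d)
        values.append(value)
        if value < truncation:
            reason = "truncated"
            break
    return EHHCurve(core_index, side, np.asarray(distances), np.asarray(values),
                    core_allele, reason)


def ehh_curves(hapset, pos_cm, core_index, core_allele=None,
               truncation=0.05, max_extend_cm=None) -> tuple[EHHCurve, EHHCurve]:
    left = ehh_curve(hapset, pos_cm, core_index, core_allele, "left", truncation, max_extend_cm)
    right = ehh_curve(hapset, pos_cm, core_index, core_allele, "right", truncation, max_extend_cm)
    return left, right


def integrate_ihh(curve_left: EHHCurve, curve_right: EHHCurve) -> float:
    """Trapezoidal integral of EHH over genetic distance, both sides (cM)."""
    if curve_left.core_index != curve_right.core_index:
        raise ValueError("curves must share the core SNP")
    total = 0.0
    for curve in (curve_left, curve_right):
        if curve.distances_cm.size > 1:
            total += float(np.trapezoid(curve.values, curve.distances_cm))
    return total


def xpehh_raw(ihh_obs: float, ihh_ref: float) -> float:
    """ln(iHH_observed / iHH_reference); NaN when either integral is 0."""
    if not (ihh_obs > 0 and ihh_ref > 0):
        return np.nan
    return float(np.log(ihh_obs / ihh_ref))


def ihs_raw(ihh_ancestral: float, ihh_derived: float) -> float:
    """ln(iHH_ancestral / iHH_derived); NaN when either integral is 0."""
    if not (ihh_ancestral > 0 and ihh_derived > 0):
        return np.nan
    return float(np.log(ihh_ancestral / ihh_derived))


def _ihh_all(hapset, pos_cm, core, allele, truncation, max_extend_cm):
    left, right = ehh_curves(hapset, pos_cm, core, allele, truncation, max_extend_cm)
    edge = left.edge_truncated or right.edge_truncated
    return integrate_ihh(left, right), edge


def ihs_track(
    hapset: HaplotypeSet,
    marker_map: MarkerMap,
    truncation: float = 0.05,
    max_extend_cm: float | None = 1.0,
    cm_per_mb: float = 1.0,
    assume_major_ancestral: bool = False,
) -> ScoreTrack:
    """Unstandardized iHS for every SNP with known ancestral orientation.

    SNPs without ancestral orientation are skipped (counted in the log)
    unless ``assume_major_ancestral`` polarizes them by the major allele —
    a fallback that is reported loudly because mispolarization flips signs.
    """
    pos_cm = marker_map.pos_cm_or_default(cm_per_mb)
    H = hapset.haplotypes
    known = hapset.ancestral_known.copy()
    flip = np.zeros(hapset.n_snps, dtype=bool)
    if assume_major_ancestral and not known.all():
        n_fallback = int((~known).sum())
        logger.warning("polarizing %d SNPs by major allele = ancestral", n_fallback)
        flip = ~known & (H.mean(axis=0) > 0.5)
        known = np.ones_like(known)
    n_skipped = int((~known).sum())
    if n_skipped:
        logger.info("iHS: skipping %d SNPs with unknown ancestral state", n_skipped)

    rows = []
    for j in range(hapset.n_snps):
        if not known[j]:
            continue
        derived = H[:, j].astype(int) ^ int(flip[j])
        daf = derived.mean()
        flags = []
        anc_allele, der_allele = (1, 0) if flip[j] else (0, 1)
        ihh_a, edge_a = _ihh_all(hapset, pos_cm, j, anc_allele, truncation, max_extend_cm)
        ihh_d, edge_d = _ihh_all(hapset, pos_cm, j, der_allele, truncation, max_extend_cm)
        raw = ihs_raw(ihh_a, ihh_d)
        if edge_a or edge_d:
            flags.append("edge")
        if np.isnan(raw):
            flags.append("undefined")
        rows.append(
            {
                "chrom": marker_map.df["chrom"].iloc[j],
                "pos_bp": marker_map.df["pos_bp"].iloc[j],
                "snp_id": marker_map.df["snp_id"].iloc[j],
                "raw_score": raw,
                "daf": daf,
                "ihh_ancestral": ihh_a,
                "ihh_derived": ihh_d,
                "n_carriers_allele0": int((derived == 0).sum()),
                "n_carriers_allele1": int((derived == 1).sum()),
                "flags": ";".join(flags) if flags else "ok",
            }
        )
    return ScoreTrack("ihs", hapset.population, pd.DataFrame(rows))


def xpehh_track(
    hap_obs: HaplotypeSet,
    hap_ref: HaplotypeSet,
    marker_map: MarkerMap,
    truncation: float = 0.05,
    max_extend_cm: float | None = 1.0,
    cm_per_mb: float = 1.0,
) -> ScoreTrack:
    """Unstandardized XPEHH per SNP.

    The core EHH pools all haplotypes of each population (no split by
    allele); positive scores point at the observed population.
    """
    if hap_obs.n_snps != hap_ref.n_snps:
        raise ValueError("populations must share the SNP set (use common_snps)")
    pos_cm = marker_map.pos_cm_or_default(cm_per_mb)
    rows = []
    for j in range(hap_obs.n_snps):
        ihh_o, edge_o = _ihh_all(hap_obs, pos_cm, j, None, truncation, max_extend_cm)
        ihh_r, edge_r = _ihh_all(hap_ref, pos_cm, j, None, truncation, max_extend_cm)
        raw = xpehh_raw(ihh_o, ihh_r)
        flags = []
        if edge_o or edge_r:
            flags.append("edge")
        if np.isnan(raw):
            flags.append("undefined")
        rows.append(
            {
                "chrom": marker_map.df["chrom"].iloc[j],
                "pos_bp": marker_map.df["pos_bp"].iloc[j],
                "snp_id": marker_map.df["snp_id"].iloc[j],
                "raw_score": raw,
                "ihh_obs": ihh_o,
                "ihh_ref": ihh_r,
                "n_carriers_allele0": int((hap_obs.haplotypes[:, j] == 0).sum()),
                "n_carriers_allele1": int((hap_obs.haplotypes[:, j] == 1).sum()),
                "flags": ";".join(flags) if flags else "ok",
            }
        )
    return ScoreTrack(
        f"xpehh:{hap_obs.population}|{hap_ref.population}",
        hap_obs.population,
        pd.DataFrame(rows),
    )


def _merge_small_bins(bin_idx: np.ndarray, min_count: int) -> np.ndarray:
    """Merge frequency bins holding < min_count scores into their nearest
    neighbour (by bin index) until every remaining bin is large enough."""
    bins = sorted(set(bin_idx.tolist()))
    groups = {b: [b] for b in bins}
    order = list(bins)

    def count(b):
        return int(np.isin(bin_idx, groups[b]).sum())

    while len(order) > 1:
        counts = [count(b) for b in order]
        smallest = int(np.argmin(counts))
        if counts[smallest] >= min_count:
            break
        # merge with the nearer neighbour; ties go left
        if smallest == 0:
            target = 1
        elif smallest == len(order) - 1:
            target = smallest - 1
        else:
            d_left = order[smallest] - order[smallest - 1]
            d_right = order[smallest + 1] - order[smallest]
            target = smallest - 1 if d_left <= d_right else smallest + 1
        groups[order[target]].extend(groups[order[smallest]])
        del groups[order[smallest]]
        order.pop(smallest)

    out = np.empty_like(bin_idx)
    for rep, members in groups.items():
        out[np.isin(bin_idx, members)] = rep
    return out


def standardize_scores(
    track: ScoreTrack,
    mode: str = "global",
    bin_width: float = 0.02,
    min_bin_count: int = 20,
    freq_col: str = "daf",
    reference: pd.DataFrame | None = None,
) -> ScoreTrack:
    """Z-score raw statistics, globally or within allele-frequency bins.

    ``freq_bins`` mode (used for iHS) bins by derived-allele frequency in
    steps of ``bin_width``; bins with fewer than ``min_bin_count`` scores
    merge with their nearest neighbour.  ``reference`` optionally supplies
    the rows whose mean/sd define the standardization (e.g. autosome-wide
    scores) while the returned track keeps only the input rows.
    """
    df = track.data.copy()
    ref = df if reference is None else reference
    combined = pd.concat([df, ref]) if reference is not None else df
    valid_all = ~combined["raw_score"].isna()
    df["std_score"] = np.nan

    if mode == "global":
        groups_all = np.zeros(len(combined), dtype=int)
    elif mode == "freq_bins":
        if freq_col not in combined.columns:
            raise ValueError(f"freq_bins mode needs a {freq_col!r} column")
        freq = combined[freq_col].to_numpy(dtype=float)
        bin_idx = np.floor(np.clip(freq, 0, 1 - 1e-12) / bin_width).astype(int)
        groups_all = np.full(len(combined), -1)
        groups_all[valid_all.to_numpy()] = _merge_small_bins(
            bin_idx[valid_all.to_numpy()], min_bin_count
        )
    else:
        raise ValueError(f"unknown standardization mode {mode!r}")

    raw_all = combined["raw_score"].to_numpy(dtype=float)
    std = np.full(len(df), np.nan)
    groups_df = groups_all[: len(df)]
    for g in np.unique(groups_all[valid_all.to_numpy()]):
        in_ref = (groups_all == g) & valid_all.to_numpy()
        if in_ref.sum() < 2:
            raise ValueError(f"bin {g}: fewer than two scores to standardize")
        mu = raw_all[in_ref].mean()
        sd = raw_all[in_ref].std(ddof=0)
        if sd == 0:
            raise ValueError(f"bin {g}: zero variance, cannot standardize")
        sel = (groups_df == g) & ~df["raw_score"].isna().to_numpy()
        std[sel] = (df["raw_score"].to_numpy(dtype=float)[sel] - mu) / sd
    df["std_score"] = std
    return ScoreTrack(track.method, track.population, df)
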