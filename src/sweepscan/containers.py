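"""Core in-memory containers shared by all scan modules.

Conventions
-----------
* Physical positions (``pos_bp``) are 1-based in all file I/O; every
  in-memory *interval* (windows, regions) is 0-based half-open.
* Genetic positions (``pos_cm``) are in centimorgans.  When a map carries
  no cM column, callers fall back to a constant rate (default 1 cM/Mb).
* Genotype calls count copies of allele B (the "alternate"); ``-1`` marks
  a missing call.
* Haplotype matrices are binary (0 = allele A, 1 = allele B).  Where the
  ancestral allele is known, allele codes are *oriented*: 0 = ancestral,
  1 = derived.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1

#: value of the ``ancestral`` map column: index of the ancestral allele
#: (0 = allele_a, 1 = allele_b) or UNKNOWN_ANCESTRAL.
UNKNOWN_ANCESTRAL = -1

MAP_COLUMNS = ["snp_id", "chrom", "pos_cm", "pos_bp", "allele_a", "allele_b", "ancestral"]


@dataclass
class MarkerMap:
    """Per-SNP coordinates and alleles.

    ``df`` holds the columns of :data:`MAP_COLUMNS`; ``pos_cm`` may be NaN
    when no genetic map is available, ``ancestral`` is 0/1 or
    :data:`UNKNOWN_ANCESTRAL`.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in ("snp_id", "chrom", "pos_bp") if c not in self.df.columns]
        if missing:
            raise ValueError(f"marker map lacks required columns: {missing}")
        df = self.df.copy().reset_index(drop=True)
        if "pos_cm" not in df.columns:
            df["pos_cm"] = np.nan
        if "allele_a" not in df.columns:
            df["allele_a"] = "A"
        if "allele_b" not in df.columns:
            df["allele_b"] = "B"
        if "ancestral" not in df.columns:
            df["ancestral"] = UNKNOWN_ANCESTRAL
        self.df = df[MAP_COLUMNS]
        for chrom, sub in df.groupby("chrom", sort=False):
            bp = sub["pos_bp"].to_numpy()
            if np.any(np.diff(bp) <= 0):
                raise ValueError(f"pos_bp not strictly increasing on chromosome {chrom}")
            cm = sub["pos_cm"].to_numpy(dtype=float)
            cm = cm[~np.isnan(cm)]
            if cm.size > 1 and np.any(np.diff(cm) < 0):
                raise ValueError(f"pos_cm decreasing on chromosome {chrom}")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def snp_ids(self) -> np.ndarray:
        return self.df["snp_id"].to_numpy()

    @property
    def pos_bp(self) -> np.ndarray:
        return self.df["pos_bp"].to_numpy()

    @property
    def chroms(self) -> list:
        return list(dict.fromkeys(self.df["chrom"]))

    def pos_cm_or_default(self, cm_per_mb: float = 1.0) -> np.ndarray:
        """Genetic positions, filling missing cM with a constant-rate map."""
        cm = self.df["pos_cm"].to_numpy(dtype=float)
        fallback = self.df["pos_bp"].to_numpy(dtype=float) * cm_per_mb / 1e6
        return np.where(np.isnan(cm), fallback, cm)

    def subset(self, index) -> "MarkerMap":
        """New map restricted to boolean mask / integer index (order kept)."""
        return MarkerMap(self.df.iloc[np.asarray(index)].reset_index(drop=True))

    def for_chrom(self, chrom) -> "MarkerMap":
        return MarkerMap(self.df[self.df["chrom"] == chrom].reset_index(drop=True))

    def indices_of(self, snp_ids) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.df["snp_id"])}
        return np.array([lookup[s] for s in snp_ids], dtype=int)


@dataclass
class GenotypeTable:
    """Diploid genotype calls: individuals x SNPs, values in {0,1,2,-1}."""

    individuals: list
    snps: list
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.individuals), len(self.snps)):
            raise ValueError(
                f"calls shape {self.calls.shape} != "
                f"({len(self.individuals)}, {len(self.snps)})"
            )
        ok = np.isin(self.calls, (0, 1, 2, MISSING))
        if not ok.all():
            raise ValueError("genotype calls must be in {0,1,2} or missing (-1)")

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def individual_call_rate(self) -> np.ndarray:
        return (self.calls != MISSING).mean(axis=1)

    def snp_call_rate(self) -> np.ndarray:
        return (self.calls != MISSING).mean(axis=0)

    def allele_counts(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-SNP (count of allele B, number of observed alleles)."""
        observed = self.calls != MISSING
        x = np.where(observed, self.calls, 0).sum(axis=0)
        n = 2 * observed.sum(axis=0)
        return x.astype(int), n.astype(int)

    def subset_individuals(self, index) -> "GenotypeTable":
        idx = np.asarray(index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeTable(
            [self.individuals[i] for i in idx], list(self.snps), self.calls[idx]
        )

    def subset_snps(self, index) -> "GenotypeTable":
        idx = np.asarray(index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeTable(
            list(self.individuals), [self.snps[i] for i in idx], self.calls[:, idx]
        )


@dataclass
class HaplotypeSet:
    """Phased binary haplotypes for one population.

    ``ancestral_known`` marks SNPs whose 0/1 coding is oriented
    (0 = ancestral, 1 = derived); elsewhere the coding is allele_a/allele_b.
    """

    population: str
    haplotypes: np.ndarray
    ancestral_known: np.ndarray = field(default=None)  # type: ignore[assignment]
    snp_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.haplotypes = np.ascontiguousarray(self.haplotypes, dtype=np.uint8)
        if self.haplotypes.ndim != 2:
            raise ValueError("haplotypes must be a 2-D matrix")
        if not np.isin(self.haplotypes, (0, 1)).all():
            raise ValueError("haplotypes must be binary with no missing values")
        if self.ancestral_known is None:
            self.ancestral_known = np.zeros(self.haplotypes.shape[1], dtype=bool)
        self.ancestral_known = np.asarray(self.ancestral_known, dtype=bool)
        if self.ancestral_known.shape != (self.haplotypes.shape[1],):
            raise ValueError("ancestral_known must have one flag per SNP")

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.haplotypes.shape[1]

    def allele_freq(self) -> np.ndarray:
        """Frequency of allele coded 1 per SNP."""
        return self.haplotypes.mean(axis=0)

    def allele_counts(self) -> tuple[np.ndarray, np.ndarray]:
        x = self.haplotypes.sum(axis=0).astype(int)
        n = np.full(self.n_snps, self.n_haplotypes, dtype=int)
        return x, n

    def subset_snps(self, index) -> "HaplotypeSet":
        idx = np.asarray(index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return HaplotypeSet(
            self.population,
            self.haplotypes[:, idx],
            self.ancestral_known[idx],
            None if self.snp_ids is None else np.asarray(self.snp_ids)[idx],
        )

    def subset_haplotypes(self, index) -> "HaplotypeSet":
        idx = np.asarray(index)
        return HaplotypeSet(
            self.population, self.haplotypes[idx], self.ancestral_known, self.snp_ids
        )


@dataclass
class ScoreTrack:
    """Per-SNP (or per grid point) statistic values for one method run."""

    method: str
    population: str
    data: pd.DataFrame  # chrom, pos_bp, snp_id, raw_score [, std_score, ...]

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index=False)
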