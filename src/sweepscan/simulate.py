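"""Forward Wright-Fisher simulator of diverging populations on a SNP grid.

The generator emulates the statistical structure SNP-chip sweep scans
assume: two (or more) populations that split from a common ancestral pool,
chip-like marker spacing (~110 kb for the default 180 SNPs on 20 Mb),
recombination, drift since the split, chip-style ascertainment (ancestral
minor allele frequency floor) and, optionally, a hard sweep in one
population.

Ancestral pool
--------------
SNP positions are uniform on the chromosome.  Derived-allele frequencies
are drawn from a neutral-like spectrum (density proportional to 1/x on a
discrete grid).  Haplotypes are built from a latent Gaussian AR(1) process thresholded at
each site's target frequency (a Gaussian copula), so nearby SNPs carry
realistic linkage disequilibrium (adjacent-marker r^2 ~ 0.3 at the default
spacing, matching chip-scale reports) while per-site marginal frequencies
follow the target spectrum exactly.

Forward phase
-------------
Each daughter population starts as a resample of the pool and then evolves
``generations_split`` generations of Wright-Fisher reproduction: every
child haplotype recombines two uniformly chosen parents (crossover count
Poisson in map length).  A sweep introduces a de-novo beneficial mutation
on a single haplotype late enough in the forward phase for the allele to
just complete its rise by sampling time; selection multiplies a parent's
sampling weight by ``(1 + s)`` per derived copy (genic selection), and
runs are conditioned on the allele reaching a frequency floor, with
bounded restarts.

All randomness flows from one integer seed through spawned generator
streams, so every output is reproducible byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import HaplotypeSet, MarkerMap
from . import io_qc

__all__ = [
    "SweepSpec",
    "SweepSimConfig",
    "SimResult",
    "simulate_ancestral",
    "evolve_split",
    "impose_sweep",
    "simulate_dataset",
    "write_fixture",
]


@dataclass
class SweepSpec:
    enabled: bool = False
    position_bp: int = 10_000_000
    s: float = 0.05
    population: str = "pop1"


@dataclass
class SweepSimConfig:
    """Full parameterization of the synthetic sweep simulator.

    Defaults mirror a chip-scale study design: ~34 diploid females per
    population (68 haplotypes sampled), ~110 kb mean marker spacing
    (180 SNPs on a 20 Mb chromosome), a 1 cM/Mb map, and array-style
    ascertainment at 5% minor allele frequency in the ancestral pool.

    The default divergence (300 generations at 3000 haplotypes per
    population, drift time t/2N = 0.1 per branch) keeps ~90% of the
    ascertained panel polymorphic within each population — the situation
    on a real SNP chip, whose content was discovered in the modern breeds
    and which retains nearly all markers through within-breed MAF
    filtering — while leaving room for a de-novo hard sweep at s = 0.05
    to establish and complete before sampling.  A much smaller population
    at the same divergence drives most SNPs to within-population fixation,
    which starves haplotype statistics of input and matches no chip
    dataset; the price of this choice is between-population
    differentiation at the low end of livestock breed pairs.
    """

    n_haplotypes_per_pop: int = 3000
    sample_size_per_pop: int = 68
    chrom_length_bp: int = 20_000_000
    target_n_snps: int = 180
    recomb_cm_per_mb: float = 1.0
    generations_split: int = 300
    sweep: SweepSpec = field(default_factory=SweepSpec)
    maf_ascertain: float = 0.05
    seed: int = 0
    n_populations: int = 2
    ancestral_pool_size: int | None = None
    ld_decay_cm: float = 0.4
    mutation_rate: float = 0.0
    n_autosome_chroms: int = 0
    chrom_name: str = "X"
    min_sweep_freq: float = 0.8
    max_sweep_restarts: int = 100

    def __post_init__(self) -> None:
        if isinstance(self.sweep, dict):
            self.sweep = SweepSpec(**self.sweep)
        if self.ancestral_pool_size is None:
            self.ancestral_pool_size = self.n_haplotypes_per_pop
        if min(self.n_haplotypes_per_pop, self.sample_size_per_pop,
               self.chrom_length_bp, self.target_n_snps, self.n_populations) <= 0:
            raise ValueError("all counts must be positive")
        if self.sweep.s < 0:
            raise ValueError("selection coefficient must be non-negative")
        if self.sweep.enabled and not 0 < self.sweep.position_bp <= self.chrom_length_bp:
            raise ValueError("sweep position must lie on the chromosome")

    @property
    def pop_labels(self) -> list[str]:
        return [f"pop{i + 1}" for i in range(self.n_populations)]

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class SimResult:
    samples: dict  # chrom -> {pop label -> HaplotypeSet} (sampled haplotypes)
    marker_map: MarkerMap
    truth: dict


# ---------------------------------------------------------------------------
# ancestral pool
# ---------------------------------------------------------------------------

def _spectrum_freqs(n_snps: int, pool: int, maf_floor: float, rng) -> np.ndarray:
    """Derived frequencies from a discrete density ~ 1/x."""
    grid = np.arange(1, pool) / pool
    lo = max(1.0 / pool, maf_floor)
    ok = (grid >= lo) & (grid <= 1 - lo)
    grid = grid[ok]
    w = 1.0 / grid
    w /= w.sum()
    return rng.choice(grid, size=n_snps, p=w)


def simulate_ancestral(
    config: SweepSimConfig, rng=None, chrom: str | None = None
) -> tuple[HaplotypeSet, MarkerMap]:
    """Ancestral haplotype pool plus marker map; deterministic under seed."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    chrom = chrom if chrom is not None else config.chrom_name
    n = config.target_n_snps
    pos = np.sort(rng.choice(
        np.arange(1, config.chrom_length_bp + 1), size=n, replace=False
    ))
    pos_cm = pos * config.recomb_cm_per_mb / 1e6
    p = _spectrum_freqs(n, config.ancestral_pool_size, config.maf_ascertain, rng)

    # latent Gaussian AR(1) copula: exact per-site marginals (the target
    # spectrum is preserved) with LD decaying over ld_decay_cm
    P = config.ancestral_pool_size
    from scipy.stats import norm as _norm

    z = np.empty((P, n))
    z[:, 0] = rng.standard_normal(P)
    for j in range(1, n):
        rho = np.exp(-(pos_cm[j] - pos_cm[j - 1]) / config.ld_decay_cm)
        z[:, j] = rho * z[:, j - 1] + np.sqrt(1 - rho * rho) * rng.standard_normal(P)
    H = (z < _norm.ppf(p)[None, :]).astype(np.uint8)

    freq = H.mean(axis=0)
    maf = np.minimum(freq, 1 - freq)
    keep = maf >= max(config.maf_ascertain, 1.0 / P)  # drop monomorphic too
    H = H[:, keep]
    pos, pos_cm = pos[keep], pos_cm[keep]

    bases = np.array(["A", "C", "G", "T"])
    ref = rng.choice(bases, size=keep.sum())
    alt = np.array([rng.choice(bases[bases != r]) for r in ref])
    mm = MarkerMap(pd.DataFrame({
        "snp_id": [f"{chrom}_snp{i + 1}" for i in range(int(keep.sum()))],
        "chrom": chrom,
        "pos_cm": pos_cm,
        "pos_bp": pos,
        "allele_a": ref,
        "allele_b": alt,
        "ancestral": 0,  # allele coded 0 is ancestral by construction
    }))
    hapset = HaplotypeSet("ancestral", H, np.ones(H.shape[1], dtype=bool),
                          mm.snp_ids)
    return hapset, mm


# ---------------------------------------------------------------------------
# forward Wright-Fisher
# ---------------------------------------------------------------------------

def _wf_generation(H, pos_cm, rng, sweep_col=None, s=0.0, mutation_rate=0.0):
    """One Wright-Fisher generation: every child recombines two uniformly
    (or fitness-weighted) chosen parents, crossover count Poisson in map
    length, breakpoints uniform in genetic distance."""
    N = H.shape[0]
    if sweep_col is not None and s > 0:
        w = (1.0 + s) ** H[:, sweep_col].astype(float)
        w /= w.sum()
        mothers = rng.choice(N, size=N, p=w)
        fathers = rng.choice(N, size=N, p=w)
    else:
        mothers = rng.integers(0, N, size=N)
        fathers = rng.integers(0, N, size=N)
    morgans = (pos_cm[-1] - pos_cm[0]) / 100.0
    n_cross = rng.poisson(morgans, size=N)
    start_with_mother = rng.random(N) < 0.5
    out = H[np.where(start_with_mother, mothers, fathers)].copy()
    for i in np.flatnonzero(n_cross > 0):
        breaks_cm = np.sort(rng.uniform(pos_cm[0], pos_cm[-1], size=n_cross[i]))
        segment = np.searchsorted(breaks_cm, pos_cm, side="right")
        use_first = segment % 2 == 0
        if start_with_mother[i]:
            first, second = mothers[i], fathers[i]
        else:
            first, second = fathers[i], mothers[i]
        out[i] = np.where(use_first, H[first], H[second])
    if mutation_rate > 0:
        flips = rng.random(H.shape) < mutation_rate
        out ^= flips.astype(np.uint8)
    return out


def _evolve(H0, pos_cm, generations, rng, sweep_col=None, s=0.0, mutation_rate=0.0):
    H = H0
    for _ in range(generations):
        H = _wf_generation(H, pos_cm, rng, sweep_col, s, mutation_rate)
    return H


def evolve_split(
    ancestral: HaplotypeSet, marker_map: MarkerMap, config: SweepSimConfig, rng=None
) -> dict[str, HaplotypeSet]:
    """Evolve each daughter population independently from the common pool.

    Neutral only — sweeps are layered on by :func:`impose_sweep` (which the
    top-level :func:`simulate_dataset` arranges).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    pos_cm = marker_map.df["pos_cm"].to_numpy(dtype=float)
    pops = {}
    for label in config.pop_labels:
        init = ancestral.haplotypes[
            rng.integers(0, ancestral.n_haplotypes, size=config.n_haplotypes_per_pop)
        ].copy()
        H = _evolve(init, pos_cm, config.generations_split, rng,
                    mutation_rate=config.mutation_rate)
        pops[label] = HaplotypeSet(label, H, ancestral.ancestral_known, ancestral.snp_ids)
    return pops


def _evolve_sweep(H0, pos_cm, generations, col, s, rng, mutation_rate=0.0,
                  stop_freq=0.9):
    """Selection epoch.

    Returns None early when the swept allele is lost; stops as soon as the
    allele reaches ``stop_freq`` so the population is sampled right at
    sweep completion rather than after post-fixation erosion.
    """
    H = H0
    for _ in range(generations):
        H = _wf_generation(H, pos_cm, rng, sweep_col=col, s=s,
                           mutation_rate=mutation_rate)
        x = H[:, col].mean()
        if x == 0:
            return None
        if x >= stop_freq:
            break
    return H


def impose_sweep(
    initial: HaplotypeSet, marker_map: MarkerMap, config: SweepSimConfig, rng=None
) -> tuple[HaplotypeSet, int]:
    """Forward phase with a recent hard sweep from a de-novo mutation.

    The population drifts neutrally up to selection onset; there the sweep
    site (the SNP nearest the configured position) receives a fresh derived
    allele on a single haplotype — the hard-sweep scenario, where one
    haplotype background hitchhikes to high frequency.  Genic selection
    (fitness ``(1+s)`` per derived copy) then acts over the remaining
    generations, whose number is set from the logistic fixation time so the
    sweep completes close to sampling; an older sweep would have its
    haplotype signature eroded by recombination, a younger one would not
    reach the conditioning frequency.

    Runs are conditioned on the derived allele finishing at frequency
    >= ``min_sweep_freq``; lost or under-threshold sweeps restart the
    selection epoch (bounded by ``max_sweep_restarts``).  Returns the
    evolved population and the sweep SNP index.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    pos_bp = marker_map.pos_bp
    pos_cm = marker_map.df["pos_cm"].to_numpy(dtype=float)
    s = config.sweep.s
    N = initial.n_haplotypes
    if s == 0:
        H = _evolve(initial.haplotypes.copy(), pos_cm, config.generations_split, rng,
                    mutation_rate=config.mutation_rate)
        col = int(np.argmin(np.abs(pos_bp - config.sweep.position_bp)))
        return HaplotypeSet(initial.population, H, initial.ancestral_known,
                            initial.snp_ids), col

    # logistic travel time 1/N -> ~0.9, the selection-epoch budget
    duration = int(np.ceil(np.log(9.0 * (N - 1)) / s))
    duration = min(max(duration, 1), config.generations_split)
    neutral_gens = config.generations_split - duration
    H_onset = _evolve(initial.haplotypes.copy(), pos_cm, neutral_gens, rng,
                      mutation_rate=config.mutation_rate)
    col = int(np.argmin(np.abs(pos_bp - config.sweep.position_bp)))

    for _ in range(config.max_sweep_restarts):
        H = H_onset.copy()
        H[:, col] = 0  # de-novo origin: one carrier haplotype
        H[rng.integers(0, N), col] = 1
        out = _evolve_sweep(H, pos_cm, duration, col, s, rng,
                            config.mutation_rate)
        if out is not None and out[:, col].mean() >= config.min_sweep_freq:
            return (
                HaplotypeSet(initial.population, out, initial.ancestral_known,
                             initial.snp_ids),
                col,
            )
    raise RuntimeError(
        f"sweep allele failed to reach frequency {config.min_sweep_freq} "
        f"in {config.max_sweep_restarts} attempts"
    )


# ---------------------------------------------------------------------------
# top-level dataset generation
# ---------------------------------------------------------------------------

def _simulate_chrom(config, chrom, seed_seq):
    rngs = [np.random.default_rng(s) for s in seed_seq.spawn(3 + config.n_populations)]
    ancestral, mm = simulate_ancestral(config, rngs[0], chrom=chrom)
    pos_cm = mm.df["pos_cm"].to_numpy(dtype=float)
    sweep_here = config.sweep.enabled and chrom == config.chrom_name
    pops = {}
    sweep_info = None
    for i, label in enumerate(config.pop_labels):
        rng = rngs[2 + i]
        init = ancestral.haplotypes[
            rng.integers(0, ancestral.n_haplotypes, size=config.n_haplotypes_per_pop)
        ].copy()
        init_set = HaplotypeSet(label, init, ancestral.ancestral_known, ancestral.snp_ids)
        if sweep_here and label == config.sweep.population:
            evolved, col = impose_sweep(init_set, mm, config, rng)
            sweep_info = {
                "population": label,
                "snp_index": col,
                "snp_id": str(mm.snp_ids[col]),
                "pos_bp": int(mm.pos_bp[col]),
                "s": config.sweep.s,
                "final_derived_freq": float(evolved.haplotypes[:, col].mean()),
            }
            pops[label] = evolved
        else:
            H = _evolve(init, pos_cm, config.generations_split, rng,
                        mutation_rate=config.mutation_rate)
            pops[label] = HaplotypeSet(label, H, ancestral.ancestral_known, ancestral.snp_ids)
    # sample study haplotypes (distinct chromosomes) from each population
    sample_rng = rngs[1]
    samples = {}
    for label, hapset in pops.items():
        take = sample_rng.choice(hapset.n_haplotypes,
                                 size=min(config.sample_size_per_pop, hapset.n_haplotypes),
                                 replace=False)
        samples[label] = hapset.subset_haplotypes(np.sort(take))
    return samples, mm, sweep_info


def simulate_dataset(config: SweepSimConfig) -> SimResult:
    """Simulate the focal chromosome plus optional neutral 'autosomes'.

    Autosome chromosomes (labelled "1", "2", ...) are always neutral and
    share the focal chromosome's configuration; they stand in for the
    genome-wide score distribution that calibrates empirical cutoffs.
    """
    root = np.random.SeedSequence(config.seed)
    chrom_names = [config.chrom_name] + [str(i + 1) for i in range(config.n_autosome_chroms)]
    seqs = root.spawn(len(chrom_names))
    samples: dict = {}
    maps = []
    truth = {"config": config.to_dict(), "seed": config.seed, "sweep": None}
    for chrom, seq in zip(chrom_names, seqs):
        chrom_samples, mm, sweep_info = _simulate_chrom(config, chrom, seq)
        samples[chrom] = chrom_samples
        maps.append(mm.df)
        if sweep_info is not None:
            truth["sweep"] = sweep_info
    marker_map = MarkerMap(pd.concat(maps, ignore_index=True))
    return SimResult(samples, marker_map, truth)


def write_fixture(result: SimResult, outdir) -> dict:
    """Write one phased VCF per population, a shared map TSV and a truth
    JSON; returns the paths.  Round-trips exactly through read_genotypes."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chroms = list(result.samples)
    pops = list(result.samples[chroms[0]])
    chrom_lengths = {
        c: int(result.truth["config"]["chrom_length_bp"]) for c in chroms
    }
    paths = {"vcf": {}, "map": str(outdir / "markers.tsv"),
             "truth": str(outdir / "truth.json")}
    for pop in pops:
        blocks = [result.samples[c][pop].haplotypes for c in chroms]
        known = np.concatenate([result.samples[c][pop].ancestral_known for c in chroms])
        full = HaplotypeSet(pop, np.hstack(blocks), known, result.marker_map.snp_ids)
        vcf_path = outdir / f"{pop}.vcf"
        io_qc.write_vcf(full, result.marker_map, vcf_path, chrom_lengths)
        paths["vcf"][pop] = str(vcf_path)
    io_qc.write_map(result.marker_map, paths["map"])
    with open(paths["truth"], "w") as fh:
        json.dump(result.truth, fh, indent=2)
    return paths
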