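# sweepscan

Detection of selective-sweep footprints in SNP-chip data from small sets of
phased samples — the study design used for scans of livestock chromosomes,
where a few dozen individuals per breed are genotyped on a medium-density
array (~110 kb marker spacing) and several complementary statistics are
scanned along a chromosome.

The package implements five selection statistics, the two empirical
significance procedures used with them, the region-building conventions of
chip-scale scans, and a forward Wright-Fisher simulator that generates
phased two-or-more-population datasets with an optional hard sweep for
validating the whole pipeline.

## Statistics

**Haplotype-based (phased data).** Extended haplotype homozygosity around a
core SNP is the probability that two random carriers of the core allele are
identical over the intervening stretch,

    EHH = Σ_h C(e_h, 2) / C(c, 2),

with `c` carriers and `e_h` copies of each distinct extended haplotype; iHH
is its integral over genetic distance on both sides of the core.

* **iHS** (within population): `ln(iHH_A / iHH_D)` contrasting carriers of
  the ancestral vs. derived core allele, standardized within
  derived-allele-frequency bins; strongly negative scores mark new alleles
  that rose quickly on one haplotype background.
* **XPEHH** (between populations): `ln(iHH_obs / iHH_ref)` with the core
  pooled over all haplotypes of each population; positive scores point at
  the observed population, negative at the reference.

**Frequency-based (genotype data suffice).**

* **Bayesian Fst**: per SNP, each population's allele frequency gets a
  `Beta(x+1, n−x+1)` posterior; joint draws are converted to Fst draws via
  `Fst = [Σ_r (p_r − p̄)²/R] / [p̄(1 − p̄)]` (0 = identical populations,
  1 = fixed for alternate alleles) and summarized by the posterior mean.
* **Tajima's D** in 800-kb windows: standardized difference between mean
  pairwise diversity π and the segregating-sites estimate `S/a1`; negative
  after recent sweeps, positive under balancing selection.
* **XPCLR-style composite likelihood**: observed-population allele counts
  are scored under neutral drift around the reference frequencies
  (variance `ω·p(1−p)`, truncated normal with boundary atoms) versus a
  hitchhiking model in which SNPs escape a sweep with probability
  `c = 1 − exp(−ρ·r/s)`; the window score is
  `CLR = 2[max_s Σ w_i ll_sweep − Σ w_i ll_neutral] ≥ 0`, with LD-based
  weights `w_i` from the reference population.

**Significance.** Haplotype/composite statistics are thresholded at the
empirical top 5% of their genome-wide distribution on neutral "autosome"
chromosomes (two-sided where the sign is informative); Fst and Tajima's D
use permutation nulls built by shuffling each population's allele
frequencies across the fixed SNP positions (default 5000 permutations,
alpha 0.05). SNP-level outliers extend ±400 kb and merge into selection
regions; window statistics flag whole fixed-length 800-kb windows.

## Worked example

Simulate two populations (34 diploid females each on a 20-Mb chromosome
with ~110-kb marker spacing, plus two neutral calibration chromosomes)
with a hard sweep at s = 0.05 near 10 Mb in `pop1`, then scan:

```python
from sweepscan import RunConfig, run_pipeline
from sweepscan.simulate import SweepSimConfig, SweepSpec, simulate_dataset, write_fixture

config = SweepSimConfig(
    seed=7, n_autosome_chroms=2,
    sweep=SweepSpec(enabled=True, position_bp=10_000_000, s=0.05, population="pop1"),
)
data = simulate_dataset(config)
paths = write_fixture(data, "example/data")      # phased VCFs + map + truth
print(data.truth["sweep"])
# {'population': 'pop1', 'snp_index': 94, 'snp_id': 'X_snp95',
#  'pos_bp': 9997796, 's': 0.05, 'final_derived_freq': 0.902}

run = RunConfig(
    populations=paths["vcf"], map_path=paths["map"], outdir="example/scan",
    methods=["xpehh", "fst"], target_chrom="X",
    chrom_length_bp=config.chrom_length_bp, n_perm=1000, seed=11,
)
run_pipeline(run)
```

The summary table (`example/scan/summary.tsv`) and the XPEHH region BED:

```
method population  n_regions  mean_length_mb  mean_snps_per_region
   fst       pop1          0          0.0000                0.0000
   fst       pop2          0          0.0000                0.0000
 xpehh       pop1          4          0.8893               12.0000
 xpehh       pop2          3          1.0662                9.6667

X  9793298  10854739  xpehh:pop1  0.8124   <- contains the true sweep site
```

The region `[9,793,298, 10,854,739)` flagged for `pop1` carries the
genome-wide peak XPEHH score (0.81) and contains the simulated sweep SNP at
9,997,796 bp. Positive-score regions are attributed to the observed
population (`pop1`), negative-score regions to the reference. The Fst
permutation threshold flags nothing here — single-SNP frequency contrast is
the least powerful of the five methods at this sample size, consistent with
its role as the strictest of the procedures.

The same pipeline runs from the shell:

```bash
sweepscan simulate --config sim.json --out data/
sweepscan run --config run.json
sweepscan report data/scan/regions_*.bed --map data/markers.tsv
sweepscan overlap data/scan/regions_*.bed
```

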