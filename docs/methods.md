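# Methods

This note records the statistical models implemented in `sweepscan`, the
defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical conventions that matter for
reproducing results.

## Quality control

Filters run in a fixed order: individual call rate ≥ 0.90, SNP call rate
≥ 0.90, Hardy-Weinberg exact-test p ≥ 1e-6, and — only for
within-population haplotype statistics — minor allele frequency ≥ 0.05.
The HWE test is the exact conditional test (enumeration over heterozygote
counts given the allele counts, two-sided by cumulative probability), the
standard choice for chip QC because it is exact at small sample sizes. HWE
is tested per population under analysis. The pipeline ingests
female/homogametic samples by contract, so no hemizygote handling is
needed on X data.

Haplotype statistics require phased, complete input (`0|1` VCF genotypes
or a haplotype-matrix text file); no imputation or statistical phasing is
performed. Frequency statistics tolerate missing genotypes through per-SNP
observed allele counts.

## Haplotype statistics

EHH at a target SNP is the exact pair-counting form
`Σ_h C(e_h,2) / C(c,2)` among the carriers of the core allele; the curve
is evaluated SNP by SNP outward (each SNP refines the haplotype partition)
and truncated at the first value below 0.05, at the chromosome end
(scores there carry an `edge` flag), or at 1 cM from the core. The 1-cM
integration bound matters: in populations with small effective size,
baseline identity-by-descent holds EHH above the truncation level over
multi-cM scales, and an unbounded integral measures chromosome-scale
relatedness instead of local sweep structure. One centimorgan at the
default marker density spans ~9 markers and comfortably covers the extent
of hitchhiking for the selection strengths of interest.

iHH is the trapezoidal integral of EHH over genetic distance (cM), both
sides of the core summed. Where the map supplies no cM positions a
constant 1 cM/Mb is assumed (configurable). Ties in cM contribute zero
area.

iHS = ln(iHH_ancestral / iHH_derived) requires ancestral orientation, read
from the marker map (`AA` INFO field or map column); unoriented SNPs are
skipped and counted, with an optional, loudly-warned fallback that
polarizes by the major allele. Standardization subtracts the mean and
divides by the standard deviation within derived-allele-frequency bins
(width 0.02; bins with fewer than 20 scores merge into their nearest
neighbour), because the raw statistic's null distribution depends strongly
on the derived-allele frequency. XPEHH pools all haplotypes at the core
(no allele split) and is reported raw and, optionally, globally z-scored;
its sign carries direction (positive = observed population).

## Frequency statistics

The two-step Bayesian Fst treats each population's per-SNP allele
frequency as `Beta(x+1, n−x+1)` under a uniform prior, draws jointly, and
converts each draw vector to a per-locus Fst through the Wright-style
ratio `[Σ_r (p_r−p̄)²/R] / [p̄(1−p̄)]` with the unweighted population mean
p̄ (populations enter symmetrically regardless of sample size); the
posterior mean over (default) 1000 draws is the per-SNP statistic. The
ratio is defined as 0 when p̄ is 0 or 1 (no variation to apportion), and
hits 1 exactly for populations fixed for alternate alleles. The published
second-stage mixture clustering of the Fst draws is not implemented:
significance is decided by the permutation machinery instead.

Tajima's D is computed per 800-kb window from per-site allele counts, with
π as `Σ 2x(n−x)/(n(n−1))` (identical to the average pairwise difference)
and the standard variance constants as functions of the haplotype sample
size n. Windows with no segregating site are flagged missing. D is
invariant to allele-label flips, so ancestral orientation is not needed.

## XPCLR-style composite likelihood

Neutral model: given reference frequency p and drift intensity ω, the
observed-population frequency q is normal with mean p and variance
`ω·p(1−p)`, truncated to (0,1) with the tail masses as atoms at the
boundaries; the observed allele count is binomial given q. The integral is
evaluated by trapezoidal quadrature on 201 nodes placed adaptively over
p ± 8 standard deviations (clipped to (0,1)), which converges in both the
tight- and broad-drift regimes; doubling the node count changes
log-likelihoods by < 1e-4 in the tested range.

Sweep model: each SNP at genetic distance r (cM) from the window centre
escapes the sweep with probability `c = 1 − exp(−ρ·(r/100)/s)` (r
converted to Morgans; ρ defaults to ln(2N) with N = 100) and otherwise
its frequency is concentrated at the boundary of whichever allele class
hitchhiked: an atom at 1 with prior weight p plus an atom at 0 with weight
1−p, each atom paired with a `Beta(50,1)`/`Beta(1,50)` slab carrying half
the component's mass so that interior counts never have zero likelihood.
`s = 0` forces c = 1 and reduces exactly to the neutral model, which makes
`CLR = 2[max_s Σ w_i ll_s − Σ w_i ll_0] ≥ 0` by construction (the grid is
0 plus 12 log-spaced values in [1e-4, 0.5]).

Reference frequencies are shrunk to the uniform-prior posterior mean
`(x+1)/(n+2)` so the drift density stays defined at SNPs fixed in the
finite reference sample — exactly the SNPs that carry the strongest sweep
information. ω is estimated by the method of moments,
`mean[(p_obs−p_ref)²/(p_ref(1−p_ref))]`, over SNPs segregating in the
reference; sampling noise inflates it slightly, making the scan mildly
conservative. Windows tile the chromosome in 0.5-cM steps, use at most the
100 SNPs nearest the window centre, and need ≥ 3 informative SNPs.
LD weights group SNPs whose r² in the reference exceeds 0.95 (transitive
closure) and give each SNP 1/group-size, so a block of duplicated markers
counts once. The scan is directional: each population of a pair is scored
once as observed, matching reciprocal reporting.

## Significance and regions

Autosomal cutoffs take the empirical top 5% of a genome-wide score
distribution from neutral calibration chromosomes (linear-interpolation
quantiles; two-sided variants use 2.5% per tail). Permutation nulls
shuffle each population's per-SNP frequency information independently
across the fixed SNP positions — independent shuffling also breaks
cross-population coupling, giving a proper no-differentiation null for
Fst — and recompute the statistic per permutation (per SNP for Fst, by
re-pairing pre-drawn Beta posterior samples, which is exactly a
permutation of the frequency posteriors; per window for Tajima's D).
Pooled permuted values supply the 1−α quantile (and the α quantile as a
lower cutoff for D). Permutation is not offered for haplotype/composite
statistics: shuffling frequencies destroys the LD those statistics
measure, so their null would be incoherent.

Scores strictly beyond a cutoff are outliers; exact ties are not flagged.
Signed XPEHH outliers are attributed to the observed (positive) or
reference (negative) population. SNP-level outliers extend ±400 kb each
way, clip at chromosome bounds, and merge when overlapping or book-ended;
window-level methods flag whole 800-kb windows without merging. All
in-memory and BED intervals are 0-based half-open; physical positions in
I/O are 1-based, and a SNP at bp k·w belongs to window k (the boundary SNP
falls in the right-hand window). Overlap matrices report merged lengths on
the diagonal and pairwise intersection lengths off it, in Mb.

## Synthetic data generator

The generator produces the statistical structure the scans assume, not a
demographic reconstruction of any real breed history.

* **Ancestral pool**: SNP positions uniform on a 20-Mb chromosome
  (default 180 markers ≈ 110-kb spacing); derived-allele frequencies from
  a discrete `∝ 1/x` spectrum; haplotypes from a latent Gaussian AR(1)
  copula whose correlation decays as `exp(−d/0.4 cM)`, giving
  adjacent-marker r² ≈ 0.2–0.3 (chip-scale LD) while preserving the
  marginal spectrum exactly. Array-style ascertainment drops SNPs with
  pool MAF < 0.05.
* **Divergence**: each population is a resample of the pool evolved 300
  Wright-Fisher generations at 3000 haplotypes (drift time 0.1 per
  branch). These defaults keep ~90% of the panel polymorphic within each
  population — as on a real chip, whose content was ascertained in the
  modern populations — at the cost of between-population Fst (~0.06–0.1)
  at the low end of real livestock pairs. Crossovers are Poisson in map
  length with breakpoints uniform in genetic distance.
* **Hard sweep**: a de-novo beneficial mutation is placed on a single
  haplotype at the marker nearest the configured position, at a selection
  onset computed from the logistic fixation time (`ln(9(N−1))/s`
  generations before sampling) so the allele completes its rise close to
  sampling time; genic selection weights parents by `(1+s)` per derived
  copy; the selection epoch stops at first passage of frequency 0.9 and
  the run is conditioned on reaching ≥ 0.8 (bounded restarts). Sampling
  at completion matters: a sweep that fixes long before sampling has its
  haplotype signature eroded by recombination, and a sweep from standing
  variation is soft (the allele rides many backgrounds) and near-invisible
  to EHH-based statistics.
* **Calibration chromosomes**: optional neutral "autosomes" simulated
  under the same configuration stand in for the genome-wide distribution
  behind the empirical cutoffs.

All randomness flows from one integer seed through spawned generator
streams; reruns are byte-identical.  `write_fixture` emits one phased VCF
per population, a shared marker-map TSV and `truth.json`, which echoes the
full configuration (including the seed, so the files can be regenerated
exactly) plus the realized sweep: population, SNP id/index, position,
selection coefficient and final derived-allele frequency.

What the generator does **not** emulate: realistic livestock demography
(bottlenecks, migration, variable Ne), new mutations during divergence
(optional recurrent flipping exists but defaults off), variable
recombination rate, genotyping error, and the ascertainment bias of real
chips toward intermediate frequencies in several breeds at once. Passing
validation on these data therefore demonstrates correctness of the
statistics and calibration of the procedures under a clean two-population
drift model, not expected power on any particular real dataset.

## Validation design choices

* Tajima's D neutrality is checked on equilibrium data (populations
  sampled directly from the neutral-spectrum pool, no ascertainment floor)
  because drift without mutation input ages the frequency spectrum and
  drives D genuinely positive — a property of that scenario, not an error;
  likewise the MAF≥0.05 ascertainment floor removes rare variants and
  biases D upward on chip panels.
* Permutation type-I error is measured on data generated under the
  permutation's own null: population frequency vectors drawn independently
  (cross-pairing two independent simulations). With a shared ancestor the
  matched pairs are positively coupled and the test is conservative by
  design.
* Sweep localization uses per-window summaries matched to each statistic's
  signature: fraction of SNPs with standardized iHS < −2 (extreme-fraction
  ranking in the negative, derived-sweep tail), mean |XPEHH|, and maximum
  CLR; a method localizes a replicate when the sweep-containing 800-kb
  window ranks in the top decile of the 25 windows.
* Problem sizes in the test suite: statistical checks run at the default
  study scale (3000-haplotype populations, 68-haplotype samples, 180
  markers, 50 sweep replicates, 20 neutral replicates, 1000 permutations);
  mechanical unit tests use smaller configurations.

## Known limitations

* Between-population differentiation under the default divergence is
  modest; scans of strongly diverged pairs should raise
  `generations_split` (at the expense of within-population polymorphism).
* iHS loses power as sweeps complete (the classic blind spot of the
  statistic); with ~34 diploid samples the minor-allele haplotype class at
  high derived frequencies is small and its EHH noisy.
* The composite-likelihood drift model is a truncated-normal
  approximation; at drift intensities ω ≳ 0.5 it under-weights boundary
  accumulation relative to a diffusion solution, making the scan
  conservative in heavily drifted pairs.
* Multi-allelic sites are rejected at parse time; the pipeline is
  biallelic throughout.
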