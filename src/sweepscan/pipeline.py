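"""End-to-end orchestration: QC -> statistics -> thresholds -> regions.

One :class:`RunConfig` drives the whole scan.  Between-population methods
(XPEHH, Fst, XPCLR) run per population pair on the pair's common SNPs;
within-population methods (iHS, Tajima's D) run per population on its
MAF-filtered SNP set.  Haplotype/composite methods take their cutoffs from
the empirical top fraction of the scores on the neutral "autosome"
chromosomes in the input; frequency methods use permutation nulls.

Per-population regions from different pairs merge into a single region set
per (method, population) — XPEHH partitions each pair's outliers by sign,
XPCLR runs reciprocally (each population once as observed), and an Fst
region belongs to both populations of its pair.

Outputs are a pure function of (inputs, config): tracks and window tables
as TSV, regions as BED, thresholds and a run manifest as JSON.
"""

from __future__ import annotations

import dataclasses
import itertools
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import haplotype_scan, io_qc, regions as regions_mod, sitefreq_scan
from .xpclr_scan import XpclrModel, estimate_omega, xpclr_scan
from .containers import HaplotypeSet, MarkerMap, ScoreTrack

logger = logging.getLogger(__name__)

BETWEEN_METHODS = {"xpehh", "xpclr", "fst"}
WITHIN_METHODS = {"ihs", "tajd"}
ALL_METHODS = BETWEEN_METHODS | WITHIN_METHODS

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "summarize_regions"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    populations: dict  # label -> phased VCF path
    outdir: str
    methods: list = field(default_factory=lambda: ["xpehh", "xpclr", "fst", "ihs", "tajd"])
    map_path: str | None = None
    target_chrom: str = "X"
    chrom_length_bp: int | None = None
    window_bp: int = 800_000
    extend_bp: int = 400_000
    fraction: float = 0.05
    alpha: float = 0.05
    n_perm: int = 5000
    n_draws: int = 1000
    seed: int = 0
    cm_per_mb: float = 1.0
    min_call_rate: float = 0.90
    hwe_alpha: float = 1e-6
    maf_min: float = 0.05
    truncation: float = 0.05
    max_extend_cm: float | None = 1.0
    min_autosome_scores: int = 100

    def __post_init__(self) -> None:
        unknown = set(self.methods) - ALL_METHODS
        if unknown:
            raise ValueError(f"unknown methods: {sorted(unknown)}")
        if not self.methods:
            raise ValueError("need at least one method")
        if BETWEEN_METHODS & set(self.methods) and len(self.populations) < 2:
            raise ValueError("between-population methods need at least two populations")
        if not self.populations:
            raise ValueError("need at least one population")

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**json.load(fh))


def _load_population(label, path, config) -> tuple[HaplotypeSet, MarkerMap]:
    gt, mm, haps = io_qc.read_genotypes(
        path, format="vcf", map_path=config.map_path, require_haplotypes=True
    )
    gt = io_qc.filter_individuals(gt, config.min_call_rate)
    gt, report = io_qc.filter_snps(
        gt, config.min_call_rate, config.hwe_alpha, config.maf_min, apply_maf=False
    )
    logger.info("qc %s: %s", label, report.to_dict("records"))
    keep = mm.indices_of(gt.snps)
    haps = haps.subset_snps(keep)
    haps.population = label
    return haps, mm.subset(keep)


def _split_chrom(haps: HaplotypeSet, mm: MarkerMap, chrom):
    mask = (mm.df["chrom"] == chrom).to_numpy()
    return haps.subset_snps(mask), mm.subset(mask)


def _pair_common(data, a, b):
    mm = io_qc.common_snps([data[a][1], data[b][1]])
    ids = mm.snp_ids
    ha = data[a][0].subset_snps(data[a][1].indices_of(ids))
    hb = data[b][0].subset_snps(data[b][1].indices_of(ids))
    return ha, hb, mm


def run_pipeline(config: RunConfig) -> dict:
    """Execute all requested methods; returns the run manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": dataclasses.asdict(config),
        "stages": [],
        "outputs": {"tracks": [], "regions_bed": {}, "thresholds": {}},
    }

    def stage(name):
        logger.info("stage: %s", name)
        manifest["stages"].append(name)

    try:
        stage("load")
        data = {
            label: _load_population(label, path, config)
            for label, path in config.populations.items()
        }
    except Exception as exc:
        raise PipelineError(f"stage load failed: {exc}") from exc

    pops = list(data)
    chroms = data[pops[0]][1].chroms
    target = config.target_chrom
    autosomes = [c for c in chroms if c != target]
    chrom_len = config.chrom_length_bp
    regions_by: dict[tuple[str, str], list] = {}
    rng_root = np.random.SeedSequence(config.seed)
    perm_seeds = iter(rng_root.generate_state(64).tolist())

    def need_autosomes(method):
        if not autosomes:
            raise PipelineError(
                f"stage {method} failed: empirical autosomal cutoffs need "
                "autosome chromosomes in the input"
            )

    def save_track(df, name):
        path = outdir / f"track_{name}.tsv"
        df.to_csv(path, sep="\t", index=False)
        manifest["outputs"]["tracks"].append(str(path))

    def save_threshold(thr, name):
        manifest["outputs"]["thresholds"][name] = dataclasses.asdict(thr)

    def add_regions(method, pop, regs):
        regions_by.setdefault((method, pop), []).extend(regs)

    # ---------------- within-population methods ----------------
    if "ihs" in config.methods:
        stage("ihs")
        need_autosomes("ihs")
        for pop in pops:
            haps, mm = data[pop]
            maf = np.minimum(haps.allele_freq(), 1 - haps.allele_freq())
            haps_f = haps.subset_snps(maf >= config.maf_min)
            mm_f = mm.subset(maf >= config.maf_min)
            tracks = []
            for chrom in chroms:
                h, m = _split_chrom(haps_f, mm_f, chrom)
                tracks.append(
                    haplotype_scan.ihs_track(
                        h, m, config.truncation, config.max_extend_cm, config.cm_per_mb
                    ).data
                )
            combined = pd.concat(tracks, ignore_index=True)
            std = haplotype_scan.standardize_scores(
                ScoreTrack("ihs", pop, combined), mode="freq_bins"
            ).data
            save_track(std, f"ihs_{pop}")
            auto_scores = std.loc[std["chrom"] != target, "std_score"]
            thr = regions_mod.autosomal_cutoff(
                auto_scores, config.fraction, two_sided=True, method="ihs",
                min_scores=config.min_autosome_scores)
            save_threshold(thr, f"ihs_{pop}")
            x_track = std[std["chrom"] == target]
            flagged = regions_mod.flag_outliers(x_track, thr, "std_score")
            add_regions("ihs", pop, regions_mod.build_regions(
                flagged, "ihs", pop, config.extend_bp, chrom_len, "std_score"))

    if "tajd" in config.methods:
        stage("tajd")
        for pop in pops:
            haps, mm = data[pop]
            maf = np.minimum(haps.allele_freq(), 1 - haps.allele_freq())
            haps_f = haps.subset_snps(maf >= config.maf_min)
            mm_f = mm.subset(maf >= config.maf_min)
            h, m = _split_chrom(haps_f, mm_f, target)
            x, n = h.allele_counts()
            wtrack = sitefreq_scan.tajimas_d_windows(
                x, h.n_haplotypes, m.pos_bp, config.window_bp, chrom_len, target
            )
            save_track(wtrack, f"tajd_{pop}")
            thr = regions_mod.permutation_threshold(
                "tajd", x=x, n=h.n_haplotypes, pos_bp=m.pos_bp,
                window_bp=config.window_bp, n_perm=config.n_perm,
                alpha=config.alpha, seed=next(perm_seeds), method="tajd",
            )
            save_threshold(thr, f"tajd_{pop}")
            add_regions("tajd", pop, regions_mod.flag_windows(wtrack, thr, "tajd", pop))

    # ---------------- between-population methods ----------------
    pairs = list(itertools.combinations(pops, 2))

    if "xpehh" in config.methods:
        stage("xpehh")
        need_autosomes("xpehh")
        for a, b in pairs:
            ha, hb, mm = _pair_common(data, a, b)
            tracks = []
            for chrom in chroms:
                mask = (mm.df["chrom"] == chrom).to_numpy()
                tracks.append(haplotype_scan.xpehh_track(
                    ha.subset_snps(mask), hb.subset_snps(mask), mm.subset(mask),
                    config.truncation, config.max_extend_cm, config.cm_per_mb,
                ).data)
            combined = haplotype_scan.standardize_scores(
                ScoreTrack("xpehh", a, pd.concat(tracks, ignore_index=True)),
                mode="global").data
            save_track(combined, f"xpehh_{a}_{b}")
            auto_scores = combined.loc[combined["chrom"] != target, "raw_score"]
            thr = regions_mod.autosomal_cutoff(
                auto_scores, config.fraction, two_sided=True, method="xpehh",
                min_scores=config.min_autosome_scores)
            save_threshold(thr, f"xpehh_{a}_{b}")
            x_track = combined[combined["chrom"] == target]
            flagged = regions_mod.flag_outliers(x_track, thr, "raw_score",
                                                signed_populations=(a, b))
            for pop in (a, b):
                sub = flagged[flagged["population"] == pop]
                add_regions("xpehh", pop, regions_mod.build_regions(
                    sub, "xpehh", pop, config.extend_bp, chrom_len, "raw_score"))

    if "xpclr" in config.methods:
        stage("xpclr")
        need_autosomes("xpclr")
        for a, b in pairs:
            for obs, ref in ((a, b), (b, a)):
                h_obs, h_ref, mm = _pair_common(data, obs, ref)
                x_ref = h_ref.haplotypes.sum(axis=0)
                n_ref = h_ref.n_haplotypes
                seg = (x_ref > 0) & (x_ref < n_ref)
                omega = estimate_omega(
                    (x_ref[seg] + 1) / (n_ref + 2),
                    (h_obs.haplotypes.sum(axis=0)[seg] + 1) / (h_obs.n_haplotypes + 2),
                    min_snps=min(100, max(10, int(seg.sum()))),
                )
                model = XpclrModel(omega=omega)
                tracks = []
                for chrom in chroms:
                    mask = (mm.df["chrom"] == chrom).to_numpy()
                    tracks.append(xpclr_scan(
                        h_obs.subset_snps(mask), h_ref.subset_snps(mask),
                        mm.subset(mask), model, config.cm_per_mb, chrom))
                combined = pd.concat(tracks, ignore_index=True)
                save_track(combined, f"xpclr_{obs}_vs_{ref}")
                with open(outdir / f"xpclr_{obs}_vs_{ref}_config.json", "w") as fh:
                    cfg = dataclasses.asdict(model)
                    cfg["s_grid"] = list(map(float, cfg["s_grid"]))
                    json.dump(cfg, fh, indent=2)
                auto_scores = combined.loc[combined["chrom"] != target, "clr"]
                thr = regions_mod.autosomal_cutoff(
                    auto_scores, config.fraction, two_sided=False, method="xpclr",
                    min_scores=config.min_autosome_scores)
                save_threshold(thr, f"xpclr_{obs}_vs_{ref}")
                x_track = combined[combined["chrom"] == target].rename(
                    columns={"grid_pos_bp": "pos_bp"})
                x_track = x_track.assign(snp_id=None)
                flagged = regions_mod.flag_outliers(x_track, thr, "clr")
                add_regions("xpclr", obs, regions_mod.build_regions(
                    flagged, "xpclr", obs, config.extend_bp, chrom_len, "clr"))

    if "fst" in config.methods:
        stage("fst")
        for a, b in pairs:
            ha, hb, mm = _pair_common(data, a, b)
            mask = (mm.df["chrom"] == target).to_numpy()
            ha_x, hb_x, mm_x = ha.subset_snps(mask), hb.subset_snps(mask), mm.subset(mask)
            xa, na = ha_x.allele_counts()
            xb, nb = hb_x.allele_counts()
            counts = sitefreq_scan.AlleleCounts(
                np.vstack([xa, xb]), np.vstack([na, nb]), mm_x.snp_ids)
            means, _ = sitefreq_scan.fst_posterior_track(
                counts, config.n_draws, next(perm_seeds))
            track = pd.DataFrame({
                "chrom": target, "pos_bp": mm_x.pos_bp,
                "snp_id": mm_x.snp_ids, "raw_score": means,
            })
            save_track(track, f"fst_{a}_{b}")
            thr = regions_mod.permutation_threshold(
                "fst", counts=counts, n_perm=config.n_perm, alpha=config.alpha,
                seed=next(perm_seeds), n_draws=config.n_draws, method="fst")
            save_threshold(thr, f"fst_{a}_{b}")
            wtrack = sitefreq_scan.window_scan(
                mm_x.pos_bp, means, config.window_bp, chrom_len, target)
            for pop in (a, b):  # an Fst region implicates both populations
                add_regions("fst", pop, regions_mod.flag_windows(wtrack, thr, "fst", pop))

    # ---------------- merge, report, write ----------------
    stage("report")
    merged = {
        key: regions_mod.merge_regions(regs, key[0], key[1])
        if key[0] in {"xpehh", "xpclr", "ihs"} else regs
        for key, regs in regions_by.items()
    }
    for (method, pop), regs in merged.items():
        path = outdir / f"regions_{method}_{pop}.bed"
        regions_mod.regions_to_bed(regs, path)
        manifest["outputs"]["regions_bed"][f"{method}_{pop}"] = str(path)

    maps_x = {pop: data[pop][1].for_chrom(target) for pop in pops}
    summary = summarize_regions(merged, maps_x)
    summary.to_csv(outdir / "summary.tsv", sep="\t", index=False)
    manifest["outputs"]["summary"] = str(outdir / "summary.tsv")

    for pop in pops:
        sets = {m: merged.get((m, pop), []) for m in config.methods}
        mat = regions_mod.overlap_matrix(sets)
        mat.to_csv(outdir / f"overlap_{pop}.tsv", sep="\t")
        manifest["outputs"][f"overlap_{pop}"] = str(outdir / f"overlap_{pop}.tsv")

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def summarize_regions(regions_by_method_pop: dict, maps_by_pop: dict | None = None) -> pd.DataFrame:
    """Per method x population: number of regions, mean length (Mb) and mean
    SNPs per region (counted against the population's analysis map when
    given, else from the regions' own flagged-SNP counts)."""
    rows = []
    for (method, pop), regs in sorted(regions_by_method_pop.items()):
        n = len(regs)
        mean_len = float(np.mean([r.length_bp for r in regs]) / 1e6) if n else 0.0
        if maps_by_pop is not None and pop in maps_by_pop and n:
            pos = maps_by_pop[pop].pos_bp
            snps = [int(((pos >= r.start) & (pos < r.end)).sum()) for r in regs]
            mean_snps = float(np.mean(snps))
        elif n:
            mean_snps = float(np.mean([r.n_snps for r in regs]))
        else:
            mean_snps = 0.0
        rows.append({
            "method": method, "population": pop, "n_regions": n,
            "mean_length_mb": round(mean_len, 4),
            "mean_snps_per_region": round(mean_snps, 4),
        })
    return pd.DataFrame(rows)
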