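"""Genotype/haplotype input, marker maps and chip-style quality control.

Quality control follows standard SNP-chip practice: individuals are dropped
on low call rate, then SNPs on low call rate, hard Hardy-Weinberg
disequilibrium (exact conditional test), and — only for within-population
haplotype statistics — low minor allele frequency.  The filter order
(individual call rate -> SNP call rate -> HWE -> MAF) is fixed.

Haplotype-based statistics require phased, complete input (``0|1`` GT
fields in VCF, or a plain-text haplotype matrix); frequency-based
statistics tolerate missing genotypes through per-SNP observed allele
counts.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .containers import (
    MISSING,
    UNKNOWN_ANCESTRAL,
    GenotypeTable,
    HaplotypeSet,
    MarkerMap,
)

__all__ = [
    "ParseError",
    "read_genotypes",
    "read_map",
    "write_map",
    "write_vcf",
    "filter_individuals",
    "filter_snps",
    "hwe_exact_p",
    "common_snps",
]


class ParseError(ValueError):
    """Raised when an input file cannot be parsed."""


# ---------------------------------------------------------------------------
# marker map TSV
# ---------------------------------------------------------------------------

def read_map(path) -> MarkerMap:
    """Read a marker-map TSV.

    Expected header columns: ``snp_id chrom pos_cm pos_bp`` and optionally
    ``allele_a allele_b ancestral`` (ancestral given as the allele letter,
    or ``.`` when unknown) — PLINK ``.map`` content plus two allele columns
    and an ancestral flag.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"snp_id", "chrom", "pos_cm", "pos_bp"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: map header must contain {sorted(required)}")
    if "ancestral" in df.columns and df["ancestral"].dtype == object:
        anc = np.full(len(df), UNKNOWN_ANCESTRAL, dtype=int)
        anc[df["ancestral"] == df.get("allele_a", "A")] = 0
        anc[df["ancestral"] == df.get("allele_b", "B")] = 1
        df["ancestral"] = anc
    return MarkerMap(df)


def write_map(marker_map: MarkerMap, path) -> None:
    df = marker_map.df.copy()
    anc = np.where(
        df["ancestral"] == 0,
        df["allele_a"],
        np.where(df["ancestral"] == 1, df["allele_b"], "."),
    )
    df["ancestral"] = anc
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# genotype input
# ---------------------------------------------------------------------------

def read_genotypes(path, format: str = "vcf", map_path=None, require_haplotypes: bool = False):
    """Read genotypes plus marker map.

    Parameters
    ----------
    path : str
        VCF file (``format="vcf"``) or whitespace-delimited haplotype
        matrix, one haplotype per row (``format="haps_text"``).
    map_path : str, optional
        Marker-map TSV; mandatory for ``haps_text``, merged (for cM /
        ancestral columns) when given alongside a VCF.
    require_haplotypes : bool
        Raise instead of returning ``haplotypes=None`` when the input is
        not fully phased and complete.

    Returns
    -------
    (GenotypeTable, MarkerMap, HaplotypeSet or None)
    """
    if format == "vcf":
        out = _read_vcf(path)
    elif format == "haps_text":
        if map_path is None:
            raise ValueError("haps_text input requires map_path")
        out = _read_haps_text(path, map_path)
    else:
        raise ValueError(f"unknown format {format!r}")
    gt, mm, haps = out
    if format == "vcf" and map_path is not None:
        mm = _merge_map(mm, read_map(map_path))
        if haps is not None:
            haps = HaplotypeSet(
                haps.population,
                haps.haplotypes,
                mm.df["ancestral"].to_numpy() != UNKNOWN_ANCESTRAL,
                haps.snp_ids,
            )
    if require_haplotypes and haps is None:
        raise ParseError(
            f"{path}: phased, complete genotypes required for haplotype statistics "
            "(found unphased or missing GT fields)"
        )
    return gt, mm, haps


def _merge_map(vcf_map: MarkerMap, ext_map: MarkerMap) -> MarkerMap:
    """Overlay cM positions / ancestral flags from an external map TSV."""
    df = vcf_map.df.set_index("snp_id")
    ext = ext_map.df.set_index("snp_id")
    shared = df.index.intersection(ext.index)
    df.loc[shared, "pos_cm"] = ext.loc[shared, "pos_cm"]
    ext_anc = ext.loc[shared, "ancestral"]
    df.loc[shared, "ancestral"] = np.where(
        ext_anc != UNKNOWN_ANCESTRAL, ext_anc, df.loc[shared, "ancestral"]
    )
    return MarkerMap(df.reset_index())


def _read_vcf(path):
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover
        raise ImportError("reading VCF requires cyvcf2") from exc

    try:
        vcf = VCF(str(path))
    except Exception as exc:
        raise ParseError(f"{path}: cannot open VCF ({exc})") from exc

    individuals = list(vcf.samples)
    rows = []
    calls_cols = []
    hap_cols = []
    phased_complete = True
    for i, variant in enumerate(vcf):
        if len(variant.ALT) > 1:
            raise ParseError(f"{path}: multi-allelic record at line entry {i + 1}")
        gts = variant.genotypes  # [a0, a1, phased] per sample
        col = np.empty(len(individuals), dtype=np.int8)
        hap = np.empty(2 * len(individuals), dtype=np.int8)
        for j, g in enumerate(gts):
            a = g[:-1]
            if len(a) != 2 or a[0] < 0 or a[1] < 0:
                col[j] = MISSING
                hap[2 * j : 2 * j + 2] = MISSING
                phased_complete = False
            else:
                col[j] = a[0] + a[1]
                hap[2 * j], hap[2 * j + 1] = a[0], a[1]
                if not g[-1] and a[0] != a[1]:
                    phased_complete = False  # het without phase
        calls_cols.append(col)
        hap_cols.append(hap)
        aa = variant.INFO.get("AA")
        alt = variant.ALT[0] if variant.ALT else "."
        anc = UNKNOWN_ANCESTRAL
        if aa is not None:
            if aa == variant.REF:
                anc = 0
            elif aa == alt:
                anc = 1
        rows.append(
            {
                "snp_id": variant.ID or f"{variant.CHROM}:{variant.POS}",
                "chrom": str(variant.CHROM),
                "pos_cm": np.nan,
                "pos_bp": variant.POS,
                "allele_a": variant.REF,
                "allele_b": alt,
                "ancestral": anc,
            }
        )
    if not rows:
        raise ParseError(f"{path}: VCF contains no variant records")
    mm = MarkerMap(pd.DataFrame(rows))
    calls = np.column_stack(calls_cols)
    gt = GenotypeTable(individuals, list(mm.snp_ids), calls)
    haps = None
    if phased_complete:
        matrix = np.column_stack(hap_cols)
        haps = HaplotypeSet(
            population="",
            haplotypes=matrix,
            ancestral_known=mm.df["ancestral"].to_numpy() != UNKNOWN_ANCESTRAL,
            snp_ids=mm.snp_ids,
        )
    return gt, mm, haps


def _read_haps_text(path, map_path):
    mm = read_map(map_path)
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.split()
            try:
                vals = [int(v) for v in fields]
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-integer haplotype symbol")
            if any(v not in (0, 1) for v in vals):
                raise ParseError(f"{path}:{lineno}: haplotype symbols must be 0/1")
            rows.append(vals)
    if not rows:
        raise ParseError(f"{path}: empty haplotype file")
    matrix = np.array(rows, dtype=np.uint8)
    if matrix.shape[1] != len(mm):
        raise ParseError(
            f"{path}: {matrix.shape[1]} columns but map has {len(mm)} SNPs"
        )
    haps = HaplotypeSet(
        population="",
        haplotypes=matrix,
        ancestral_known=mm.df["ancestral"].to_numpy() != UNKNOWN_ANCESTRAL,
        snp_ids=mm.snp_ids,
    )
    if matrix.shape[0] % 2:
        warnings.warn("odd number of haplotype rows; genotype table pairs all but last")
    n_ind = matrix.shape[0] // 2
    calls = (matrix[0 : 2 * n_ind : 2] + matrix[1 : 2 * n_ind : 2]).astype(np.int8)
    gt = GenotypeTable([f"ind{i + 1}" for i in range(n_ind)], list(mm.snp_ids), calls)
    return gt, mm, haps


def write_vcf(hapset: HaplotypeSet, marker_map: MarkerMap, path, chrom_lengths=None) -> None:
    """Write a phased diploid VCF; consecutive haplotypes pair into samples."""
    if hapset.n_haplotypes % 2:
        raise ValueError("need an even number of haplotypes to write diploid VCF")
    n_ind = hapset.n_haplotypes // 2
    samples = [f"{hapset.population or 'sample'}_{i + 1}" for i in range(n_ind)]
    df = marker_map.df
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in dict.fromkeys(df["chrom"]):
            length = None if chrom_lengths is None else chrom_lengths.get(chrom)
            if length is None:
                length = int(df.loc[df["chrom"] == chrom, "pos_bp"].max()) + 1
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(samples) + "\n")
        H = hapset.haplotypes
        for k in range(len(df)):
            row = df.iloc[k]
            anc = row["ancestral"]
            if anc == 0:
                info = f"AA={row['allele_a']}"
            elif anc == 1:
                info = f"AA={row['allele_b']}"
            else:
                info = "."
            gts = "\t".join(
                f"{H[2 * i, k]}|{H[2 * i + 1, k]}" for i in range(n_ind)
            )
            fh.write(
                f"{row['chrom']}\t{row['pos_bp']}\t{row['snp_id']}\t"
                f"{row['allele_a']}\t{row['allele_b']}\t.\tPASS\t{info}\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# QC filters
# ---------------------------------------------------------------------------

def filter_individuals(gt: GenotypeTable, min_call_rate: float = 0.90) -> GenotypeTable:
    """Keep individuals with call rate >= ``min_call_rate`` (order kept)."""
    if not 0 < min_call_rate <= 1:
        raise ValueError("min_call_rate must be in (0, 1]")
    keep = gt.individual_call_rate() >= min_call_rate
    if not keep.any():
        warnings.warn("individual call-rate filter removed every individual")
    return gt.subset_individuals(keep)


def filter_snps(
    gt: GenotypeTable,
    min_call_rate: float = 0.90,
    hwe_alpha: float = 1e-6,
    maf_min: float = 0.05,
    apply_maf: bool = False,
) -> tuple[GenotypeTable, pd.DataFrame]:
    """Chip-style SNP filters, applied in fixed order.

    1. SNP call rate < ``min_call_rate``;
    2. Hardy-Weinberg exact-test p-value < ``hwe_alpha``;
    3. minor allele frequency < ``maf_min`` — only when ``apply_maf`` is
       true (the MAF filter is scoped to within-population haplotype
       statistics; between-population statistics keep rare SNPs).

    Returns the filtered table and a report DataFrame
    (columns ``filter``, ``n_removed``).
    """
    report = []

    keep = gt.snp_call_rate() >= min_call_rate
    report.append({"filter": "call_rate", "n_removed": int((~keep).sum())})
    gt = gt.subset_snps(keep)

    pvals = np.ones(gt.n_snps)
    for j in range(gt.n_snps):
        col = gt.calls[:, j]
        col = col[col != MISSING]
        n_aa, n_ab, n_bb = int((col == 0).sum()), int((col == 1).sum()), int((col == 2).sum())
        if n_aa + n_ab + n_bb:
            pvals[j] = hwe_exact_p(n_aa, n_ab, n_bb)
    keep = pvals >= hwe_alpha
    report.append({"filter": "hwe", "n_removed": int((~keep).sum())})
    gt = gt.subset_snps(keep)

    if apply_maf:
        x, n = gt.allele_counts()
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(n > 0, x / np.maximum(n, 1), 0.0)
        maf = np.minimum(p, 1 - p)
        keep = maf >= maf_min
        report.append({"filter": "maf", "n_removed": int((~keep).sum())})
        gt = gt.subset_snps(keep)
    else:
        report.append({"filter": "maf", "n_removed": 0})

    return gt, pd.DataFrame(report)


def hwe_exact_p(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact conditional Hardy-Weinberg test.

    Two-sided by cumulative probability: sums the probabilities of all
    heterozygote configurations (given the allele counts) no more probable
    than the observed one.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n < 1:
        raise ValueError("need at least one genotype")
    n_a_alleles = 2 * n_aa + n_Aa  # minor-side allele count
    n_alleles = 2 * n
    rare = min(n_a_alleles, n_alleles - n_a_alleles)
    # heterozygote counts share the parity of the rare-allele count
    hets = np.arange(rare % 2, rare + 1, 2)
    from scipy.special import gammaln

    def logprob(h):
        homr = (rare - h) // 2
        homc = n - h - homr
        return (
            gammaln(n + 1)
            - gammaln(h + 1)
            - gammaln(homr + 1)
            - gammaln(homc + 1)
            + h * np.log(2.0)
            + gammaln(rare + 1)
            + gammaln(n_alleles - rare + 1)
            - gammaln(n_alleles + 1)
        )

    logs = logprob(hets.astype(float))
    logs -= max(logs.max(), -np.inf)
    probs = np.exp(logs)
    probs /= probs.sum()
    obs = probs[hets == n_Aa]
    if obs.size == 0:  # impossible configuration given allele counts
        raise ValueError("inconsistent genotype counts")
    p = probs[probs <= obs[0] * (1 + 1e-12)].sum()
    return float(min(p, 1.0))


def common_snps(maps: list[MarkerMap]) -> MarkerMap:
    """Intersect marker maps by snp_id, kept in the first map's order."""
    if len(maps) < 2:
        raise ValueError("need at least two maps to intersect")
    shared = set(maps[0].snp_ids)
    for m in maps[1:]:
        shared &= set(m.snp_ids)
    if not shared:
        raise ValueError("marker maps share no SNP ids")
    mask = np.isin(maps[0].snp_ids, list(shared))
    return maps[0].subset(mask)
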