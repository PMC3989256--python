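import numpy as np
import pandas as pd
import pytest

from sweepscan.containers import HaplotypeSet, MarkerMap
from sweepscan.simulate import SweepSimConfig, SweepSpec


def make_map(n, chrom="X", spacing_bp=100_000, cm_per_mb=1.0, ancestral=0):
    pos = (np.arange(n) + 1) * spacing_bp
    return MarkerMap(pd.DataFrame({
        "snp_id": [f"{chrom}_s{i + 1}" for i in range(n)],
        "chrom": chrom,
        "pos_cm": pos * cm_per_mb / 1e6,
        "pos_bp": pos,
        "allele_a": "A",
        "allele_b": "G",
        "ancestral": ancestral,
    }))


@pytest.fixture
def marker_map_10():
    return make_map(10)


@pytest.fixture
def small_hapset():
    """8 haplotypes x 10 SNPs with mixed structure, ancestral known."""
    rng = np.random.default_rng(42)
    H = rng.integers(0, 2, size=(8, 10)).astype(np.uint8)
    H[:, 4] = [1, 1, 1, 1, 0, 0, 0, 0]  # balanced core SNP
    return HaplotypeSet("toy", H, np.ones(10, dtype=bool))


def small_sim_config(**kwargs):
    """Scaled-down simulator configuration for fast mechanics tests."""
    defaults = dict(
        n_haplotypes_per_pop=200,
        sample_size_per_pop=40,
        chrom_length_bp=6_000_000,
        target_n_snps=60,
        generations_split=40,
        seed=0,
    )
    defaults.update(kwargs)
    return SweepSimConfig(**defaults)


@pytest.fixture
def sim_config():
    return small_sim_config()


@pytest.fixture
def sweep_config():
    return small_sim_config(
        generations_split=120,
        sweep=SweepSpec(enabled=True, position_bp=3_000_000, s=0.1, population="pop1"),
    )
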