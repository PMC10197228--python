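import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from coastgen import synthetic_data as sd
from coastgen.genotype_io import HaplotypeMatrix, PopulationMap
from coastgen.genotype_io import VariantTable


@pytest.fixture(scope="session")
def small_bundle():
    """A small but complete synthetic bundle (in memory) for I/O and
    integration tests: 1 chromosome, 1.5 Mb, 1500 SNPs, 4 sweeps."""
    cfg = sd.SimConfig(seed=11, n_demes=6, samples_per_deme=10, n_chrom=1,
                       chrom_length=1_500_000, n_snps=1500, n_env_loci=10)
    cfg.sweeps = [
        sd.SweepSpec("chr1", 200_000, 25_000, (0, 1), "A"),
        sd.SweepSpec("chr1", 600_000, 25_000, (4, 5), "B"),
        sd.SweepSpec("chr1", 1_000_000, 25_000, (0, 1), "A"),
        sd.SweepSpec("chr1", 1_400_000 - 30_000, 25_000, (4, 5), "B"),
    ]
    return sd.simulate_bundle(cfg)


@pytest.fixture()
def two_pop_map():
    def make(n_a: int, n_b: int) -> PopulationMap:
        ids = [f"a{i}" for i in range(n_a)] + [f"b{i}" for i in range(n_b)]
        pops = ["A"] * n_a + ["B"] * n_b
        return PopulationMap(dict(zip(ids, pops)), dict(zip(ids, pops)))

    return make


def random_two_pop_fixture(rng, n_a=3, n_b=3, n_snps=4):
    """Random haplotype matrix + map with both populations polymorphic."""
    while True:
        alle = rng.integers(0, 2, size=(2 * (n_a + n_b), n_snps)).astype(np.int8)
        ids = [f"a{i}" for i in range(n_a)] + [f"b{i}" for i in range(n_b)]
        pops = ["A"] * n_a + ["B"] * n_b
        pm = PopulationMap(dict(zip(ids, pops)), dict(zip(ids, pops)))
        hap = HaplotypeMatrix(alle, ids)
        p = alle.mean(axis=0)
        if np.all((p > 0) & (p < 1)):
            return hap, pm


def variants_for(hap, chrom="chr1", spacing=1000):
    n = hap.n_sites
    return VariantTable.from_arrays([chrom] * n,
                                    np.arange(1, n + 1) * spacing)
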