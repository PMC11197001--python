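import numpy as np
import pytest

from rohetscan.genotype_io import GenotypeMatrix, MarkerMap
from rohetscan.synthetic_data import PlantedSegment, SimConfig, simulate


def make_matrix(calls, chrom=None, pos=None, samples=None):
    """Small GenotypeMatrix from a 2-D array of codes."""
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape
    chrom = ["1"] * m if chrom is None else list(chrom)
    pos = np.arange(1, m + 1) * 100_000 if pos is None else np.asarray(pos)
    samples = [f"s{i}" for i in range(n)] if samples is None else samples
    markers = MarkerMap(
        chrom=np.array(chrom, dtype=object),
        snp_id=np.array([f"snp{i}" for i in range(m)], dtype=object),
        pos_bp=pos,
    ).validate()
    return GenotypeMatrix(samples=samples, calls=calls, markers=markers)


@pytest.fixture(scope="session")
def small_sim():
    """A small simulated panel (fast): 40 animals, 2 chromosomes."""
    cfg = SimConfig(
        n_animals=40,
        chrom_lengths_bp=(30_000_000, 30_000_000),
        snp_density_per_mb=60.0,
        planted=(
            # one shared identical ROHom + one private-haplotype ROHom + ROHet
            PlantedSegment("ROHom", "1", 5_000_000, 8_000_000, 0.25,
                           identical=True),
            PlantedSegment("ROHom", "2", 10_000_000, 14_000_000, 0.2),
            PlantedSegment("ROHet", "1", 20_000_000, 23_000_000, 0.25),
        ),
        seed=11,
    )
    g, truth = simulate(cfg)
    return cfg, g, truth


@pytest.fixture(scope="session")
def default_sim():
    """The default study conditions (200 animals, 20k-SNP HD master)."""
    cfg = SimConfig(seed=20240527)
    g, truth = simulate(cfg)
    return cfg, g, truth
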