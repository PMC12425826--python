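import numpy as np
import pytest

from pankit.multialign import build_pangenome
from pankit.synthetic import SimulationConfig, simulate_pangenome
from pankit.variants import call_snps, classify_all


SMALL_CONFIG = SimulationConfig(
    n_accessions=4,
    n_chromosomes=1,
    chrom_length=30_000,
    snp_rate=5e-4,
    n_insertions=6,
    n_deletions=4,
    n_satellites=1,
    te_families=3,
    te_length_range=(400, 2000),
    satellite_copies=(10, 20),
)


@pytest.fixture(scope="session")
def small_sim():
    """A compact simulated pangenome shared across unit tests."""
    genomes, truth = simulate_pangenome(SMALL_CONFIG, seed=1)
    return genomes, truth


@pytest.fixture(scope="session")
def small_alignment(small_sim):
    genomes, truth = small_sim
    aln = build_pangenome(genomes)
    return genomes, truth, aln


@pytest.fixture(scope="session")
def study_pipeline():
    """The full study conditions: 8 accessions, 2 x 300 kb, star genealogy,
    per-lineage SNP rate 5e-4, 60 TE insertions, 40 deletions, 4 satellite
    blocks (seed 1). Shared by the end-to-end acceptance tests."""
    genomes, truth = simulate_pangenome(SimulationConfig(), seed=1)
    aln = build_pangenome(genomes)
    snps = call_snps(aln, mode="all")
    loci = classify_all(aln)
    return genomes, truth, aln, snps, loci


def random_genome(rng: np.random.Generator, length: int) -> str:
    return rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=length).tobytes().decode()
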