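import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from splicescan.dataset import make_split
from splicescan.simulate import SimConfig, simulate_genome

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_sim():
    """A modest fixture genome: 4 x 60 kb contigs, 60 five-exon genes."""
    cfg = SimConfig(n_contigs=4, contig_len=60_000, n_genes=60, seed=7)
    genome, genes = simulate_genome(cfg)
    return cfg, genome, genes


@pytest.fixture(scope="session")
def small_split(small_sim):
    _, genome, genes = small_sim
    return make_split(genome, genes, seed=0)


@pytest.fixture(scope="session")
def tiny_sim():
    """A very small genome for format round-trips and CLI smoke tests."""
    cfg = SimConfig(
        n_contigs=4, contig_len=15_000, n_genes=24,
        n_exons_range=(3, 3), exon_len_range=(60, 120),
        intron_len_range=(50, 150), seed=5,
    )
    genome, genes = simulate_genome(cfg)
    return cfg, genome, genes


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
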