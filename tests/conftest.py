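import numpy as np
import pytest

from ibisgen import simulate as sim


@pytest.fixture(scope="session")
def cds_landscape():
    """A small coding landscape with effect-labelled implants (both strands)."""
    return sim.generate_cds_landscape(genome_length=150_000, gene_count=8,
                                      seed=11, n_synonymous=40)


@pytest.fixture(scope="session")
def small_wf():
    """One constant-size Wright-Fisher run with full truth."""
    cfg = sim.DemographyConfig(epochs=[(40, 15)], mu=0.0,
                               genome_length=500_000, n_initial_sites=120,
                               seed=7)
    return sim.simulate_wright_fisher(cfg, sample_size=10)


@pytest.fixture(scope="session")
def family_pedigree():
    """Four-generation managed-breeding pedigree from two founder pairs."""
    return sim.simulate_pedigree(founder_pairs=2, generations=4, seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
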