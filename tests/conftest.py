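import pytest
from hypothesis import settings

from allokit.simulate import (SimulationConfig, simulate_allopolyploid,
                              simulate_b_chromosome, simulate_observations)

settings.register_profile("suite", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_cfg():
    return SimulationConfig(n_chromosome_pairs=2, genes_per_chromosome=60,
                            codons_per_gene=60, seed=42)


@pytest.fixture(scope="session")
def small_sim(small_cfg):
    """One small allotetraploid with B chromosome and observations."""
    genome, truth = simulate_allopolyploid(small_cfg)
    genome, truth = simulate_b_chromosome(genome, small_cfg, truth)
    allele, coverage, truth = simulate_observations(genome, small_cfg, truth)
    return genome, truth, allele, coverage
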