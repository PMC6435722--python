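import numpy as np
import pytest
from hypothesis import settings

from m6dakit.calling import CallingParams, filter_sites
from m6dakit.simulate import (
    SimulationConfig,
    generate_genome,
    plant_m6dA,
    simulate_kinetics,
)

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


class Sim:
    """One simulated dataset shared by read-only tests."""

    def __init__(self, config: SimulationConfig):
        self.config = config
        self.genome, self.annotation, self.cluster_regions = generate_genome(config)
        self.true_sites = plant_m6dA(
            self.genome, self.annotation, config, self.cluster_regions
        )
        self.molecules, self.summaries = simulate_kinetics(
            self.true_sites, self.genome, config
        )
        self.params = CallingParams(
            mu0=config.mu0, sigma=config.sigma, delta=config.delta
        )
        self.called, self.null_set = filter_sites(self.summaries, self.params)


@pytest.fixture(scope="session")
def sim() -> Sim:
    """Default-condition simulation (diploid sample, coverage 40)."""
    return Sim(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def motif_sim() -> Sim:
    """Motif-recovery conditions: AG/GA placement bias with homogeneous
    methylation and no AT-rich cluster regions, so every planted site is
    callable and the failed-filter null set reduces to the unbiased
    genomic background (low-fraction planted sites and AT-cluster contexts
    would otherwise leak the placement bias into the null)."""
    return Sim(
        SimulationConfig(
            seed=13, n_clusters=0, spike_weight=1.0, hap_restricted_prop=0.0
        )
    )


@pytest.fixture(scope="session")
def tiny_config() -> SimulationConfig:
    """A small, fast configuration for end-to-end smoke tests."""
    return SimulationConfig(
        seed=7,
        chrom_sizes={"chr1": 60_000},
        n_genes=6,
        n_clusters=2,
        m6dA_density=0.008,
        coverage_mean=60.0,
        spot_check_density=0.002,
        trio_n_sites=300,
        trio_universe=8_000,
        common_pool_size=200,
    )


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
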