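import numpy as np
import pytest

from triorigin.simdata import (
    SimulationConfig,
    simulate_accessions,
    simulate_allele_depths,
    simulate_founders,
)


@pytest.fixture(scope="session")
def clean_cfg() -> SimulationConfig:
    """Noise-free study conditions shared across tests."""
    return SimulationConfig(
        seed=1,
        genome_length=30_000,
        within_pool_theta=0.0,
        error_rate=0.0,
        depth_mean=100.0,
        depth_dispersion=0.0,
    )


@pytest.fixture(scope="session")
def clean_sim(clean_cfg):
    """(founders, accessions, depths) for the clean seed-1 fixture."""
    founders = simulate_founders(clean_cfg)
    accessions = simulate_accessions(founders, clean_cfg)
    depths = simulate_allele_depths(accessions, clean_cfg)
    return founders, accessions, depths


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)
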