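import numpy as np
import pytest

from nddbias.keywords import default_keyword_map
from nddbias.simulate import SimulationConfig, simulate_cohort, simulate_interval_tracks


@pytest.fixture(scope="session")
def kmap():
    return default_keyword_map()


@pytest.fixture(scope="session")
def planted_scenario():
    return simulate_interval_tracks(seed=7)


@pytest.fixture(scope="session")
def small_cohort():
    """A 4,000-individual simulated cohort shared by pipeline-level tests."""
    config = SimulationConfig(n_individuals=4_000, seed=11)
    pheno, cnv, truth = simulate_cohort(config)
    return config, pheno, cnv, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
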