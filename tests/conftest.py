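import numpy as np
import pytest

from sigpevo.synthetic_data import SimulationConfig, simulate_dataset, \
    simulate_taxonomy


@pytest.fixture(scope="session")
def small_config():
    """Small but non-trivial study conditions for pipeline-level tests."""
    return SimulationConfig(seed=7, n_species=30, n_families=60,
                            predictor_noise=(0.0, 0.0, 0.0))


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_dataset(small_config)


@pytest.fixture(scope="session")
def species20():
    return simulate_taxonomy(SimulationConfig(seed=1, n_species=20))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
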