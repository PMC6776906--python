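import numpy as np
import pytest

from lysoquant import synthgen


@pytest.fixture(scope="session")
def small_config():
    return synthgen.SimulationConfig(rng_seed=11, n_cells=10)


@pytest.fixture(scope="session")
def small_field(small_config):
    return synthgen.generate_field(small_config)


@pytest.fixture(scope="session")
def noiseless_config():
    return synthgen.SimulationConfig(
        rng_seed=21,
        n_cells=8,
        noise_gaussian_sd=0.0,
        noise_poisson_gain=0.0,
    )


@pytest.fixture(scope="session")
def noiseless_field(noiseless_config):
    return synthgen.generate_field(noiseless_config)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
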