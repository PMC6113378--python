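import numpy as np
import pytest

from devkin import SigmoidParams, SimulationConfig, simulate_two_species_dataset


@pytest.fixture(scope="session")
def figure_params() -> SigmoidParams:
    """The worked-example activation curve: a=0.8, b=0.6, c=1, t_i=8 hpf."""
    return SigmoidParams(a=0.8, b=0.6, c=1.0, t_i=8.0)


@pytest.fixture(scope="session")
def default_dataset():
    config = SimulationConfig(seed=11)
    return config, simulate_two_species_dataset(config)


@pytest.fixture(scope="session")
def noiseless_dataset():
    config = SimulationConfig.noiseless(seed=11)
    return config, simulate_two_species_dataset(config)


@pytest.fixture(scope="session")
def small_dataset():
    """A reduced dataset for fit-heavy tests."""
    config = SimulationConfig(
        n_developmental=40, n_housekeeping=15, n_maternal=10, n_environmental=15, seed=5
    )
    return config, simulate_two_species_dataset(config)
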