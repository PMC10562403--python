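import numpy as np
import pytest

from perturbcite import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """One default-world synthetic dataset shared across tests."""
    return simulate_dataset(SimulationConfig(), seed=11)


@pytest.fixture(scope="session")
def tagonly_dataset():
    """Smaller tag-only dataset (no expression) for scoring tests."""
    return simulate_dataset(SimulationConfig(n_cells=2000, simulate_expression=False), seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
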