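import numpy as np
import pytest

from hdmediation import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """Quick dataset with all eight structural mediators (n=400, p=60)."""
    return simulate_dataset(SimulationConfig(n=400, p=60), seed=11)


@pytest.fixture(scope="session")
def big_dataset():
    """Large-sample dataset for consistency checks (n=10000, p=10)."""
    return simulate_dataset(SimulationConfig(n=10_000, p=10), seed=5)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
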