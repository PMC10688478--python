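import numpy as np
import pytest

from cistromix.simulate import SimConfig, Simulation, simulate


@pytest.fixture(scope="session")
def default_sim() -> Simulation:
    """One default-condition simulation shared across tests (seed fixed)."""
    return simulate(SimConfig(seed=20240917))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
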