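import numpy as np
import pytest

from microhost import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort (17 vs 19 samples), shared across tests."""
    return simulate_cohort(SimulationConfig(seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(20240915)
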