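import numpy as np
import pytest

import kneemon as km


@pytest.fixture(scope="session")
def fast_sim_config() -> km.SimulationConfig:
    """Protocol session with the rest period compressed so tests run fast."""
    return km.SimulationConfig(seed=7, rest_s=2.0)


@pytest.fixture(scope="session")
def sim_session(fast_sim_config):
    """One simulated coupled EMG + angle session with ground truth."""
    return km.simulate_session(fast_sim_config)


@pytest.fixture(scope="session")
def reference_cohort():
    return km.load_reference_cohort()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
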