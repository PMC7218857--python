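import numpy as np
import pytest

import imugait as ig


@pytest.fixture(scope="session")
def noiseless_trial():
    """Noiseless, bias-free 7-sensor trial with ground truth attached."""
    profile = ig.default_profile("flat", "normal", n_cycles=8)
    sensor = ig.SensorParams(fs=100.0, seed=11)
    return ig.simulate_trial(profile, sensor)


@pytest.fixture(scope="session")
def noiseless_states(noiseless_trial):
    return ig.calibrate_trial(noiseless_trial)


@pytest.fixture
def rng():
    return np.random.default_rng(20260101)
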