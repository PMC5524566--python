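import numpy as np
import pytest

from lfpbold.config import InputCondition, PopulationConfig, TrialConfig, baseline_condition


@pytest.fixture
def small_cfg():
    """A small population for fast unit tests."""
    return TrialConfig(n_neurons=20, duration=1.0, dt=0.001, rng_seed=123)


@pytest.fixture
def small_pcfg(small_cfg):
    return PopulationConfig(tau=0.010, trial=small_cfg)


@pytest.fixture
def default_pcfg():
    """The full-size population (200 neurons, 1 s at 1 kHz)."""
    return PopulationConfig(trial=TrialConfig(rng_seed=7))


@pytest.fixture
def blank():
    return baseline_condition()


@pytest.fixture
def rng():
    return np.random.default_rng(99)
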