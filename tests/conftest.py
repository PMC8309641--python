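import numpy as np
import pytest

from mieeg import CwtConfig, SimConfig, simulate_dataset, simulate_trial


@pytest.fixture(scope="session")
def strong_sim_config() -> SimConfig:
    """Strong, low-noise ERD/ERS — the clearly class-separable regime."""
    return SimConfig(
        erd_depth=0.75, ers_gain=1.5, noise_scale=0.2, n_trials_per_class=10, seed=7
    )


@pytest.fixture(scope="session")
def strong_trials(strong_sim_config):
    return simulate_dataset(strong_sim_config)


@pytest.fixture(scope="session")
def left_trial(strong_sim_config):
    return simulate_trial(strong_sim_config, "left", 5)


@pytest.fixture(scope="session")
def coarse_cwt_config() -> CwtConfig:
    """A light 2 Hz frequency grid for fast tests."""
    return CwtConfig(freqs=np.arange(8.0, 30.5, 2.0))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
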