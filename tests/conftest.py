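import datetime

import pytest

from orscreen import SimConfig, make_truth, simulate_primary_screen


@pytest.fixture(scope="session")
def small_config():
    """One-run screen: 85 receptors x 11 odors, a few planted agonists."""
    return SimConfig(n_receptors=85, n_odors=11, agonist_density=0.02)


@pytest.fixture(scope="session")
def quiet_config():
    """Same design with all stochastic terms switched off."""
    return SimConfig(
        n_receptors=85,
        n_odors=11,
        agonist_density=0.02,
        noise_sigma=0.0,
        well_efficiency_sigma=0.0,
        plate_gain_sigma=0.0,
        rl_noise_sigma=0.0,
    )


@pytest.fixture(scope="session")
def small_screen(small_config):
    """A simulated one-run primary screen plus its latent truth."""
    return simulate_primary_screen(small_config, seed=7)


@pytest.fixture(scope="session")
def small_truth(small_config):
    return make_truth(small_config, seed=7)


@pytest.fixture
def a_date():
    return datetime.date(2013, 3, 14)
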