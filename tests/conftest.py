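import numpy as np
import pytest

from thetaconn import PlantedCoupling, SimulationConfig, bandpass_theta, generate_epochs


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_config():
    """Small but fully structured generator config shared across unit tests."""
    return SimulationConfig(n_subjects=2, n_trials_per_cell=8, seed=99)


@pytest.fixture(scope="session")
def coupled_recording(tiny_config):
    """One theta-filtered cell with a single strong planted pair."""
    coup = [PlantedCoupling((("C5", "F3"),), kappa=0.8, lag=np.pi / 4)]
    rec = generate_epochs(tiny_config, coup, "Sleep", "L", subject=0)
    return bandpass_theta(rec)
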