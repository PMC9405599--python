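import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import windkessel5 as wk

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def waveform():
    return wk.DrivingWaveform()


@pytest.fixture(scope="session")
def init():
    return wk.InitialState()


@pytest.fixture(scope="session")
def grid():
    return wk.SimulationGrid()


@pytest.fixture(scope="session")
def fig3_caption_traj(waveform, init, grid):
    """One full-length reference simulation, shared across tests."""
    return wk.simulate(wk.PRESETS["fig3_caption"], waveform, init, grid)


@pytest.fixture(scope="session")
def fig6_traj(waveform, init, grid):
    return wk.simulate(wk.PRESETS["fig6"], waveform, init, grid)


@pytest.fixture(scope="session")
def omega(waveform):
    return waveform.omega


@pytest.fixture
def dense_t():
    return np.linspace(0.0, 60.0, 30001)
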