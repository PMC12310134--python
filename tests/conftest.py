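import numpy as np
import pytest

from threea import SchoolState, SimulationParams


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_params():
    """A small, fast parameter set for unit tests."""
    return SimulationParams(n_fish=20, total_time=10.0, seed=7)


def make_state(positions, headings, time=0.0):
    positions = np.asarray(positions, dtype=float)
    headings = np.asarray(headings, dtype=float)
    headings = headings / np.linalg.norm(headings, axis=1, keepdims=True)
    return SchoolState(time=time, positions=positions, headings=headings)


@pytest.fixture
def make_school():
    return make_state
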