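import numpy as np
import pytest

from attnflock.dynamics import AgentState, ModelParams
from attnflock.environment import EnvironmentSpec


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def empty_env():
    return EnvironmentSpec(box_size=25.0)


def make_state(positions, headings=None, informed=None, box_size=None):
    """Hand-built agent state for scenario tests."""
    pos = np.asarray(positions, dtype=float)
    n = len(pos)
    phi = np.zeros(n) if headings is None else np.asarray(headings, dtype=float)
    inf = np.zeros(n, dtype=bool) if informed is None else np.asarray(informed, dtype=bool)
    return AgentState(pos, phi, inf)


@pytest.fixture
def default_params():
    return ModelParams()
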