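import numpy as np
import pytest

from statebmi import SimParams, generate_session, make_default_schedule
from statebmi.pipeline import session_schedule


@pytest.fixture(scope="session")
def small_params():
    """A small but decodable session configuration (fast to generate)."""
    return SimParams(n_units=4, n_trials_per_stimulus=15, seed=42)


@pytest.fixture(scope="session")
def small_session(small_params):
    return generate_session(small_params)


@pytest.fixture(scope="session")
def small_schedule(small_session):
    """Default adaptive schedule matched to the small session's windows."""
    return session_schedule(small_session)


@pytest.fixture(scope="session")
def default_schedule():
    """The canonical 39-bin pre / 5-ms post schedule (50 ms response span)."""
    return make_default_schedule(0.75, 0.05, 0.030)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
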