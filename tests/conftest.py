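import numpy as np
import pytest

from fearsemble import synthdata
from fearsemble.io import Event, EventSchedule, EventType, TraceMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_session():
    """A 2+2-tone session spec small enough for fast tests."""
    return synthdata.SessionSpec(
        n_nt_tones=2, n_cs_tones=2, iti_s=30.0, pre_session_s=20.0, post_session_s=20.0
    )


@pytest.fixture
def mixed_population():
    return synthdata.PopulationSpec(
        n_neurons=60,
        archetype_fractions={"dual_plus": 0.2, "cs_plus": 0.3, "none": 0.5},
        response_amplitude=6.0,
        noise_sd=1.0,
        seed=7,
    )


@pytest.fixture
def simple_schedule():
    """Two NT tones at 100 s and 160 s, 15 s long."""
    return EventSchedule(
        [Event(EventType.NT, 100.0, 15.0), Event(EventType.NT, 160.0, 15.0)]
    )


def make_traces(values, rate_hz=10.0):
    return TraceMatrix(values=np.atleast_2d(np.asarray(values, float)), rate_hz=rate_hz)
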