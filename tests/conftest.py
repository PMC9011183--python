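import numpy as np
import pytest

from pupilresp.io_formats import EventTable, RawRecording


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_recording(pupil, dt=2, gaze_x=None, gaze_y=None, valid=None, rate=None, t0=0):
    """Hand-built recording from a pupil vector on a uniform ms grid."""
    pupil = np.asarray(pupil, dtype=float)
    n = len(pupil)
    time = t0 + dt * np.arange(n)
    if valid is None:
        valid = np.isfinite(pupil)
    gx = np.zeros(n) if gaze_x is None else np.asarray(gaze_x, dtype=float)
    gy = np.zeros(n) if gaze_y is None else np.asarray(gaze_y, dtype=float)
    return RawRecording("test", rate or 1000.0 / dt, time, pupil, gx, gy, np.asarray(valid, bool))


def make_events(onsets, category="sun", duration=1000):
    onsets = np.asarray(onsets)
    return EventTable(onsets, np.full(len(onsets), category, dtype=object),
                      np.full(len(onsets), duration))


@pytest.fixture
def recording_factory():
    return make_recording


@pytest.fixture
def event_factory():
    return make_events
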