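import numpy as np
import pytest

from ppgtrend import DeviceModel, RhythmParams
from ppgtrend.alignment import PairedSamples, PairedTrend


@pytest.fixture
def rhythm():
    return RhythmParams()


@pytest.fixture
def aww():
    return DeviceModel.aww()


@pytest.fixture
def fbt():
    return DeviceModel.fbt()


def make_pairs(t, p, h):
    return PairedSamples(
        np.asarray(t, float), np.asarray(p, float), np.asarray(h, float)
    )


def make_trend(t, P, H, frame_duration=None, window_size=10):
    t = np.asarray(t, float)
    fd = (
        np.asarray(frame_duration, float)
        if frame_duration is not None
        else np.full(t.size, 60.0)
    )
    return PairedTrend(t, np.asarray(P, float), np.asarray(H, float), fd,
                       window_size)


def random_trend(rng, n=20, base=100.0):
    """A small random trend pair for oracle comparisons."""
    t = np.cumsum(rng.uniform(3.0, 8.0, size=n))
    P = base + rng.normal(0, 8, size=n) + 0.01 * t
    H = base + rng.normal(0, 8, size=n) - 0.02 * t
    return make_trend(t, P, H)
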