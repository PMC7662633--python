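import numpy as np
import pytest

from emdhar.signal import TimeSeries


@pytest.fixture()
def two_tone() -> TimeSeries:
    """2 Hz + 40 Hz tones at 512 Hz for 4 s: a clean two-scale signal."""
    t = np.arange(512 * 4) / 512
    x = np.sin(2 * np.pi * 2 * t) + 0.5 * np.sin(2 * np.pi * 40 * t)
    return TimeSeries(x, 512.0, id="two_tone")


@pytest.fixture()
def tone_10hz() -> TimeSeries:
    """On-bin 10 Hz unit tone, 512 Hz, 4 s."""
    t = np.arange(512 * 4) / 512
    return TimeSeries(np.sin(2 * np.pi * 10 * t), 512.0, id="tone10")


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
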