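import numpy as np
import pytest

from delayrep import Trajectory

RATE = 200.0


@pytest.fixture
def rate():
    return RATE


@pytest.fixture
def sine_cycle():
    """One full 5 s sagittal sine cycle, 8 cm amplitude, at 200 Hz."""
    t = np.arange(0, 5 + 1 / RATE, 1 / RATE)
    return Trajectory(t=t, x=np.zeros_like(t), y=8 * np.sin(2 * np.pi * t / 5),
                      rate=RATE)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
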