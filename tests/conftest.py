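import numpy as np
import pytest

from breathwave.core import SensorTrace


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def breathing_trace():
    """A clean 20 s sensor trace with a 0.25 Hz sinusoidal breathing motion
    on every channel, built directly (not via the simulator)."""
    rate = 100.0
    t = np.arange(int(20 * rate)) / rate
    d = np.sin(2 * np.pi * 0.25 * t)
    theta = np.deg2rad(2.0 * d)
    channels = {
        "pressure": 10.0 + 2.0 * d,
        "accel_x": np.sin(theta),
        "accel_y": np.zeros_like(t),
        "accel_z": np.cos(theta),
        "mag_x": 30.0 + 1.0 * d,
        "mag_y": -10.0 + 0.5 * d,
        "mag_z": 40.0 + 5.0 * d,
        "gyro_x": np.zeros_like(t),
        "gyro_y": 2.0 * 2 * np.pi * 0.25 * np.cos(2 * np.pi * 0.25 * t),
        "gyro_z": np.zeros_like(t),
    }
    trace = SensorTrace(t, channels, rate)
    return trace, d
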