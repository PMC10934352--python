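"""Breathing-waveform extraction from thoracic-variation sensor channels.

Four methods, matching the four chest-piece sensing routes:

* ``pressure``   — contact force of the chest piece varies with the
  back-and-forth thoracic motion; lowpass the pressure channel.
* ``accel``      — parallel shift of the thorax appears as acceleration on
  the chest-normal axis; remove the gravity mean and lowpass. The output is
  the filtered acceleration itself (phase-consistent up to sign with the
  displacement; double integration is available but drifts).
* ``magnetic``   — a magnet on the deformable diaphragm surface shifts with
  chest-wall deflection, modulating the field at the magnetometer; take the
  field magnitude (orientation-robust), remove the mean, lowpass.
* ``accel_gyro`` — thoracic motion tilts the chest piece; fuse the
  accelerometer tilt with the gyro rate via a Kalman filter, then mean-remove
  and lowpass the angle.

Every extractor returns a zero-mean waveform on the trace's time axis; sign
is unconstrained because the evaluation correlates via the extremum of |R|
over lags.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import detrend

from .core import BreathWaveform, SensorTrace, ParameterError
from .config import RunConfig
from .filters import lowpass, kalman_angle, accel_to_angle

__all__ = [
    "SensorMethod",
    "SENSOR_METHODS",
    "extract_pressure",
    "extract_accel_shift",
    "extract_magnetic",
    "extract_accel_gyro",
    "extract",
]

#: The four thoracic extraction methods.
SENSOR_METHODS = ("pressure", "accel", "magnetic", "accel_gyro")

_REQUIRED_CHANNELS = {
    "pressure": ("pressure",),
    "accel": ("accel_x", "accel_y", "accel_z"),
    "magnetic": ("mag_x", "mag_y", "mag_z"),
    "accel_gyro": ("accel_x", "accel_y", "accel_z", "gyro_x", "gyro_y", "gyro_z"),
}


@dataclass
class SensorMethod:
    """Parameterization of one thoracic extraction route."""

    name: str
    lowpass_cutoff: float = 1.0
    #: chest-normal axis for the accel route
    axis: str = "z"
    #: single magnetometer axis, or None for vector magnitude
    mag_axis: str | None = None
    kalman: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.name not in SENSOR_METHODS:
            raise ParameterError(
                f"unknown method {self.name!r}; valid methods: {list(SENSOR_METHODS)}"
            )
        if self.axis not in ("x", "y", "z"):
            raise ParameterError(f"axis must be x, y or z, got {self.axis!r}")

    @property
    def required_channels(self) -> tuple:
        return _REQUIRED_CHANNELS[self.name]


def _finish(trace: SensorTrace, series: np.ndarray, cutoff: float,
            source: str) -> BreathWaveform:
    """Mean-remove, zero-phase lowpass, and re-center (exact zero mean)."""
    y = lowpass(series - series.mean(), trace.sample_rate, cutoff)
    y = y - y.mean()
    return BreathWaveform(trace.time, y, source=source)


def extract_pressure(trace: SensorTrace, cutoff: float = 1.0) -> BreathWaveform:
    """Breathing waveform from the chest-piece contact-pressure channel."""
    (p,) = trace.require("pressure")
    return _finish(trace, p, cutoff, "pressure")


def extract_accel_shift(trace: SensorTrace, cutoff: float = 1.0,
                        axis: str = "z", integrate: bool = False) -> BreathWaveform:
    """Breathing waveform from parallel-shift acceleration.

    Projects acceleration onto the chest-normal axis (default z, device worn
    flat), removes the gravity component as the series mean, and lowpasses.
    By default the waveform is the filtered acceleration itself;
    ``integrate=True`` double-integrates to displacement with linear
    detrending after each cumulative sum (integration noise drifts
    quadratically otherwise).
    """
    if axis not in ("x", "y", "z"):
        raise ParameterError(f"axis must be x, y or z, got {axis!r}")
    (a,) = trace.require(f"accel_{axis}")
    if integrate:
        dt = 1.0 / trace.sample_rate
        vel = detrend(np.cumsum(a - a.mean()) * dt)
        a = detrend(np.cumsum(vel) * dt)
    return _finish(trace, a, cutoff, "accel")


def extract_magnetic(trace: SensorTrace, cutoff: float = 1.0,
                     mag_axis: str | None = None) -> BreathWaveform:
    """Breathing waveform from magnet-deflection field changes.

    Uses the magnetic vector magnitude by default (robust to device
    orientation); a single axis can be selected instead.
    """
    if mag_axis is not None:
        if mag_axis not in ("x", "y", "z"):
            raise ParameterError(f"mag_axis must be x, y or z, got {mag_axis!r}")
        (b,) = trace.require(f"mag_{mag_axis}")
        scalar = b
    else:
        bx, by, bz = trace.require("mag_x", "mag_y", "mag_z")
        scalar = np.sqrt(bx * bx + by * by + bz * bz)
    return _finish(trace, scalar, cutoff, "magnetic")


def extract_accel_gyro(trace: SensorTrace, cutoff: float = 1.0,
                       q_angle: float = 0.001, q_bias: float = 0.003,
                       r_measure: float = 0.03) -> BreathWaveform:
    """Breathing waveform from thoracic angular displacement.

    Per-sample accelerometer tilt (about the mediolateral axis) is fused
    with the matching gyro rate (gyro_y) by the 2-state Kalman filter; the
    fused angle is then mean-removed and lowpassed.
    """
    ax, ay, az, gy = trace.require("accel_x", "accel_y", "accel_z", "gyro_y")
    tilt = accel_to_angle(ax, ay, az)
    dt = 1.0 / trace.sample_rate
    fused = kalman_angle(tilt, gy, dt, q_angle=q_angle, q_bias=q_bias,
                         r_measure=r_measure)
    return _finish(trace, fused, cutoff, "accel_gyro")


def extract(trace: SensorTrace, method: SensorMethod | str,
            config: RunConfig | None = None) -> BreathWaveform:
    """Dispatch to the extractor named by ``method``.

    A bare string selects a method with defaults taken from ``config``
    (or the package defaults when no config is given).
    """
    if isinstance(method, str):
        cfg = config or RunConfig()
        method = SensorMethod(
            method,
            lowpass_cutoff=cfg.lowpass_cutoff,
            kalman=dict(q_angle=cfg.kalman_q_angle,
                        q_bias=cfg.kalman_q_bias,
                        r_measure=cfg.kalman_r_measure),
        )
    if method.name == "pressure":
        return extract_pressure(trace, method.lowpass_cutoff)
    if method.name == "accel":
        return extract_accel_shift(trace, method.lowpass_cutoff, axis=method.axis)
    if method.name == "magnetic":
        return extract_magnetic(trace, method.lowpass_cutoff, mag_axis=method.mag_axis)
    return extract_accel_gyro(trace, method.lowpass_cutoff, **method.kalman)
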