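"""Digital-filtering primitives used by every extraction pipeline.

All filters are length-preserving. The Butterworth filters are applied
forward-backward (zero phase) so that waveform timing survives intact for
the cross-correlation evaluation; a causal filter would shift every method's
waveform by a different group delay and bias the lag estimates.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as _sig

from .core import ParameterError

__all__ = [
    "moving_average",
    "lowpass",
    "bandpass",
    "kalman_angle",
    "accel_to_angle",
]


def moving_average(values, width: int) -> np.ndarray:
    """Centered moving average with boundary windows shrunk to fit.

    Each output sample is the mean of the input samples inside a window of
    nominal size ``width`` centered on it; near the edges the window is
    truncated to the available samples, so constant sequences pass through
    unchanged and the output has the input's length.
    """
    if width < 1:
        raise ParameterError(f"width must be >= 1, got {width}")
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size == 0:
        raise ParameterError("values must be a non-empty 1-d sequence")
    if width == 1:
        return x.copy()
    kernel = np.ones(min(width, x.size))
    num = np.convolve(x, kernel, mode="same")
    den = np.convolve(np.ones(x.size), kernel, mode="same")
    return num / den


def _butter_sos(sample_rate, btype, edges, order=4):
    nyq = sample_rate / 2.0
    for f in np.atleast_1d(edges):
        if not 0 < f < nyq:
            raise ParameterError(
                f"filter edge {f} Hz outside (0, Nyquist={nyq} Hz) at fs={sample_rate} Hz"
            )
    return _sig.butter(order, edges, btype=btype, fs=sample_rate, output="sos")


def _zero_phase(sos, x):
    # sosfiltfilt needs len(x) > padlen; shrink padding for short inputs
    padlen = min(3 * (2 * sos.shape[0] + 1), x.size - 1)
    return _sig.sosfiltfilt(sos, x, padlen=padlen)


def lowpass(values, sample_rate: float, cutoff: float, order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth lowpass (default 4th order)."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ParameterError("lowpass needs at least 2 samples")
    sos = _butter_sos(sample_rate, "low", cutoff, order)
    return _zero_phase(sos, x)


def bandpass(values, sample_rate: float, low: float, high: float,
             order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth bandpass (default 4th order)."""
    if not low < high:
        raise ParameterError(f"need low < high, got ({low}, {high})")
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ParameterError("bandpass needs at least 2 samples")
    sos = _butter_sos(sample_rate, "bandpass", (low, high), order)
    return _zero_phase(sos, x)


def accel_to_angle(accel_x, accel_y, accel_z) -> np.ndarray:
    """Tilt angle (degrees) of the device about the mediolateral axis.

    Computed as atan2(a_x, a_z): 0° when gravity is along +z (device flat on
    the chest), 90° when along +x. Range (−180, 180]. The y component is
    accepted for interface symmetry and magnitude validation only; tilt about
    the mediolateral axis lives in the x–z plane.
    """
    ax = np.asarray(accel_x, dtype=float)
    ay = np.asarray(accel_y, dtype=float)
    az = np.asarray(accel_z, dtype=float)
    norm = np.sqrt(ax * ax + ay * ay + az * az)
    if np.any(norm == 0):
        raise ParameterError("zero acceleration vector: tilt undefined")
    return np.degrees(np.arctan2(ax, az))


def kalman_angle(accel_angle, gyro_rate, dt: float,
                 q_angle: float = 0.001, q_bias: float = 0.003,
                 r_measure: float = 0.03,
                 angle0: float | None = None, bias0: float = 0.0) -> np.ndarray:
    """Fuse accelerometer tilt with gyro rate via a 2-state Kalman filter.

    State is (angle in degrees, gyro bias in deg/s). Each step predicts
    ``angle += (rate − bias)·dt`` and propagates the 2×2 covariance with the
    dt-scaled process noise (q_angle, q_bias), then updates against the
    accelerometer-derived angle with measurement variance ``r_measure``.

    Limiting behaviour: as ``r_measure → 0`` the output follows the
    accelerometer angle; as ``r_measure → ∞`` it reduces to pure gyro
    integration.

    Parameters
    ----------
    accel_angle : sequence of degrees (tilt from gravity, noisy but unbiased)
    gyro_rate : sequence of deg/s (fast but drifting)
    dt : sampling interval, seconds

    Returns
    -------
    Fused angle sequence in degrees, same length as the inputs.
    """
    za = np.asarray(accel_angle, dtype=float)
    zg = np.asarray(gyro_rate, dtype=float)
    if za.shape != zg.shape or za.ndim != 1:
        raise ParameterError(
            f"accel_angle and gyro_rate must be equal-length 1-d, "
            f"got {za.shape} and {zg.shape}"
        )
    if dt <= 0:
        raise ParameterError(f"dt must be positive, got {dt}")
    if min(q_angle, q_bias, r_measure) <= 0:
        raise ParameterError("noise parameters must be positive")

    angle = za[0] if angle0 is None else float(angle0)
    bias = float(bias0)
    # covariance, start uncertain so early measurements dominate
    p00, p01, p10, p11 = 1.0, 0.0, 0.0, 1.0
    out = np.empty_like(za)
    for k in range(za.size):
        # predict
        rate = zg[k] - bias
        angle += dt * rate
        p00 += dt * (dt * p11 - p01 - p10 + q_angle)
        p01 -= dt * p11
        p10 -= dt * p11
        p11 += q_bias * dt
        # update against the accelerometer angle
        s = p00 + r_measure
        k0 = p00 / s
        k1 = p10 / s
        innov = za[k] - angle
        angle += k0 * innov
        bias += k1 * innov
        p00_, p01_ = p00, p01
        p00 -= k0 * p00_
        p01 -= k0 * p01_
        p10 -= k1 * p00_
        p11 -= k1 * p01_
        out[k] = angle
    return out
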