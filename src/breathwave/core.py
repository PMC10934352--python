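"""Domain types shared by every pipeline.

The package works with three kinds of time series:

* :class:`AudioSignal` — a mono breath-sound recording from the stethoscope
  microphone, uniformly sampled (typically 44.1 kHz).
* :class:`SensorTrace` — a timestamped multi-channel log from the chest-piece
  sensor rig: contact pressure, 3-axis accelerometer (g), 3-axis magnetometer
  (µT) and 3-axis gyroscope (deg/s).
* :class:`BreathWaveform` — the common output of every extraction method: a
  scalar time series tracking respiratory phase/effort, tagged with the
  method that produced it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AudioSignal",
    "SensorTrace",
    "BreathWaveform",
    "BreathwaveError",
    "FormatError",
    "ContentError",
    "ParameterError",
    "MissingChannelError",
    "SENSOR_CHANNELS",
    "WAVEFORM_SOURCES",
]

#: Fixed vocabulary of sensor-log column names.
SENSOR_CHANNELS = (
    "pressure",
    "accel_x", "accel_y", "accel_z",
    "mag_x", "mag_y", "mag_z",
    "gyro_x", "gyro_y", "gyro_z",
)

#: Fixed vocabulary of waveform provenance tags.
WAVEFORM_SOURCES = (
    "pressure", "accel", "magnetic", "accel_gyro",
    "microphone", "belt", "ground_truth",
)


class BreathwaveError(Exception):
    """Base class for all package errors."""


class FormatError(BreathwaveError):
    """A file could not be parsed in its declared format."""


class ContentError(BreathwaveError):
    """Parsed data violates an invariant (empty, non-monotonic, too short...)."""


class ParameterError(BreathwaveError, ValueError):
    """A parameter is outside its valid domain."""


class MissingChannelError(BreathwaveError, KeyError):
    """A required sensor channel is absent from the trace."""

    def __init__(self, missing, available):
        self.missing = tuple(missing)
        self.available = tuple(available)
        super().__init__(
            f"missing channel(s) {sorted(self.missing)}; "
            f"trace has {sorted(self.available)}"
        )

    def __str__(self):  # KeyError would repr() the tuple
        return self.args[0]


def _as_float_array(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise ContentError(f"{name} must be one-dimensional, got shape {arr.shape}")
    if arr.size == 0:
        raise ContentError(f"{name} is empty")
    if not np.all(np.isfinite(arr)):
        raise ContentError(f"{name} contains non-finite values")
    return arr


@dataclass
class AudioSignal:
    """Uniformly sampled mono audio, amplitude nominally within [-1, 1]."""

    samples: np.ndarray
    sample_rate: int

    def __post_init__(self):
        self.samples = _as_float_array(self.samples, "samples")
        if self.sample_rate <= 0:
            raise ParameterError(f"sample_rate must be positive, got {self.sample_rate}")
        self.sample_rate = int(self.sample_rate)

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return self.samples.size / self.sample_rate

    @property
    def time(self) -> np.ndarray:
        """Per-sample time axis in seconds, t=0 at the first sample."""
        return np.arange(self.samples.size) / self.sample_rate


@dataclass
class SensorTrace:
    """Multi-channel thoracic-variation record on a shared time axis.

    ``channels`` maps names from :data:`SENSOR_CHANNELS` to series of the same
    length as ``time``. Absent channels are simply missing — readers never
    fill them.
    """

    time: np.ndarray
    channels: dict
    sample_rate: float

    def __post_init__(self):
        self.time = _as_float_array(self.time, "time")
        if np.any(np.diff(self.time) <= 0):
            raise ContentError("time must be strictly increasing")
        if self.sample_rate <= 0:
            raise ParameterError(f"sample_rate must be positive, got {self.sample_rate}")
        clean = {}
        for name, series in self.channels.items():
            if name not in SENSOR_CHANNELS:
                raise ContentError(
                    f"unknown channel {name!r}; valid channels: {list(SENSOR_CHANNELS)}"
                )
            arr = _as_float_array(series, f"channel {name!r}")
            if arr.size != self.time.size:
                raise ContentError(
                    f"channel {name!r} has length {arr.size}, time has {self.time.size}"
                )
            clean[name] = arr
        self.channels = clean

    def require(self, *names: str) -> tuple:
        """Return the named channel arrays, raising if any is missing."""
        missing = [n for n in names if n not in self.channels]
        if missing:
            raise MissingChannelError(missing, self.channels.keys())
        return tuple(self.channels[n] for n in names)

    @property
    def duration(self) -> float:
        return float(self.time[-1] - self.time[0])


@dataclass
class BreathWaveform:
    """A respiratory phase/effort time series with provenance.

    ``phase`` is an optional per-sample label used by the simulator's ground
    truth (0 = pause, 1 = inhale, 2 = exhale); extraction methods leave it None.
    """

    time: np.ndarray
    values: np.ndarray
    source: str
    phase: np.ndarray | None = field(default=None)

    def __post_init__(self):
        self.time = _as_float_array(self.time, "time")
        self.values = _as_float_array(self.values, "values")
        if self.time.size != self.values.size:
            raise ContentError(
                f"time ({self.time.size}) and values ({self.values.size}) differ in length"
            )
        if self.time.size < 2:
            raise ContentError("waveform needs at least 2 samples")
        if np.any(np.diff(self.time) <= 0):
            raise ContentError("time must be strictly increasing")
        if self.source not in WAVEFORM_SOURCES:
            raise ContentError(
                f"unknown source {self.source!r}; valid sources: {list(WAVEFORM_SOURCES)}"
            )
        if self.phase is not None:
            self.phase = np.asarray(self.phase, dtype=int)
            if self.phase.size != self.time.size:
                raise ContentError("phase labels must match the time axis")

    @property
    def duration(self) -> float:
        return float(self.time[-1] - self.time[0])

    @property
    def rate(self) -> float:
        """Mean sampling rate in Hz."""
        return (self.time.size - 1) / self.duration
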