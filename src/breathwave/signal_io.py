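"""Readers and writers for the formats the pipelines touch.

WAV audio is 16-bit PCM little-endian (consumer microphone capture); sensor
logs and waveforms are plain CSV with a mandatory header, '.' decimals and
'#' comment lines. Readers never reorder, resample or fill data; all
round-trips are lossless up to the declared quantization / printed precision.
Time is expressed in seconds from record start (t=0 at the first sample).
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .core import (
    AudioSignal,
    BreathWaveform,
    SensorTrace,
    ContentError,
    FormatError,
    SENSOR_CHANNELS,
    WAVEFORM_SOURCES,
)

__all__ = [
    "read_audio",
    "write_audio",
    "read_sensor_trace",
    "write_sensor_trace",
    "read_waveform",
    "write_waveform",
]

log = logging.getLogger(__name__)

_PCM16_SCALE = 32768.0  # 2**15


def read_audio(path) -> AudioSignal:
    """Read a WAV file as a mono :class:`AudioSignal` scaled to [-1, 1].

    Multichannel files are reduced to the first (left) channel with a
    warning. Integer PCM is scaled by the full-scale code; float WAV is
    taken as already normalized.
    """
    try:
        rate, data = wavfile.read(path)
    except Exception as exc:
        raise FormatError(f"cannot read WAV file {path}: {exc}") from exc
    if data.size == 0:
        raise ContentError(f"WAV file {path} contains no audio")
    if data.ndim == 2:
        log.warning("%s has %d channels; using channel 0", path, data.shape[1])
        data = data[:, 0]
    if np.issubdtype(data.dtype, np.integer):
        info = np.iinfo(data.dtype)
        scale = float(max(abs(info.min), info.max) + (1 if info.min == 0 else 0))
        if info.min == 0:  # unsigned 8-bit: offset binary
            samples = (data.astype(float) - (info.max + 1) / 2) / ((info.max + 1) / 2)
        else:
            samples = data.astype(float) / (abs(info.min))
    else:
        samples = data.astype(float)
    return AudioSignal(samples, int(rate))


def write_audio(signal: AudioSignal, path) -> None:
    """Write 16-bit PCM WAV; out-of-range amplitudes are clipped with a warning."""
    x = signal.samples
    if np.any(np.abs(x) > 1.0):
        warnings.warn(f"amplitude outside [-1, 1] clipped while writing {path}")
        x = np.clip(x, -1.0, 1.0)
    codes = np.round(x * _PCM16_SCALE)
    codes = np.clip(codes, -32768, 32767).astype(np.int16)
    wavfile.write(path, signal.sample_rate, codes)


def _read_csv(path):
    try:
        df = pd.read_csv(path, comment="#")
    except FileNotFoundError:
        raise
    except Exception as exc:
        raise FormatError(f"cannot parse CSV file {path}: {exc}") from exc
    if df.empty:
        raise ContentError(f"CSV file {path} contains no data rows")
    return df


def read_sensor_trace(path, sample_rate: float | None = None) -> SensorTrace:
    """Read a sensor-log CSV: a ``time`` column plus any subset of the
    channel vocabulary. Missing channels stay absent; unknown columns are an
    error naming the valid set.

    The log format carries no rate, so ``sample_rate`` defaults to the
    median time step of the file.
    """
    df = _read_csv(path)
    if "time" not in df.columns:
        raise FormatError(f"{path}: sensor log needs a 'time' column")
    unknown = [c for c in df.columns if c != "time" and c not in SENSOR_CHANNELS]
    if unknown:
        raise FormatError(
            f"{path}: unknown column(s) {unknown}; valid channels: {list(SENSOR_CHANNELS)}"
        )
    t = df["time"].to_numpy(float)
    if np.any(np.diff(t) <= 0):
        raise ContentError(f"{path}: time column is not strictly increasing")
    if sample_rate is None:
        sample_rate = 1.0 / float(np.median(np.diff(t)))
    channels = {c: df[c].to_numpy(float) for c in df.columns if c != "time"}
    return SensorTrace(t, channels, sample_rate)


def write_sensor_trace(trace: SensorTrace, path) -> None:
    """Write a sensor log as CSV (12 significant digits)."""
    cols = {"time": trace.time, **trace.channels}
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.12g")


def read_waveform(path) -> BreathWaveform:
    """Read a breathing waveform CSV (``time,value`` plus a ``# source:`` line)."""
    source = "ground_truth"
    try:
        with open(path) as fh:
            for line in fh:
                if not line.startswith("#"):
                    break
                if "source:" in line:
                    source = line.split("source:", 1)[1].strip()
    except OSError as exc:
        raise FormatError(f"cannot read {path}: {exc}") from exc
    if source not in WAVEFORM_SOURCES:
        raise ContentError(
            f"{path}: unknown source {source!r}; valid: {list(WAVEFORM_SOURCES)}"
        )
    df = _read_csv(path)
    for col in ("time", "value"):
        if col not in df.columns:
            raise FormatError(f"{path}: waveform CSV needs a {col!r} column")
    t = df["time"].to_numpy(float)
    if np.any(np.diff(t) <= 0):
        raise ContentError(f"{path}: time column is not strictly increasing")
    return BreathWaveform(t, df["value"].to_numpy(float), source=source)


def write_waveform(wave: BreathWaveform, path) -> None:
    """Write a breathing waveform CSV with its source tag in a comment header."""
    with open(path, "w") as fh:
        fh.write(f"# source: {wave.source}\n")
        fh.write("time,value\n")
        for t, v in zip(wave.time, wave.values):
            fh.write(f"{t:.12g},{v:.12g}\n")
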