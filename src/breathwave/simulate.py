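"""Seeded synthetic breath-sound, sensor-trace and belt generator.

Stands in for a human measurement study: 20-second records at five chest
positions (four front, one back), normal and deep breathing, three repeats
per condition. Every signal of a record — microphone audio, the multi-channel
thoracic trace, and the 20 Hz respiration-belt reference — is driven by one
shared ground-truth respiratory displacement, so extraction pipelines can be
scored against a known phase.

Breath sounds are synthesized as band-limited Gaussian turbulence (not
tones): per phase, noise bandpassed around the sound type's inhale or exhale
center frequency, gated by a smooth envelope, with additive white noise at a
configurable SNR. Bronchial/bronchoalveolar presets center at 600 Hz
(inhale) / 400 Hz (exhale); the alveolar preset at 400 / 200 Hz with a quiet
exhale.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d

from .core import AudioSignal, BreathWaveform, SensorTrace, ParameterError
from .filters import bandpass, lowpass
from . import signal_io

__all__ = [
    "BreathPattern",
    "SoundType",
    "NoiseSpec",
    "BRONCHIAL",
    "BRONCHOALVEOLAR",
    "ALVEOLAR",
    "POSITION_AMPLITUDE",
    "phase_signal",
    "synth_breath_sound",
    "synth_sensor_trace",
    "synth_belt",
    "method_ground_truth",
    "study_noise",
    "make_study",
    "iter_study_records",
]

# phase label codes on ground-truth waveforms
PAUSE, INHALE, EXHALE = 0, 1, 2


@dataclass
class BreathPattern:
    """Breathing-cycle parameterization.

    ``ie_ratio`` is the inhale:exhale duration ratio (≈1:2 at rest);
    ``pause_fraction`` is the fraction of each cycle spent silent, split
    equally between the post-inhale and post-exhale pauses. Deep breathing
    is slower and larger: rate 10/min and depth 2.0 vs 15/min and 1.0.
    """

    breathing_rate: float = 15.0  # breaths/min
    ie_ratio: tuple = (1.0, 2.0)
    pause_fraction: float = 0.10
    mode: str = "normal"
    depth_scale: float = 1.0

    def __post_init__(self):
        if self.breathing_rate <= 0:
            raise ParameterError("breathing_rate must be positive")
        if min(self.ie_ratio) <= 0:
            raise ParameterError("ie_ratio components must be positive")
        if not 0 <= self.pause_fraction < 0.5:
            raise ParameterError("pause_fraction must lie in [0, 0.5)")
        if self.mode not in ("normal", "deep"):
            raise ParameterError(f"mode must be 'normal' or 'deep', got {self.mode!r}")
        if self.depth_scale <= 0:
            raise ParameterError("depth_scale must be positive")

    @classmethod
    def normal(cls, **kw) -> "BreathPattern":
        return cls(mode="normal", **kw)

    @classmethod
    def deep(cls, **kw) -> "BreathPattern":
        kw.setdefault("breathing_rate", 10.0)
        kw.setdefault("depth_scale", 2.0)
        return cls(mode="deep", **kw)


@dataclass
class SoundType:
    """Spectral signature of one breath-sound class."""

    name: str
    inhale_center: float  # Hz
    exhale_center: float  # Hz
    bandwidth: float = 200.0
    inhale_gain: float = 1.0
    exhale_gain: float = 1.0

    def __post_init__(self):
        if min(self.inhale_center, self.exhale_center, self.bandwidth) <= 0:
            raise ParameterError("centers and bandwidth must be positive")
        if min(self.inhale_gain, self.exhale_gain) < 0:
            raise ParameterError("gains must be >= 0")


#: Bronchial sounds: loud, louder on exhale, 600/400 Hz centers.
BRONCHIAL = SoundType("bronchial", 600.0, 400.0, inhale_gain=1.0, exhale_gain=1.2)
#: Bronchoalveolar: comparable loudness both phases, same centers.
BRONCHOALVEOLAR = SoundType("bronchoalveolar", 600.0, 400.0)
#: Alveolar: 400/200 Hz, exhale quiet and hard to hear.
ALVEOLAR = SoundType("alveolar", 400.0, 200.0, inhale_gain=1.0, exhale_gain=0.4)

_SOUND_PRESETS = {s.name: s for s in (BRONCHIAL, BRONCHOALVEOLAR, ALVEOLAR)}


@dataclass
class NoiseSpec:
    """Noise model for the generators.

    ``channel_sd`` is white noise per sensor channel (channel units);
    ``channel_drift_sd`` drives a random-walk baseline wander (units per
    √s) emulating slow artifacts — clothing rustle, contact creep — that
    survive lowpass filtering. ``rustle_rate`` adds short broadband audio
    bursts (events/min).
    """

    audio_snr_db: float = 10.0
    channel_sd: dict = field(default_factory=lambda: {
        "pressure": 0.02, "accel": 0.005, "mag": 0.2, "gyro": 0.2,
    })
    channel_drift_sd: dict = field(default_factory=lambda: {
        "pressure": 0.02, "accel": 0.0005, "mag": 0.05, "gyro": 0.01,
    })
    rustle_rate: float = 0.0

    @classmethod
    def silent(cls) -> "NoiseSpec":
        return cls(audio_snr_db=np.inf,
                   channel_sd={}, channel_drift_sd={}, rustle_rate=0.0)

    def sd(self, channel: str) -> float:
        return float(self.channel_sd.get(channel.split("_")[0], 0.0))

    def drift_sd(self, channel: str) -> float:
        return float(self.channel_drift_sd.get(channel.split("_")[0], 0.0))


def phase_signal(pattern: BreathPattern, duration: float, rate: float) -> BreathWaveform:
    """Ground-truth respiratory displacement with per-sample phase labels.

    Each cycle is inhale → pause → exhale → pause; the breathing time
    (1 − pause_fraction of the cycle) is split inhale:exhale by ``ie_ratio``.
    Displacement rises 0 → depth_scale along a raised cosine during inhale,
    holds through the pause, and falls back during exhale — continuous with
    continuous first derivative.
    """
    if duration <= 0 or rate <= 0:
        raise ParameterError("duration and rate must be positive")
    n = int(round(duration * rate))
    t = np.arange(n) / rate
    period = 60.0 / pattern.breathing_rate
    tau = (t % period) / period  # cycle fraction in [0, 1)

    i, e = pattern.ie_ratio
    breathing = 1.0 - pattern.pause_fraction
    f_in = breathing * i / (i + e)
    f_ex = breathing * e / (i + e)
    f_pause = pattern.pause_fraction / 2.0
    b1 = f_in                  # end of inhale
    b2 = f_in + f_pause        # end of post-inhale pause
    b3 = b2 + f_ex             # end of exhale

    d = np.zeros(n)
    phase = np.full(n, PAUSE, dtype=int)

    m = tau < b1
    d[m] = 0.5 * (1 - np.cos(np.pi * tau[m] / f_in))
    phase[m] = INHALE
    m = (tau >= b1) & (tau < b2)
    d[m] = 1.0
    m = (tau >= b2) & (tau < b3)
    d[m] = 0.5 * (1 + np.cos(np.pi * (tau[m] - b2) / f_ex))
    phase[m] = EXHALE
    # tau >= b3: post-exhale pause, d = 0

    return BreathWaveform(t, d * pattern.depth_scale, source="ground_truth",
                          phase=phase)


def _phase_envelope(phase: np.ndarray, code: int, sample_rate: float,
                    ramp: float = 0.05) -> np.ndarray:
    """Smooth 0/1 gate for one phase with ~``ramp``-second onset/offset."""
    gate = (phase == code).astype(float)
    width = max(1, int(round(ramp * sample_rate)))
    return uniform_filter1d(gate, size=width, mode="nearest")


def synth_breath_sound(pattern: BreathPattern, sound_type: SoundType | str,
                       noise: NoiseSpec | None = None,
                       duration: float = 20.0, sample_rate: int = 44100,
                       seed: int = 0,
                       truth_rate: float = 50.0) -> tuple[AudioSignal, BreathWaveform]:
    """Synthesize a breath-sound recording plus its ground-truth waveform.

    Per phase, Gaussian noise bandpassed to ``center ± bandwidth/2`` is gated
    by a smooth envelope and scaled by the phase gain; broadband white noise
    is added at ``audio_snr_db``. Deterministic for a fixed seed.
    """
    if isinstance(sound_type, str):
        sound_type = _SOUND_PRESETS[sound_type]
    noise = noise or NoiseSpec()
    nyq = sample_rate / 2.0
    for center in (sound_type.inhale_center, sound_type.exhale_center):
        if center + sound_type.bandwidth / 2.0 >= nyq:
            raise ParameterError(
                f"band around {center} Hz exceeds Nyquist ({nyq} Hz)"
            )
    rng = np.random.default_rng(seed)
    lab = phase_signal(pattern, duration, float(sample_rate))
    n = lab.time.size

    audio = np.zeros(n)
    for code, center, gain in ((INHALE, sound_type.inhale_center, sound_type.inhale_gain),
                               (EXHALE, sound_type.exhale_center, sound_type.exhale_gain)):
        lo = max(1.0, center - sound_type.bandwidth / 2.0)
        hi = center + sound_type.bandwidth / 2.0
        burst = bandpass(rng.standard_normal(n), sample_rate, lo, hi)
        audio += gain * _phase_envelope(lab.phase, code, sample_rate) * burst

    active = lab.phase != PAUSE
    sig_power = float(np.mean(audio[active] ** 2)) if active.any() else 0.0
    if np.isfinite(noise.audio_snr_db) and sig_power > 0:
        noise_power = sig_power / 10.0 ** (noise.audio_snr_db / 10.0)
        audio += rng.standard_normal(n) * np.sqrt(noise_power)
    if noise.rustle_rate > 0:
        n_events = rng.poisson(noise.rustle_rate * duration / 60.0)
        for _ in range(n_events):
            start = int(rng.integers(0, n))
            length = int(rng.uniform(0.05, 0.3) * sample_rate)
            stop = min(n, start + length)
            if stop - start > 30:  # need enough samples to filter
                seg = lowpass(rng.standard_normal(stop - start), sample_rate, 300.0)
                audio[start:stop] += 3.0 * np.sqrt(max(sig_power, 1e-12)) * seg

    peak = np.max(np.abs(audio))
    if peak > 0:
        audio = 0.9 * audio / peak
    truth = phase_signal(pattern, duration, truth_rate)
    return AudioSignal(audio, sample_rate), truth


#: Relative thoracic-motion amplitude at the five auscultation positions;
#: positions 2 and 4 (near the upper thorax and the abdomen) move most.
POSITION_AMPLITUDE = (0.8, 1.2, 0.8, 1.2, 0.9)

# channel coupling gains (simulator conventions, self-consistent arbitrary units)
_PRESSURE_GAIN = 2.0       # sensor units per unit displacement
_PRESSURE_BASE = 10.0
_MAG_BASE = np.array([30.0, -10.0, 40.0])   # µT ambient field
_MAG_GAIN = np.array([1.0, 0.5, 5.0])       # µT per unit displacement
_ACCEL_SCALE = 0.02        # g per (unit displacement / s^2)
_TILT_DEG = 2.0            # degrees of chest-piece tilt per unit displacement
_GRAVITY = 1.0             # g


def synth_sensor_trace(pattern: BreathPattern, noise: NoiseSpec | None = None,
                       duration: float = 20.0, rate: float = 100.0,
                       position: int = 1,
                       seed: int = 0) -> tuple[SensorTrace, BreathWaveform]:
    """Synthesize a thoracic-variation sensor trace plus its ground truth.

    The shared displacement d(t) (scaled by the per-position amplitude
    profile) drives every channel: pressure ∝ d; the chest-normal
    accelerometer axis carries gravity plus d̈; the magnetometer sees the
    ambient field plus a gain·d deflection; the device tilt is ∝ d with the
    gyro reporting its derivative. Per-channel white noise and random-walk
    drift follow the :class:`NoiseSpec`.
    """
    if not 1 <= position <= 5:
        raise ParameterError(f"position must be 1..5, got {position}")
    noise = noise or NoiseSpec()
    rng = np.random.default_rng(seed)

    truth = phase_signal(pattern, duration, rate)
    amp = POSITION_AMPLITUDE[position - 1]
    d = truth.values * amp
    dt = 1.0 / rate
    d_dot = np.gradient(d, dt)
    d_ddot = np.gradient(d_dot, dt)

    theta = np.deg2rad(_TILT_DEG * d)
    channels = {
        "pressure": _PRESSURE_BASE + _PRESSURE_GAIN * d,
        "accel_x": _GRAVITY * np.sin(theta),
        "accel_y": np.zeros_like(d),
        "accel_z": _GRAVITY * np.cos(theta) + _ACCEL_SCALE * d_ddot,
        "mag_x": _MAG_BASE[0] + _MAG_GAIN[0] * d,
        "mag_y": _MAG_BASE[1] + _MAG_GAIN[1] * d,
        "mag_z": _MAG_BASE[2] + _MAG_GAIN[2] * d,
        "gyro_x": np.zeros_like(d),
        "gyro_y": _TILT_DEG * d_dot,  # deg/s
        "gyro_z": np.zeros_like(d),
    }
    n = d.size
    for name in channels:
        sd = noise.sd(name)
        if sd > 0:
            channels[name] = channels[name] + rng.normal(0.0, sd, n)
        dsd = noise.drift_sd(name)
        if dsd > 0:
            walk = np.cumsum(rng.normal(0.0, dsd * np.sqrt(dt), n))
            channels[name] = channels[name] + walk

    return SensorTrace(truth.time.copy(), channels, rate), truth


def method_ground_truth(truth: BreathWaveform, method: str,
                        cutoff: float | None = None) -> BreathWaveform:
    """Ground-truth proxy for one extraction method.

    The pressure, magnetic and angle routes track displacement directly; the
    accelerometer route physically measures its second time-derivative, so
    its proxy is d̈. Passing ``cutoff`` band-limits the proxy with the same
    zero-phase lowpass the extractors use — out-of-band truth content is
    unrecoverable by construction and should not count against a method.
    """
    if method == "accel":
        dt = float(np.mean(np.diff(truth.time)))
        v = np.gradient(np.gradient(truth.values, dt), dt)
    else:
        v = truth.values.copy()
    if cutoff is not None:
        v = lowpass(v, truth.rate, cutoff)
    return BreathWaveform(truth.time.copy(), v - v.mean(), source="ground_truth")


def synth_belt(truth: BreathWaveform, noise_sd: float = 0.0,
               rate: float = 20.0, seed: int = 0) -> BreathWaveform:
    """Respiration-belt reference: truth resampled to 20 Hz plus small noise."""
    if truth.duration < 1.0:
        raise ParameterError("need at least 1 s of ground truth")
    n = int(np.floor((truth.time[-1] - truth.time[0]) * rate)) + 1
    t = truth.time[0] + np.arange(n) / rate
    v = np.interp(t, truth.time, truth.values)
    if noise_sd > 0:
        v = v + np.random.default_rng(seed).normal(0.0, noise_sd, n)
    return BreathWaveform(t, v, source="belt")


def study_noise(mode: str) -> NoiseSpec:
    """Mode-dependent noise profile for the synthetic study.

    In gentle (normal) breathing the chest piece keeps firm contact and the
    pressure channel is clean, while the small magnet deflection leaves the
    magnetometer dominated by drift. In deep breathing the large excursion
    makes the magnet deflection dominant, but the contact force repeatedly
    slips and creeps, putting heavy wander on the pressure channel.
    """
    base = NoiseSpec()
    if mode == "normal":
        drift = {"pressure": 0.05, "accel": 0.0005, "mag": 2.5, "gyro": 0.01}
    elif mode == "deep":
        drift = {"pressure": 3.0, "accel": 0.0005, "mag": 0.3, "gyro": 0.01}
    else:
        raise ParameterError(f"mode must be 'normal' or 'deep', got {mode!r}")
    return replace(base, channel_drift_sd=drift)


def _subject_params(rng) -> dict:
    """Per-subject physiology draws."""
    return {
        "rate_normal": float(rng.normal(15.0, 2.0)),
        "rate_deep": float(rng.normal(10.0, 1.5)),
        "depth_normal": float(rng.uniform(0.8, 1.2)),
        "depth_deep": float(rng.uniform(1.7, 2.3)),
        "snr_db": float(rng.uniform(8.0, 14.0)),
    }


def iter_study_records(n_subjects: int, seed: int = 0, duration: float = 20.0,
                       include_audio: bool = True, n_repeats: int = 3,
                       sensor_rate: float = 100.0):
    """Yield every record of a synthetic study, in manifest order.

    Design mirrors the emulated protocol: per subject, 5 positions × 2
    breathing modes × ``n_repeats`` 20-second records. Yields dicts with the
    condition keys plus the in-memory signals (audio is None when
    ``include_audio`` is False). Fully deterministic for a fixed seed.
    """
    if n_subjects < 1:
        raise ParameterError("need at least one subject")
    master = np.random.default_rng(seed)
    for subject in range(1, n_subjects + 1):
        sp = _subject_params(master)
        for position in range(1, 6):
            for mode in ("normal", "deep"):
                if mode == "normal":
                    pattern = BreathPattern.normal(
                        breathing_rate=max(sp["rate_normal"], 6.0),
                        depth_scale=sp["depth_normal"])
                    sound = BRONCHIAL if position in (1, 2, 5) else ALVEOLAR
                else:
                    pattern = BreathPattern.deep(
                        breathing_rate=max(sp["rate_deep"], 5.0),
                        depth_scale=sp["depth_deep"])
                    sound = BRONCHIAL if position in (1, 2, 5) else ALVEOLAR
                noise = replace(study_noise(mode), audio_snr_db=sp["snr_db"])
                for repeat in range(1, n_repeats + 1):
                    rec_seed = int(master.integers(0, 2**31 - 1))
                    trace, truth = synth_sensor_trace(
                        pattern, noise, duration, sensor_rate,
                        position, seed=rec_seed)
                    belt = synth_belt(truth, noise_sd=0.01 * pattern.depth_scale,
                                      seed=rec_seed + 1)
                    audio = None
                    if include_audio:
                        audio, _ = synth_breath_sound(
                            pattern, sound, noise, duration, seed=rec_seed + 2)
                    yield {
                        "subject": subject,
                        "position": position,
                        "mode": mode,
                        "repeat": repeat,
                        "sound_type": sound.name,
                        "seed": rec_seed,
                        "pattern": pattern,
                        "audio": audio,
                        "trace": trace,
                        "belt": belt,
                        "truth": truth,
                    }


def make_study(n_subjects: int, seed: int = 0, out_dir=None,
               duration: float = 20.0, include_audio: bool = True,
               n_repeats: int = 3) -> pd.DataFrame:
    """Generate a full synthetic study and (optionally) write it to disk.

    Writes, per record, the audio WAV, sensor-trace CSV, belt CSV and
    ground-truth CSV, plus a ``manifest.csv`` indexing them. Returns the
    manifest as a DataFrame (with a content hash per record so reproducibility
    is checkable). n_subjects=14 with defaults emulates the full protocol:
    14 × 5 positions × 2 modes × 3 repeats = 420 records.
    """
    rows = []
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    for rec in iter_study_records(n_subjects, seed, duration,
                                  include_audio, n_repeats):
        stem = (f"s{rec['subject']:02d}_p{rec['position']}"
                f"_{rec['mode']}_r{rec['repeat']}")
        row = {k: rec[k] for k in
               ("subject", "position", "mode", "repeat", "sound_type", "seed")}
        row["breathing_rate"] = rec["pattern"].breathing_rate
        row["depth_scale"] = rec["pattern"].depth_scale
        h = hashlib.sha256()
        for key in ("trace", "belt", "truth"):
            obj = rec[key]
            data = obj.time.tobytes() + (
                b"".join(v.tobytes() for v in obj.channels.values())
                if key == "trace" else obj.values.tobytes())
            h.update(data)
        if rec["audio"] is not None:
            h.update(rec["audio"].samples.tobytes())
        row["sha256"] = h.hexdigest()[:16]
        if out is not None:
            signal_io.write_sensor_trace(rec["trace"], out / f"{stem}_trace.csv")
            signal_io.write_waveform(rec["belt"], out / f"{stem}_belt.csv")
            signal_io.write_waveform(rec["truth"], out / f"{stem}_truth.csv")
            row["trace_file"] = f"{stem}_trace.csv"
            row["belt_file"] = f"{stem}_belt.csv"
            row["truth_file"] = f"{stem}_truth.csv"
            if rec["audio"] is not None:
                signal_io.write_audio(rec["audio"], out / f"{stem}_audio.wav")
                row["audio_file"] = f"{stem}_audio.wav"
        rows.append(row)
    manifest = pd.DataFrame(rows)
    if out is not None:
        manifest.to_csv(out / "manifest.csv", index=False)
    return manifest
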