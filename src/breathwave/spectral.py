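"""Breathing-waveform extraction from breath sounds via spectral integration.

Breath sounds carry more high-band energy during inhalation than exhalation
(bronchial/bronchoalveolar sounds center near 600 Hz on inhale vs 400 Hz on
exhale; alveolar sounds near 400 vs 200 Hz). The pipeline exploits this:

1. denoise the audio with a short moving average,
2. short-time Fourier transform with a Hann window (4096 points, 50 ms hop),
3. per frame, take the ratio of spectral integration (SI, summed spectral
   power) in a high "inhale" band (default 500–800 Hz) to SI over the full
   breath-sound band (default 100–1000 Hz),
4. smooth the frame series with a moving average.

The resulting frame-rate series rises during inhalation and falls during
exhalation — a respiratory phase proxy that can be scored against a
respiration-belt reference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import AudioSignal, BreathWaveform, ContentError, ParameterError
from .config import StftConfig, BandRatioConfig
from .filters import moving_average, bandpass

__all__ = [
    "SpectralFrame",
    "stft",
    "spectral_integration",
    "normalized_spectral_integration",
    "band_ratio_waveform",
]


@dataclass
class SpectralFrame:
    """One STFT frame: magnitude spectrum and its placement in time.

    ``magnitudes`` has window_length//2 + 1 non-negative entries; bin *k*
    is centered at ``k * bin_width`` Hz. ``frame_time`` is the window center.
    """

    frame_time: float
    magnitudes: np.ndarray
    bin_width: float

    def __post_init__(self):
        self.magnitudes = np.asarray(self.magnitudes, dtype=float)
        if self.magnitudes.ndim != 1 or np.any(self.magnitudes < 0):
            raise ContentError("magnitudes must be a 1-d non-negative array")
        if self.bin_width <= 0:
            raise ParameterError("bin_width must be positive")

    @property
    def frequencies(self) -> np.ndarray:
        return np.arange(self.magnitudes.size) * self.bin_width


def stft(signal: AudioSignal, cfg: StftConfig | None = None) -> list[SpectralFrame]:
    """Short-time Fourier transform with a Hann window.

    Frames start every ``hop = round(frameshift * sample_rate)`` samples; no
    zero padding is applied and a final partial window is dropped, so the
    number of frames is ``(len − window) // hop + 1``. Each frame's time is
    the center of its window.
    """
    cfg = cfg or StftConfig()
    win = cfg.window_length
    x = signal.samples
    if x.size < win:
        raise ContentError(
            f"signal has {x.size} samples, shorter than one {win}-point window"
        )
    hop = cfg.hop(signal.sample_rate)
    n_frames = (x.size - win) // hop + 1
    window = np.hanning(win)
    starts = np.arange(n_frames) * hop
    segments = np.lib.stride_tricks.sliding_window_view(x, win)[starts]
    mags = np.abs(np.fft.rfft(segments * window, axis=1))
    bin_width = signal.sample_rate / win
    times = (starts + win / 2) / signal.sample_rate
    return [SpectralFrame(float(t), m, bin_width) for t, m in zip(times, mags)]


def _band_mask(frame: SpectralFrame, band) -> np.ndarray:
    low, high = float(band[0]), float(band[1])
    if not low < high:
        raise ParameterError(f"band must satisfy low < high, got ({low}, {high})")
    f = frame.frequencies
    # half-open on bin centers so abutting bands never double-count
    return (f >= low) & (f < high)


def spectral_integration(frame: SpectralFrame, band, use_power: bool = True) -> float:
    """Spectral integration (SI): summed spectral power over a band.

    Sums squared magnitudes over the bins whose center frequency lies in
    ``[low, high)``; an empty band integrates to 0. With ``use_power=False``
    plain magnitudes are summed instead.
    """
    mask = _band_mask(frame, band)
    m = frame.magnitudes[mask]
    return float(np.sum(m * m) if use_power else np.sum(m))


def normalized_spectral_integration(frame: SpectralFrame, bands,
                                    use_power: bool = True) -> np.ndarray:
    """Normalized SI (NSI): per-band SI scaled so the set sums to 1."""
    bands = list(bands)
    if not bands:
        raise ParameterError("need at least one band")
    si = np.array([spectral_integration(frame, b, use_power) for b in bands])
    total = si.sum()
    if total == 0:
        raise ContentError("total spectral integration is zero: NSI undefined")
    return si / total


def band_ratio_waveform(signal: AudioSignal,
                        stft_cfg: StftConfig | None = None,
                        ratio_cfg: BandRatioConfig | None = None) -> BreathWaveform:
    """Extract a breathing waveform from breath-sound audio.

    Pipeline: moving-average denoise on the raw audio → STFT → per-frame
    SI(numerator band) / SI(denominator band), zero where the denominator
    vanishes → moving-average smoothing at the frame rate. Because the
    numerator band lies inside the denominator band, every value is in
    [0, 1], and scaling the audio amplitude leaves the waveform unchanged.
    """
    stft_cfg = stft_cfg or StftConfig()
    ratio_cfg = ratio_cfg or BandRatioConfig()

    x = moving_average(signal.samples, ratio_cfg.denoise_samples)
    if ratio_cfg.prefilter_band is not None:
        lo, hi = ratio_cfg.prefilter_band
        x = bandpass(x, signal.sample_rate, lo, hi)
    frames = stft(AudioSignal(x, signal.sample_rate), stft_cfg)

    ratios = np.empty(len(frames))
    for i, fr in enumerate(frames):
        den = spectral_integration(fr, ratio_cfg.denominator_band, ratio_cfg.use_power)
        if den == 0.0:
            ratios[i] = 0.0
        else:
            num = spectral_integration(fr, ratio_cfg.numerator_band, ratio_cfg.use_power)
            ratios[i] = num / den
    smoothed = moving_average(ratios, ratio_cfg.smoothing_frames)
    times = np.array([fr.frame_time for fr in frames])
    return BreathWaveform(times, smoothed, source="microphone")
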