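"""Run configuration for the extraction and evaluation pipelines.

Defaults follow the published operating point of the breath-sound method:
4096-point Hann window, 50 ms frameshift, a 500–800 Hz numerator band inside
the 100–1000 Hz breath-sound band, size-10 moving-average denoising and
smoothing, a 1 Hz zero-phase lowpass for the thoracic channels, a 20 Hz belt
reference rate, and a ±5 s lag search for the cross-correlation score.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import yaml

from .core import ParameterError

__all__ = ["StftConfig", "BandRatioConfig", "RunConfig", "load_config"]


@dataclass
class StftConfig:
    """Short-time Fourier transform parameters.

    window_length : samples per frame (Hann window, no zero padding)
    frameshift    : hop between frame starts, seconds
    """

    window_length: int = 4096
    frameshift: float = 0.050
    window_function: str = "hanning"

    def __post_init__(self):
        if self.window_length < 2:
            raise ParameterError(f"window_length must be >= 2, got {self.window_length}")
        if self.frameshift <= 0:
            raise ParameterError(f"frameshift must be positive, got {self.frameshift}")
        if self.window_function != "hanning":
            raise ParameterError(f"unsupported window {self.window_function!r}")

    def hop(self, sample_rate: float) -> int:
        """Hop size in samples for a given audio rate."""
        h = int(round(self.frameshift * sample_rate))
        if h < 1:
            raise ParameterError("frameshift shorter than one sample period")
        return h


def _check_band(band, name):
    low, high = float(band[0]), float(band[1])
    if not low < high:
        raise ParameterError(f"{name} must satisfy low < high, got ({low}, {high})")
    if low < 0:
        raise ParameterError(f"{name} lower edge must be >= 0, got {low}")
    return (low, high)


@dataclass
class BandRatioConfig:
    """Band-ratio waveform parameters.

    The waveform value per frame is SI(numerator) / SI(denominator), where SI
    is summed spectral power over a band. The numerator must lie inside the
    denominator so the ratio stays in [0, 1].
    """

    numerator_band: tuple = (500.0, 800.0)
    denominator_band: tuple = (100.0, 1000.0)
    denoise_samples: int = 10
    smoothing_frames: int = 10
    #: sum |X|^2 (power) if True, |X| if False — a sensitivity switch
    use_power: bool = True
    #: optional zero-phase bandpass applied before the STFT, e.g. (150, 1000)
    #: to suppress heart sounds; off by default
    prefilter_band: tuple | None = None

    def __post_init__(self):
        self.numerator_band = _check_band(self.numerator_band, "numerator_band")
        self.denominator_band = _check_band(self.denominator_band, "denominator_band")
        if not (self.denominator_band[0] <= self.numerator_band[0]
                and self.numerator_band[1] <= self.denominator_band[1]):
            raise ParameterError(
                f"numerator band {self.numerator_band} must lie inside "
                f"denominator band {self.denominator_band}"
            )
        if self.denoise_samples < 1 or self.smoothing_frames < 1:
            raise ParameterError("filter lengths must be >= 1")
        if self.prefilter_band is not None:
            self.prefilter_band = _check_band(self.prefilter_band, "prefilter_band")


@dataclass
class RunConfig:
    """Top-level configuration bundling every tunable of the pipelines."""

    stft: StftConfig = field(default_factory=StftConfig)
    ratio: BandRatioConfig = field(default_factory=BandRatioConfig)
    #: zero-phase Butterworth cutoff for thoracic channels, Hz
    lowpass_cutoff: float = 1.0
    #: Kalman tilt-filter noise parameters (per-step, dt-scaled)
    kalman_q_angle: float = 0.001
    kalman_q_bias: float = 0.003
    kalman_r_measure: float = 0.03
    #: lag search half-window for the correlation score, seconds
    lag_window: float = 5.0
    #: common evaluation grid rate (the belt's native rate), Hz
    grid_rate: float = 20.0

    def __post_init__(self):
        if isinstance(self.stft, dict):
            self.stft = StftConfig(**self.stft)
        if isinstance(self.ratio, dict):
            self.ratio = BandRatioConfig(**self.ratio)
        if self.lowpass_cutoff <= 0:
            raise ParameterError("lowpass_cutoff must be positive")
        for name in ("kalman_q_angle", "kalman_q_bias", "kalman_r_measure"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")
        if self.lag_window < 0:
            raise ParameterError("lag_window must be >= 0")
        if self.grid_rate <= 0:
            raise ParameterError("grid_rate must be positive")

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path) -> RunConfig:
    """Load a :class:`RunConfig` from a YAML file; missing keys keep defaults."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ParameterError(f"config file {path} must contain a mapping")
    return RunConfig(**data)
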