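"""Score extracted breathing waveforms against a reference.

The evaluation index is the normalized cross-correlation: both series are
z-normalized (population standard deviation), then

    R(Δt) = 1/(N − Δt) · Σ_{t=1..N−Δt} x_t · y_{t+Δt}

is scanned over integer lags within a symmetric window (±5 s by default,
covering phase offsets between chest-wall motion and the abdominal belt).
The reported coefficient is R at the lag of maximal |R|, signed; the lag-0
value is also carried. Coefficients above 0.4 are conventionally considered
correlated, and 0.7 is the strong-correlation bar the extraction methods
aim for.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import BreathWaveform, ContentError, ParameterError

__all__ = [
    "CorrelationResult",
    "ConditionSummary",
    "resample_to_common",
    "normalized_xcorr",
    "score_waveform",
    "summarize",
    "apply_selection",
]

#: coefficient magnitude above which waveforms are considered correlated
CORRELATED_THRESHOLD = 0.4
#: coefficient magnitude considered a strong correlation (the target bar)
STRONG_THRESHOLD = 0.7


@dataclass
class CorrelationResult:
    """Outcome of one normalized cross-correlation scan."""

    coefficient: float       # R at the lag of max |R|, signed
    best_lag: float          # seconds; positive = y lags x
    lag_window: float        # half-width of the scanned window, seconds
    n_overlap: int           # series length entering the scan
    coefficient_lag0: float  # R(0), for lag-free comparisons

    def __post_init__(self):
        if abs(self.coefficient) > 1 + 1e-9:
            raise ContentError(f"|coefficient| > 1: {self.coefficient}")
        if abs(self.best_lag) > self.lag_window + 1e-12:
            raise ContentError("best_lag outside the scanned window")

    @property
    def correlated(self) -> bool:
        return abs(self.coefficient) > CORRELATED_THRESHOLD

    @property
    def strong(self) -> bool:
        return abs(self.coefficient) >= STRONG_THRESHOLD


@dataclass
class ConditionSummary:
    """Mean ± SD of coefficients within one condition group."""

    condition: dict
    mean: float
    sd: float
    n: int

    @property
    def correlated(self) -> bool:
        return abs(self.mean) > CORRELATED_THRESHOLD

    @property
    def strong(self) -> bool:
        return abs(self.mean) >= STRONG_THRESHOLD


def resample_to_common(x: BreathWaveform, y: BreathWaveform, rate: float = 20.0,
                       min_overlap: float = 5.0) -> tuple[np.ndarray, np.ndarray]:
    """Linearly interpolate both waveforms onto a shared uniform grid.

    The grid spans the overlap of the two time supports at ``rate`` Hz; an
    overlap shorter than ``min_overlap`` seconds is an error.
    """
    t0 = max(x.time[0], y.time[0])
    t1 = min(x.time[-1], y.time[-1])
    if t1 - t0 < min_overlap:
        raise ContentError(
            f"time supports overlap for {max(t1 - t0, 0):.3f} s, "
            f"need >= {min_overlap} s"
        )
    n = int(np.floor((t1 - t0) * rate)) + 1
    grid = t0 + np.arange(n) / rate
    return (np.interp(grid, x.time, x.values),
            np.interp(grid, y.time, y.values))


def _znorm(v: np.ndarray) -> np.ndarray:
    sd = v.std()  # population SD, so R(0) of identical series is exactly 1
    if sd == 0:
        raise ContentError("series has zero variance: correlation undefined")
    return (v - v.mean()) / sd


def normalized_xcorr(x, y, lag_window: float = 5.0,
                     rate: float = 20.0) -> CorrelationResult:
    """Normalized cross-correlation of two equal-length series over ±lag_window.

    Both series are z-normalized first. For a non-negative integer lag k,
    R(k) = mean(x[:N−k] · y[k:]); negative lags swap the roles, so
    R_xy(−k) = R_yx(k). Returns R at the lag maximizing |R| (ties broken
    toward the smallest |lag|), plus R(0).
    """
    x = _znorm(np.asarray(x, dtype=float))
    y = _znorm(np.asarray(y, dtype=float))
    if x.shape != y.shape or x.ndim != 1:
        raise ParameterError("x and y must be equal-length 1-d series")
    if lag_window < 0:
        raise ParameterError("lag_window must be >= 0")
    n = x.size
    max_lag = min(int(np.floor(lag_window * rate)), n - 2)
    lags = np.arange(-max_lag, max_lag + 1)
    r = np.empty(lags.size)
    for i, k in enumerate(lags):
        if k >= 0:
            r[i] = np.mean(x[: n - k] * y[k:])
        else:
            r[i] = np.mean(y[: n + k] * x[-k:])
    # max |R|; among ties prefer the smallest |lag|. The 1/(N-k) estimator
    # normalizes with full-series moments, so |R| can exceed 1 by a sliver
    # at nonzero lags; clamp to the correlation range.
    order = np.lexsort((np.abs(lags), -np.abs(r)))
    best = order[0]
    return CorrelationResult(
        coefficient=float(np.clip(r[best], -1.0, 1.0)),
        best_lag=float(lags[best] / rate),
        lag_window=float(lag_window),
        n_overlap=n,
        coefficient_lag0=float(r[max_lag]),
    )


def score_waveform(wave: BreathWaveform, reference: BreathWaveform,
                   lag_window: float = 5.0, rate: float = 20.0,
                   min_overlap: float = 5.0) -> CorrelationResult:
    """Resample a waveform and its reference to a common grid and correlate."""
    xv, yv = resample_to_common(wave, reference, rate, min_overlap)
    return normalized_xcorr(xv, yv, lag_window, rate)


def summarize(results, by=("mode", "method")) -> list[ConditionSummary]:
    """Group per-record coefficients by condition and report mean ± SD.

    ``results`` is a DataFrame (or list of dicts) with a ``coefficient``
    column plus the condition columns named in ``by``. SD is the population
    standard deviation.
    """
    df = pd.DataFrame(results)
    if df.empty:
        raise ParameterError("no results to summarize")
    by = [c for c in by if c in df.columns]
    if not by:
        g = df["coefficient"]
        return [ConditionSummary({}, float(g.mean()), float(g.std(ddof=0)), len(g))]
    out = []
    for keys, grp in df.groupby(list(by), sort=True):
        if not isinstance(keys, tuple):
            keys = (keys,)
        cond = dict(zip(by, keys))
        c = grp["coefficient"]
        out.append(ConditionSummary(cond, float(c.mean()),
                                    float(c.std(ddof=0)), len(c)))
    return out


def apply_selection(results, rule: dict,
                    condition_key: str = "mode") -> ConditionSummary:
    """Keep, per record, only the method a selection rule assigns its condition.

    ``rule`` maps a condition value (e.g. breathing mode) to a method name —
    for instance ``{"normal": "pressure", "deep": "magnetic"}``. Each record
    (identified by everything except ``method``) must carry a coefficient for
    its selected method. Returns the overall mean ± SD of the selected
    coefficients.
    """
    df = pd.DataFrame(results)
    for col in (condition_key, "method", "coefficient"):
        if col not in df.columns:
            raise ParameterError(f"results need a {col!r} column")
    missing_conditions = set(df[condition_key]) - set(rule)
    if missing_conditions:
        raise ParameterError(
            f"selection rule has no entry for condition(s) {sorted(missing_conditions)}"
        )
    selected = df[df.apply(lambda r: r["method"] == rule[r[condition_key]], axis=1)]
    id_cols = [c for c in df.columns if c not in ("method", "coefficient")]
    n_records = len(df.drop_duplicates(id_cols)) if id_cols else len(df)
    if len(selected) < n_records:
        raise ContentError(
            "some records lack a coefficient for their selected method"
        )
    c = selected["coefficient"]
    return ConditionSummary({"selection": dict(rule)},
                            float(c.mean()), float(c.std(ddof=0)), len(c))
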