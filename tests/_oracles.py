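"""Independent brute-force oracles used by multiple test modules.

Everything here is written as literal loops / direct transcriptions of the
definitions, deliberately independent of the package's vectorized paths.
"""

import numpy as np


def windowed_mean(x, width):
    """Centered moving average with shrunk edge windows, by explicit loop."""
    x = np.asarray(x, float)
    n = x.size
    out = np.empty(n)
    left = (width - 1) // 2 if width % 2 == 1 else width // 2 - 1
    right = width - 1 - left
    # np.convolve 'same' places the kernel center at index (width-1)//2 for
    # odd widths and width//2 for even widths; mirror that alignment
    if width % 2 == 0:
        left, right = width // 2, width // 2 - 1
    else:
        left = right = (width - 1) // 2
    for i in range(n):
        lo = max(0, i - left)
        hi = min(n, i + right + 1)
        out[i] = x[lo:hi].mean()
    return out


def band_power(frame_mags, bin_width, low, high, power=True):
    """Spectral integration by explicit loop over bins."""
    total = 0.0
    for k, m in enumerate(frame_mags):
        f = k * bin_width
        if low <= f < high:
            total += m * m if power else m
    return total


def dft_magnitudes(segment, window):
    """|DFT| of one windowed segment via the definition (O(n^2) safe for small n,
    np.fft for large) — independent of the package's stft framing code."""
    return np.abs(np.fft.rfft(np.asarray(segment) * np.asarray(window)))


def xcorr_scan(x, y, max_lag):
    """All-lag normalized cross-correlation by double loop.

    Series are z-normalized with population SD; R(k) = 1/(N-k) sum over the
    overlap, with roles swapped for negative lags.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    x = (x - x.mean()) / x.std()
    y = (y - y.mean()) / y.std()
    n = x.size
    out = {}
    for k in range(-max_lag, max_lag + 1):
        s = 0.0
        if k >= 0:
            for t in range(n - k):
                s += x[t] * y[t + k]
            out[k] = s / (n - k)
        else:
            for t in range(n + k):
                s += y[t] * x[t - k]
            out[k] = s / (n + k)
    return out


def reference_kalman(accel_angle, gyro_rate, dt, q_angle, q_bias, r_measure,
                     angle0, bias0=0.0, p0=1.0):
    """Scripted 2-state Kalman tilt filter, transcribed step by step."""
    angle, bias = float(angle0), float(bias0)
    P = np.array([[p0, 0.0], [0.0, p0]])
    out = []
    for za, zg in zip(accel_angle, gyro_rate):
        # predict
        angle = angle + dt * (zg - bias)
        F = np.array([[1.0, -dt], [0.0, 1.0]])
        Q = np.array([[q_angle, 0.0], [0.0, q_bias]]) * dt
        P = F @ P @ F.T + Q
        # update with measurement za of the angle
        H = np.array([[1.0, 0.0]])
        S = (H @ P @ H.T)[0, 0] + r_measure
        K = (P @ H.T / S).ravel()
        innov = za - angle
        angle += K[0] * innov
        bias += K[1] * innov
        P = (np.eye(2) - np.outer(K, H.ravel())) @ P
        out.append(angle)
    return np.array(out)


def segment_band_fraction(samples, sample_rate, low, high):
    """Fraction of a segment's spectral power inside [low, high) Hz, by DFT."""
    spec = np.abs(np.fft.rfft(samples)) ** 2
    freqs = np.fft.rfftfreq(len(samples), 1.0 / sample_rate)
    total = spec.sum()
    inside = spec[(freqs >= low) & (freqs < high)].sum()
    return inside / total
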