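"""Thoracic-variation extraction: pressure, accel, magnetic, accel+gyro."""

import numpy as np
import pytest

from breathwave import (
    MissingChannelError,
    ParameterError,
    SensorMethod,
    SensorTrace,
    extract,
    extract_accel_gyro,
    extract_accel_shift,
    extract_magnetic,
    extract_pressure,
    normalized_xcorr,
)
from breathwave.simulate import (
    BreathPattern,
    NoiseSpec,
    method_ground_truth,
    synth_sensor_trace,
)
from breathwave.evaluate import score_waveform


def _static_trace(n=2000, rate=100.0, tilt_deg=0.0):
    t = np.arange(n) / rate
    th = np.deg2rad(tilt_deg)
    z = np.zeros(n)
    return SensorTrace(t, {
        "pressure": np.full(n, 5.0),
        "accel_x": np.full(n, np.sin(th)),
        "accel_y": z.copy(),
        "accel_z": np.full(n, np.cos(th)),
        "mag_x": np.full(n, 30.0),
        "mag_y": np.full(n, -10.0),
        "mag_z": np.full(n, 40.0),
        "gyro_x": z.copy(), "gyro_y": z.copy(), "gyro_z": z.copy(),
    }, rate)


class TestStaticTraces:
    def test_constant_pressure_yields_zero_waveform(self):
        w = extract_pressure(_static_trace())
        np.testing.assert_allclose(w.values, 0.0, atol=1e-9)

    def test_static_accel_yields_zero_waveform(self):
        w = extract_accel_shift(_static_trace())
        np.testing.assert_allclose(w.values, 0.0, atol=1e-9)

    def test_constant_field_yields_zero_waveform(self):
        w = extract_magnetic(_static_trace())
        np.testing.assert_allclose(w.values, 0.0, atol=1e-9)

    def test_static_tilt_yields_zero_waveform_after_mean_removal(self):
        w = extract_accel_gyro(_static_trace(tilt_deg=15.0))
        assert np.max(np.abs(w.values)) < 0.2  # Kalman settling transient only


class TestRecovery:
    def test_pressure_recovers_clean_sinusoid_under_noise(self, breathing_trace, rng):
        trace, d = breathing_trace
        noisy = SensorTrace(trace.time, dict(trace.channels), trace.sample_rate)
        noisy.channels["pressure"] = noisy.channels["pressure"] + \
            0.3 * rng.normal(size=trace.time.size)  # broadband, above cutoff
        w = extract_pressure(noisy)
        r = normalized_xcorr(w.values, d, lag_window=1.0, rate=trace.sample_rate)
        assert abs(r.coefficient) >= 0.95

    def test_pure_high_frequency_noise_suppressed(self, rng):
        from breathwave.filters import bandpass
        rate, n = 100.0, 4000
        t = np.arange(n) / rate
        # noise strictly above the 1 Hz cutoff
        hf = bandpass(rng.normal(size=n), rate, 5.0, 45.0)
        trace = SensorTrace(t, {"pressure": hf}, rate)
        w = extract_pressure(trace)
        assert np.sqrt(np.mean(w.values**2)) < 0.1 * np.sqrt(np.mean(hf**2))

    def test_accel_tracks_displacement_derived_acceleration(self):
        pat = BreathPattern.normal()
        trace, truth = synth_sensor_trace(pat, NoiseSpec.silent(), seed=3)
        w = extract_accel_shift(trace)
        proxy = method_ground_truth(truth, "accel", cutoff=1.0)
        r = score_waveform(w, proxy)
        assert abs(r.coefficient) >= 0.9

    def test_accel_double_integration_approximates_displacement(self):
        pat = BreathPattern.normal()
        trace, truth = synth_sensor_trace(pat, NoiseSpec.silent(), seed=3)
        w = extract_accel_shift(trace, integrate=True)
        # detrended double integration tracks displacement (not acceleration)
        r = score_waveform(w, truth)
        assert abs(r.coefficient) >= 0.8

    def test_magnetic_tracks_displacement(self):
        pat = BreathPattern.normal()
        trace, truth = synth_sensor_trace(pat, NoiseSpec.silent(), seed=4)
        w = extract_magnetic(trace)
        r = score_waveform(w, truth)
        assert abs(r.coefficient) >= 0.95

    def test_magnetic_rejects_mains_interference(self, breathing_trace):
        rate = 400.0
        n = 8000
        t = np.arange(n) / rate
        d = np.sin(2 * np.pi * 0.25 * t)
        hum = 2.0 * np.sin(2 * np.pi * 50.0 * t)
        trace = SensorTrace(t, {"mag_x": 30 + d + hum,
                                "mag_y": np.full(n, -10.0),
                                "mag_z": np.full(n, 40.0)}, rate)
        w = extract_magnetic(trace, mag_axis="x")
        # interference RMS after the 1 Hz lowpass under 5% of its input RMS
        resid = w.values - (d - d.mean())
        assert np.sqrt(np.mean(resid**2)) < 0.05 * np.sqrt(np.mean(hum**2))

    def test_accel_gyro_recovers_breathing_tilt(self):
        pat = BreathPattern.normal()
        trace, truth = synth_sensor_trace(pat, NoiseSpec.silent(), seed=5)
        w = extract_accel_gyro(trace)
        r = score_waveform(w, truth)
        assert abs(r.coefficient) >= 0.9

    def test_accel_gyro_bounded_under_contradictory_inputs(self):
        # gyro insists on rotation while the accelerometer stays static:
        # the fused angle must not diverge over a minute
        n = 6000
        rate = 100.0
        t = np.arange(n) / rate
        z = np.zeros(n)
        trace = SensorTrace(t, {
            "accel_x": z.copy(), "accel_y": z.copy(), "accel_z": np.ones(n),
            "gyro_x": z.copy(), "gyro_y": np.full(n, 5.0), "gyro_z": z.copy(),
        }, rate)
        w = extract_accel_gyro(trace)
        assert np.max(np.abs(w.values)) < 10.0


class TestInvariances:
    @pytest.mark.parametrize("method", ["pressure", "accel", "magnetic", "accel_gyro"])
    def test_zero_noise_simulation_recovery(self, method):
        trace, truth = synth_sensor_trace(
            BreathPattern.deep(), NoiseSpec.silent(), seed=6)
        w = extract(trace, method)
        proxy = method_ground_truth(truth, method, cutoff=1.0)
        r = score_waveform(w, proxy)
        assert abs(r.coefficient) >= 0.99

    @pytest.mark.parametrize("method", ["pressure", "accel", "magnetic", "accel_gyro"])
    def test_outputs_are_zero_mean(self, method):
        trace, _ = synth_sensor_trace(BreathPattern.normal(), NoiseSpec(), seed=7)
        w = extract(trace, method)
        rms = np.sqrt(np.mean(w.values**2))
        assert abs(np.mean(w.values)) < 1e-9 * rms

    def test_linear_extractors_invariant_to_channel_offset(self, breathing_trace):
        trace, _ = breathing_trace
        shifted = {k: v + 3.0 for k, v in trace.channels.items()}
        strace = SensorTrace(trace.time, shifted, trace.sample_rate)
        np.testing.assert_allclose(extract_pressure(strace).values,
                                   extract_pressure(trace).values, atol=1e-9)
        np.testing.assert_allclose(extract_accel_shift(strace).values,
                                   extract_accel_shift(trace).values, atol=1e-9)
        np.testing.assert_allclose(
            extract_magnetic(strace, mag_axis="z").values,
            extract_magnetic(trace, mag_axis="z").values, atol=1e-9)

    def test_axis_flag_tracks_permuted_axes(self, breathing_trace):
        trace, _ = breathing_trace
        permuted = dict(trace.channels)
        permuted["accel_x"], permuted["accel_z"] = \
            trace.channels["accel_z"], trace.channels["accel_x"]
        ptrace = SensorTrace(trace.time, permuted, trace.sample_rate)
        np.testing.assert_allclose(
            extract_accel_shift(ptrace, axis="x").values,
            extract_accel_shift(trace, axis="z").values, atol=1e-12)


class TestDispatch:
    @pytest.mark.parametrize("method,func", [
        ("pressure", extract_pressure),
        ("accel", extract_accel_shift),
        ("magnetic", extract_magnetic),
        ("accel_gyro", extract_accel_gyro),
    ])
    def test_dispatch_equals_direct_call(self, breathing_trace, method, func):
        trace, _ = breathing_trace
        np.testing.assert_array_equal(extract(trace, method).values,
                                      func(trace).values)

    def test_unknown_method_lists_vocabulary(self, breathing_trace):
        with pytest.raises(ParameterError, match="magnetic"):
            extract(breathing_trace[0], "sonar")

    def test_missing_channel_named(self):
        t = np.arange(100) / 10.0
        trace = SensorTrace(t, {"pressure": np.ones(100)}, 10.0)
        with pytest.raises(MissingChannelError, match="mag_x"):
            extract_magnetic(trace)

    def test_sensor_method_validation(self):
        with pytest.raises(ParameterError):
            SensorMethod("sonar")
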