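# Methods

This note documents the models, parameter choices and numerical conventions
behind `breathwave`, and what the synthetic-data results do and do not show.

## Breath-sound route (band-ratio waveform)

Breath sounds are broadband turbulence whose center frequency differs
between respiratory phases: bronchial and bronchoalveolar sounds center
near 600 Hz on inhalation and 400 Hz on exhalation; alveolar sounds near
400 and 200 Hz, with a quiet exhalation. The extraction pipeline is

1. moving average over 10 audio samples (denoising),
2. STFT, Hann window of 4096 samples, 50 ms frameshift (2205 samples at
   44.1 kHz), no zero padding — a trailing partial window is dropped, so a
   signal of length L yields ⌊(L − 4096)/hop⌋ + 1 frames, each stamped with
   its window-center time,
3. per frame, SI(500–800 Hz) / SI(100–1000 Hz), defined as 0 where the
   denominator vanishes,
4. moving average over 10 frames (0.5 s at the 50 ms hop).

Choices worth stating:

* **SI sums squared magnitudes (power).** Whether spectral integration sums
  magnitude or power is a convention; power makes the Parseval consistency
  check exact and matches the energy framing of band-feature analyses in
  the lung-sound literature. `use_power=False` switches to magnitude for
  sensitivity runs.
* **Band edges are half-open on bin centers**, [low, high), so abutting
  bands (300–600, 600–800) never double-count a bin.
* **The same phrase "size 10" is applied at two different rates**: 10 audio
  samples (≈0.23 ms at 44.1 kHz) for denoising and 10 STFT frames (0.5 s)
  for smoothing. Only the second is meaningful at breathing timescales;
  reading both as audio samples would make the smoothing a no-op.
* **Numerator ⊆ denominator** is enforced, which bounds every waveform
  value in [0, 1] and makes the waveform invariant to audio amplitude
  scaling.
* An optional 150–1000 Hz zero-phase bandpass (the classical heart-sound /
  muscle-noise suppression stage) can be inserted before the STFT; it is
  off by default because the band ratio itself ignores energy outside
  100–1000 Hz.
* For peripheral auscultation points dominated by alveolar sounds, a
  300–600 Hz numerator matches the lower inhale/exhale centers; the
  acceptance run measures the resulting correlation gain.

## Thoracic routes

All four extractors end identically: subtract the series mean, apply a
zero-phase (forward-backward) 4th-order Butterworth lowpass, re-center.
Zero-phase filtering keeps every route's timing unbiased for the lag scan;
the cutoff default is **1.0 Hz** — breathing fundamentals stay below
≈0.7 Hz even for fast breathing, while sensor noise, mains interference and
circuit artifacts sit far above. Output sign is deliberately unconstrained
(the evaluation takes the extremum of |R|), since e.g. pressure increases
while magnetic field magnitude may decrease with the same chest motion.

* **pressure** — the contact-force channel directly, filtered.
* **accel** — the chest-normal axis (default z, device flat on the chest;
  configurable). The output is the filtered *acceleration*, not a doubly
  integrated displacement: double integration of a noisy accelerometer
  drifts quadratically, and for correlation scoring against a reference the
  phase-consistent acceleration is equally informative. Consequently the
  fair ground-truth proxy for this route is d²x/dt² of the displacement
  (`method_ground_truth`), band-limited to the extractor's lowpass band —
  content above the cutoff is removed by design and cannot be recovered.
* **magnetic** — vector magnitude of the magnetometer by default
  (orientation-robust); a single axis is selectable. The magnitude is a
  nonlinear map, so exact offset-invariance holds only in single-axis mode;
  for the small deflections involved the magnitude route is linear to first
  order.
* **accel_gyro** — per-sample tilt about the mediolateral axis,
  atan2(aₓ, a_z) in degrees, fused with the matching gyro rate (gyro_y) by
  a standard 2-state (angle, gyro-bias) Kalman filter. Defaults
  q_angle = 0.001, q_bias = 0.003, r_measure = 0.03 (per-step, dt-scaled)
  are the customary IMU-tilt values; the limits r→0 (pure accelerometer)
  and r→∞ (pure gyro integration) are verified in tests. The lowpass is
  applied to the fused angle output rather than to the raw channels — the
  filter order is not dictated by the physics, and filtering once at the
  end preserves the Kalman innovation statistics.

## Evaluation

Both series are linearly interpolated onto a shared uniform grid over their
time overlap (default 20 Hz, the belt's native rate; ≥ 5 s of overlap
required), z-normalized with the population standard deviation, and scanned
with R(Δt) = 1/(N−Δt)·Σ x_t·y_{t+Δt} over integer lags within ±5 s — wide
enough to absorb phase offsets between chest-wall motion and the abdominal
belt. The headline coefficient is R at the lag of maximal |R|, reported
signed (ties broken toward the smallest |lag|); R(0) is also carried for
lag-free comparisons, since published summaries rarely state their lag
convention.

Two numerical notes. First, normalize-then-correlate means R(0) of
identical series is exactly 1 under the 1/N convention. Second, because the
1/(N−Δt) estimator normalizes with full-series moments, |R| can exceed 1 by
a sliver at a perfectly aligned nonzero lag; the reported coefficient is
clipped to [−1, 1] while the scan itself follows the estimator exactly.

Summaries report mean and population SD per condition group and flag the
conventional thresholds (|R| > 0.4 correlated, ≥ 0.7 strong) as labels
only. `apply_selection` implements condition-dependent method choice —
e.g. pressure for normal breathing, magnetic for deep breathing — and
reports the mean over the per-record selected coefficients for comparison
with the pooled unselected mean.

## Simulator

The generator's defaults are the study conditions every test and the
acceptance run use:

* **Breathing pattern**: raised-cosine displacement, inhale:exhale = 1:2,
  10 % of each cycle spent in (two equal) pauses; *normal* = 15 breaths/min
  at depth 1.0, *deep* = 10 breaths/min at depth 2.0 (the protocol being
  emulated quantifies neither; these are typical adult values).
* **Sounds**: Gaussian noise bandpassed to center ± 100 Hz (bandwidth
  200 Hz) per phase, gated with ≈50 ms smooth onsets; presets
  bronchial (600/400 Hz, exhale 1.2× louder), bronchoalveolar (600/400,
  equal), alveolar (400/200, exhale gain 0.4). White noise is added at
  10 dB SNR by default.
* **Sensor trace** (default 100 Hz — the log format carries an explicit
  rate since the capture rig's rate is not standardized): one displacement
  d(t), scaled by a fixed per-position amplitude profile
  (0.8, 1.2, 0.8, 1.2, 0.9) favoring the upper-thorax and abdomen-adjacent
  points, drives all channels coherently: pressure = 10 + 2·d; the
  chest-normal accelerometer axis carries gravity·cos θ plus 0.02·d̈ (g);
  tilt θ = 2°·d with gyro_y = dθ/dt; magnetometer = ambient field
  (30, −10, 40) µT plus (1, 0.5, 5) µT·d. Units are arbitrary but
  self-consistent — every pipeline is amplitude-invariant after
  normalization.
* **Noise**: per-channel white noise plus a random-walk drift (units·√s)
  emulating slow contact/clothing artifacts that a lowpass cannot remove.
  The *study* profile makes the drift mode-dependent: deep breathing slips
  the pressure contact (heavy pressure drift, modest magnetic drift) while
  shallow breathing leaves the magnet deflection small relative to ambient
  wander (the reverse). This is what makes pressure the best normal-mode
  method and magnetic the best deep-mode method in the synthetic study,
  the regime the selection analysis is designed to expose.
* **Belt**: ground truth resampled to 20 Hz (a 20-s record gives 400
  samples) plus small Gaussian noise.
* **Study**: subjects draw breathing rate (N(15, 2) / N(10, 1.5) per mode),
  depth (±20 %/±15 %) and audio SNR (8–14 dB) from a master seeded stream;
  every record also derives its own seed from that stream, so the whole
  study is bit-reproducible from one integer.

**What passing on this simulator does not show.** The generated sounds are
stationary band-limited noise with clean phase gating — real lung sounds
have heart sounds, crackles, variable spectra and position-dependent
transmission; the sensor model is linear and drift is the only structured
artifact. Results here validate the *algorithms* (correctness against
oracles, phase recovery under the stated noise), not clinical performance
on human recordings.

## Problem sizes

Tests and the acceptance run use 20-second records (the protocol's record
length), 5 seeds for audio-route means, and a 4-subject study (120 records,
two methods scored per record) for the selection analysis; oracle
equivalence uses 100 random frames and 50 random series pairs. The full
14-subject layout (420 records) is available through `make_study(14, ...)`.

## Known limitations

* Double-integration of acceleration to displacement is implemented only as
  an option with detrending caveats; the default accel route reports
  filtered acceleration (see above).
* The magnetometer model is phenomenological (field ∝ displacement); no
  magnet-geometry field computation is attempted.
* `normalized_xcorr` scans integer lags on the common grid; sub-grid lag
  refinement is not implemented (at 20 Hz the lag quantum is 50 ms, small
  against breathing periods of 4–6 s).
* The Kalman tilt filter assumes a single rotation axis; full quaternion
  orientation and magnetometer-aided heading are out of scope.
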