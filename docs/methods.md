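# Methods

This note records the physical model, the simulator's assumptions, the
numerical choices in the analysis chain, and the open design decisions —
everything a reader needs to judge what the numbers produced by this
package do and do not mean.

## 1. Physical model

**Faraday rotation.** Linearly polarized light traversing an optically
active medium of length `L` along a magnetic field `B` has its plane of
polarization rotated by

    φ = V · B · L                        (physics.faraday_rotation)

where `V` is the Verdet constant. An equivalent form in terms of the
field-induced circular birefringence `Δn` at wavelength `λ`,

    φ = π · L · B · Δn / λ               (physics.faraday_rotation_birefringence)

agrees with the first when `V = π·Δn/λ`; the test suite checks that
identity. The inverse, `V = φ / (L·B·cos α)` with `α` the angle between
propagation and field, is `physics.verdet_constant`; geometries with
`L·B·cos α = 0` raise `DegenerateGeometryError` rather than returning
infinities.

**Minimum decorrelation field.** The smallest field that produces a
detectable speckle decorrelation scales as

    B_min = k · π · L / (R · φ)          (physics.min_decorrelation_field)

with `R` the illuminated-spot radius and `k` a proportionality constant
that defaults to 1 (it is a device calibration; we expose it rather than
bury it). Monotonicity in each argument is tested.

**Attenuation.** `physics.beer_lambert` implements the standard absorbance
convention `A = ln(I0/I) = ε·C·d` and returns `(A, I0·e^{-A})`. In
`reflection_mode` the effective path is doubled (`d_eff = 2d`), modelling
light that enters the tissue, is back-scattered, and exits through the same
surface. Transmitted intensity is clamped to `[0, I0]`; for `A ≳ 700` the
exponential underflows to exactly 0.0 in double precision, which the tests
acknowledge explicitly.

Glucose is chiral and has a comparatively large magnetic rotatory power, so
to first order `φ` — and therefore the amplitude of the field-driven
speckle motion — is linear in glucose concentration. That linearity is the
entire information channel the classifier uses.

## 2. What the simulator emulates — and what it does not

`simulator.simulate_recording` produces a sequence of 2-D intensity frames
meant to mimic a defocused camera imaging the secondary speckle of a
laser spot on skin over a wrist, with an electromagnet driven at
`drive_frequency` behind the tissue.

**Speckle texture.** A fully developed speckle field is generated as the
squared modulus of a circular complex-Gaussian random field band-limited
by a circular pupil mask of radius `1/(2·grain_size)` in frequency space.
This yields the correct first-order statistics (negative-exponential
intensity, contrast ≈ 1, checked in tests) and a controllable correlation
length (`grain_size`, default 4 px). It does not model polarization,
partial coherence, or depth-resolved multiple scattering.

**Motion.** In the defocused-imaging regime, surface tilt maps to rigid
translation of the pattern, so all deterministic motion is applied as
sub-pixel Fourier phase ramps to the underlying complex field (exact
translation, no interpolation error). The per-frame position is the sum of:

- a glucose-proportional sinusoid at the drive frequency on the x axis,
  amplitude = `glucose_gain · glucose_level · field_strength/150`, with
  `glucose_gain = 0.5/198 px per mg/dl` so that the largest reference
  level (198 mg/dl) moves 0.5 px at the nominal 150 Gauss — comfortably
  inside the tracker's sub-pixel regime, which is where the real
  instrument operates;
- a cardiac pulse: 1.2 Hz sinusoid, amplitude 0.1 px, random phase and
  20 % cycle-length jitter, on both axes;
- a random-walk drift of 0.01 px/frame step (tissue/operator motion);
- when the field is off, a small (`field_off_coupling = 0.1`) leakage of
  the glucose cue into the second pulse harmonic, so field-off recordings
  are weakly — not zero — informative, as real physiology would be.

**Decorrelation and noise.** Speckle "boiling" is modelled as per-frame
convex mixing of the propagated field with a fresh independent field,
`F_t = √(1−r)·F_{t−1} + √r·fresh` with `r = boiling_rate = 0.02`/frame,
which gives an exponential pattern-decorrelation time of ~0.1 s at
500 FPS. Additive Gaussian sensor noise (`noise_std = 0.02` of mean
intensity) is applied to the intensity frames; optional 8-bit quantization
mimics the camera ADC.

**Protocol defaults.** 128×128 px frames, 500 FPS, 5 s (2501 frames),
140 Hz drive, 150 Gauss — the acquisition geometry the analysis chain is
designed for. The frame rate must exceed twice the drive frequency;
violations raise `NyquistError` at construction. All randomness descends
from a single integer seed via `numpy.random.SeedSequence` spawning, so a
recording is bit-reproducible and the field-on/field-off members of a pair
share the same speckle realization.

Not modelled: scattering-medium speckle *decorrelation by the field
itself* (we model the tilt channel only), camera shot noise statistics,
motion blur within a frame, and inter-subject tissue variability.

## 3. Displacement tracking

`tracking.cross_correlate` computes the normalized zero-mean circular
cross-correlation via `rfft2` (value at zero lag equals the Pearson
correlation of the two frames). `estimate_shift` takes the arg-max —
ties broken first by smallest lag magnitude, then lexicographically —
and refines each axis with a 3-point parabolic fit through the
log-free correlation values, clamped to ±0.5 px. `track_video` batches the
FFTs over all frame pairs and supports `sequential` (frame t vs t−1,
the default; robust to slow decorrelation) and `fixed_reference` modes.
Accuracy is verified two ways: against analytically Fourier-shifted fields
(max error ≈ 0.06 px at half-pixel shifts) and against
`skimage.registration.phase_cross_correlation` as an independent sub-pixel
oracle.

## 4. Lock-in extraction

`lockin.lockin_filter` takes the real FFT of the displacement series,
zeroes every bin except the one nearest the drive frequency ±
`bandwidth_bins` (DC is always excluded), and inverse-transforms. This is
a linear, idempotent projection — both properties are tested — and on a
clean sinusoid reconstructs the input to ~1e-13 relative error.
`band_energy_fraction` reports the Parseval fraction of AC energy inside
the band (half-spectrum weights: 2 for interior bins, 1 for DC/Nyquist)
and is the per-recording quality diagnostic; a series with zero AC energy
raises `DegenerateInputError` rather than returning 0/0.

With the 5 s default recording the bin spacing is 0.2 Hz, so
`bandwidth_bins = 1` keeps 139.8–140.2 Hz; with the 1 s recordings used in
the shipped experiments the spacing is 1 Hz.

## 5. Features and classifiers

**SVM path.** Each recording becomes one 500-column row: the lock-in
filtered dx and dy series, each resampled to 250 points by linear
interpolation (`models.build_ml_features`). Two normalization choices are
deliberate and load-bearing:

- *No per-row z-score by default* (`scale="none"`). The lock-in output is
  (nearly) a pure sinusoid whose **amplitude** is the glucose signal; a
  per-row z-score maps every row to approximately the same unit sine and
  erases the classes. The `zscore` option exists for shape-based uses.
- *No per-column standardization by default* (`GlucoseSVM(standardize=False)`).
  Both axes are in the same physical unit (pixels); standardizing each
  column independently amplifies the pure-noise dy columns up to signal
  level and we measured it to roughly halve accuracy. `standardize=True`
  remains available for heterogeneous features.

Field-off ("normal condition") recordings are featured **without** the
lock-in — the mean-removed displacement series directly — because with no
drive line the 140 Hz band contains only noise and the physiologically
informative content (pulse harmonics) lies elsewhere.

Hyperparameters (kernel ∈ {rbf, linear}, `C ∈ [1e-2, 1e3]`,
`γ ∈ [1e-4, 1e1]`, both log-scaled) are chosen by Bayesian optimization:
a Gaussian-process surrogate (Matérn ν = 2.5 + white noise,
`bayesopt.minimize`) maximizing expected improvement over 5-fold
stratified cross-validated accuracy, with the budget split 2:1 between
rbf and linear. The fitted model is returned as an `SVMResults` object
(statsmodels-style: estimator configuration in `GlucoseSVM`, fitted state +
`summary()` in the results object).

**CNN→LSTM path.** An alternative end-to-end classifier consumes stacks of
min-max-scaled frame differences (`models.frame_difference_stack`; the
scaling floor is `min(0, diff_min)` so that zero motion maps to a stable
gray level): two conv(3×3, same)+ReLU+maxpool(2×2) stages, flattened per
frame, then a single-layer LSTM whose last hidden state feeds a softmax.
It is implemented in pure numpy with hand-written backpropagation — the
environment provides no deep-learning framework — and trained with Adam,
global-gradient-norm clipping at 2, learning rate 1e-4, batch 16. Every
analytic gradient is verified against central finite differences to
~1e-8 relative error in the test suite. It is a compact reference
implementation, not a performance-tuned network; on full-size problems the
SVM path is both faster and stronger.

**Metrics.** `models.evaluate_classifier` builds the confusion matrix by
direct counting and computes per-class precision `TP/(TP+FP)`, recall
`TP/(TP+FN)`, `F1 = 2PR/(P+R)` and their macro averages, with 0/0 defined
as 0. Results are cross-checked against `sklearn.metrics` in the tests.

## 6. Problem sizes and reported numbers

The shipped end-to-end experiment (README, `scripts/acceptance.py`,
`tests/test_acceptance.py`) uses 13 glucose levels × 10 recordings per
level per field condition at 64×64 px, 1 s, 500 FPS — a size this package
chose so the full pipeline (simulation, tracking, lock-in, Bayesian-
optimized SVM with 5-fold CV, held-out evaluation) runs in about a minute
on one CPU while still exercising every stage at realistic sampling rates.
Typical results (seeds 1/3/7): held-out accuracy 94.9–97.4 % with the
field on versus 0–15.4 % with it off (chance = 7.7 %), mean in-band energy
fraction 0.99 versus 0.01. The 30 % held-out split is stratified by level.

## 7. Limitations

- The simulator's glucose→amplitude gain is a modelling choice, not a
  physiological calibration; absolute accuracies characterize the
  pipeline, not a clinical device.
- Single "subject": one speckle statistics model, one pulse model; no
  session-to-session or inter-subject variability, so generalization
  across subjects is untested by construction.
- The lock-in assumes the drive frequency is known exactly and stable;
  real hardware would need drive-frequency tracking or a wider band.
- Classes are the 13 discrete reference levels; the package classifies,
  it does not regress concentration, and levels 3 mg/dl apart (e.g. 89
  vs 92) bound the achievable accuracy through simple confusability.
- The numpy CNN→LSTM is O(minutes) per epoch at full frame size; it is
  validated on reduced problems.
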