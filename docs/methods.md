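# Methods

This note documents the algorithms, every default that matters, and the
reasoning behind the choices. Module names in parentheses.

## 1. Synthetic cohort (`ppgage.simulate`)

### Pulse surrogate

One beat is a sum of three Gaussians — systolic, reflection, and dicrotic
components — parameterized by `PulseModelParams` (duration; per-component
amplitude, center, width, the last two as fractions of the duration).
Gaussians are smooth and have closed-form derivatives of every order
(Hermite forms: g′ = −(z/s)g, g″ = ((z²−1)/s²)g, g‴ = −((z³−3z)/s³)g with
z = (t−μ)/s), so `analytic_derivative` provides an exact oracle against
which the numerical Savitzky–Golay derivatives are tested.

### Age map

`default_age_effect_map(age, duration)` encodes vascular aging as, with
u = clip((age − 72.5)/12.5, ±1.6):

* reflection amplitude **rises**: 0.35 + 0.15·u, width 0.075;
* dicrotic amplitude **falls**: max(0.04, 0.22 − 0.08·u);
* the reflection center is **fixed** at c₁ + √3·w₂ ≈ 0.30 of the pulse,
  i.e. at the positive-curvature lobe of the reflection Gaussian relative to
  the systolic peak at 0.17. This alignment makes a stronger reflection
  deepen the SDPPG b-wave and depress the c-wave, so AI rises and c/a falls
  with age;
* resting heart rate declines 0.35 bpm per year of age
  (`heart_rate_age_slope`), lengthening the pulse, which is what carries the
  positive T_ac–age correlation.

An earlier design that shifted the reflection center earlier with age (a
common physiological narrative) was abandoned: measured through the
0.4–9 Hz zero-phase band-pass, the earlier-arriving reflection cancels the
timing signal and decorrelates AI from age. The present map reproduces the
expected correlation signs (c/a −, T_ac +, AI +, ΣTDPPG −) robustly across
master seeds with magnitudes in the 0.2–0.9 range.

### Recording assembly

Per subject: the heart rate is drawn once (N(center, 2 bpm)); the
morphology is jittered once (log-normal σ = 0.06 on amplitudes/widths,
Gaussian on reflection center). The beat waveform is sampled **in absolute
time** as one shape 1.25× the mean beat long; per-beat log-normal duration
jitter (σ = 0.03) only truncates or zero-pads the diastolic tail, so beat
timing of the systolic/reflection complex does not smear. Beats occupy
disjoint segments, making stored ground-truth onsets exact. On top:
respiratory sinusoid (0.25 Hz, amplitude 0.10), linear trend (0.20 over the
recording), white noise (σ = 0.02), per-beat gain jitter (σ = 0.05).
Cohort ages are truncated-normal (mean 71.19, SD 6.97, range 60–85,
n = 84, 300 s at 250 Hz by default). Per-subject seeds derive from the
master seed; everything is deterministic.

`synthesize_features` additionally emits feature tables directly from a known
linear age model (for exercising the regression/network stages without the
waveform pipeline). Its ΣTDPPG spread is set to SD 10 — a spread small
enough to be realistic but large enough that the −0.05 coefficient
contributes measurable age signal.

### What is and is not emulated

Emulated: sampling rate and duration, beat-to-beat variability, baseline
drift and noise, age-dependent morphology with the right correlation signs,
ground-truth onsets/derivatives. **Not** emulated: hemodynamics (no
Windkessel), sensor optics, motion artifacts, arrhythmia, and any claim
that the parameter–age mappings are physiologically calibrated. Conclusions
drawn on synthetic cohorts are software-validation conclusions only.

## 2. Preprocessing (`ppgage.preprocess`)

Linear least-squares detrend, then a fourth-order Butterworth band-pass,
0.4–9 Hz, designed in second-order sections (numerically stable with a
0.4 Hz corner at 250 Hz) and applied forward–backward (`sosfiltfilt`) for
zero phase, with odd-reflection padding of length 3×(order+1). Note that
the 0.4 Hz corner has edge transients lasting tens of seconds; tests of
exact zero-phase symmetry therefore compare signal interiors.

## 3. Segmentation (`ppgage.segment`)

Systolic peaks: `scipy.signal.find_peaks` with 300 ms minimum separation
and prominence 0.3×(p95 − p5) of the filtered signal. A pulse ends at the
global minimum between successive peaks (the post-dicrotic-notch minimum);
the next sample is the next onset. Beats are excluded when the
pulse-to-pulse interval is outside 300–2000 ms, the length is outside
median ± 25%, or the peak-to-peak amplitude is more than 3 robust SD
(1.4826×MAD) from the median. At least 10 beats must survive.

The representative pulse is the sample-wise mean of the retained beats,
truncated to the shortest retained beat. Averaging windows are anchored on
each beat's systolic peak with the onset-to-peak offset fixed at its
within-recording median: the inter-beat valley is nearly flat, so the raw
argmin jitters by tens of milliseconds under noise and smears the average
badly enough to erase the d/e waves; the systolic peak is sharp and keeps
alignment within a sample. On noise-free recordings the two alignments
coincide; beat extents, intervals, and exclusions still come from onsets.

## 4. Derivatives and fiducials (`ppgage.fiducials`)

Savitzky–Golay differentiation, window 25 ms (7 samples at 250 Hz, floor
polyorder+2, forced odd), polynomial order **5**. Order 5 rather than 4:
the third-derivative truncation bias of a degree-4 fit on a Gaussian pulse
at 250 Hz is ~2% of the oracle peak regardless of window length, while
degree 5 (exact for quintics) measures <0.01% against the analytic oracle.
Output is in physical units (scaled by fs^order) except where per-sample
units are requested (ΣTDPPG, below). Edge samples come from one-sided fits
and are excluded from fiducial search (half a window on each side).

Fiducials on the representative-pulse SDPPG: *a* = global maximum within
the first 30% of the pulse; then *b, c, d, e* = the next strict local
minimum/maximum/minimum/maximum found sequentially by first-difference sign
change, earliest sample on plateaus. Any missing wave raises an error
naming it. Detection is purely morphological.

## 5. Features (`ppgage.features`)

Per subject: b/a, c/a, d/a, e/a; T_ab, T_ac, T_ad, T_ae (ms from the
a-wave); AI = (b − c − d − e)/a; and ΣTDPPG×10⁴.

ΣTDPPG is the sum over retained beats of the RMS third-derivative
amplitude, ×10⁴. Two conventions needed fixing:

* **Per-beat, not whole-signal**: "sum of RMS values" is read as a sum over
  beats; an alternative (representative-pulse only) is a config switch.
* **Per-sample derivative units of the unit-peak-to-peak-normalized beat**:
  each beat is scaled to unit peak-to-peak before differentiation (device
  gain independence) and the third derivative is taken per sample index,
  not per second — fs³ scaling would put the ×10⁴ statistic near 10⁹,
  whereas per-sample units land a 5-minute recording near 10². A
  per-minute normalization toggle (recording-length independence) exists,
  default off.

## 6. Age models (`ppgage.regression`, `ppgage.ffnn`)

* **Reference linear model** (fixed): Age = 109.65 + 22.16·AI −
  0.05·ΣTDPPG×10⁴.
* **Stepwise OLS** over the ten features: forward entry of the smallest
  p-value below `p_enter` = 0.05, then backward removal above
  `p_remove` = 0.10 (entry < removal guarantees termination), via
  statsmodels; reports SEs, t, p, adjusted r². Zero-variance targets return
  the intercept-only model.
* **FFNN**: 4 inputs (c/a, T_ac, AI, ΣTDPPG×10⁴), one hidden layer of 15
  tanh neurons, linear output. Inputs and target are min–max normalized to
  [−1, 1] on the training split. Training is full-batch
  Levenberg–Marquardt: solve (JᵀJ + μI)δ = Jᵀr, μ starting at 10⁻³, ×10 on
  step rejection, ÷10 on acceptance; an epoch is an accepted step, so the
  training MSE is non-increasing by construction. Split 60/20/20
  train/validation/test (test fraction 0.20 fixed, remainder 75/25),
  random, seeded. Training stops after 6 consecutive validation-MSE
  increases (patience) or 1000 epochs; the returned weights are from the
  best-validation epoch, and the full per-epoch MSE trace (original units)
  is stored on the model. Initialization is seeded uniform(−0.5, 0.5); no
  dropout or weight regularization. `hidden_layer_sweep` refits across
  hidden-layer sizes and tabulates test MSE, best epoch, and per-split
  Pearson r.

## 7. Evaluation (`ppgage.evaluate`)

Pearson r (requires n ≥ 3 and nonzero variance), per-split MSE, an error
histogram with bins symmetric about zero (default 20), and Bland–Altman
agreement: differences predicted − actual, 95% limits mean ± 1.96·SD
(ddof = 1), and the fraction of points inside the limits. Optional PNG
plots (scatter with identity line, training curve, histogram, Bland–Altman)
via the Agg backend.

## 8. Configuration and provenance (`ppgage.config`, `ppgage.cli`)

A single YAML file surfaces every default above as a named key; unknown
keys anywhere are rejected. One master seed drives cohort generation and
the data split. `ppgage run` writes the feature table, all model files,
reports, and `provenance.json` (package version, SHA-256 config hash,
seed, failed subjects); per-subject extraction failures are logged and
skipped, and partial success is signalled by exit status 3. Re-running an
identical configuration reproduces identical artifacts.

## Numerical caveats

* Inter-beat valleys of the synthetic pulse are nearly flat; onset argmin
  positions are therefore not meaningful to the sample, which is why
  representative-pulse averaging anchors on systolic peaks (§3).
* Histogram bins are half-open (NumPy convention); values exactly on an
  interior edge count rightward.
* The fixed reference linear model is biased on synthetic cohorts (its
  calibration population and device differ); correlation is high but MSE is
  large — refit before interpreting absolute ages.
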