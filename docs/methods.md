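# Methods

## Signal model

A synthetic pulse waveform stands in for real PPG recordings. Each cardiac
cycle is the sum of two Gaussian bumps — a systolic component of amplitude
A and width σ_s, and a diastolic component of amplitude r·A (r < 1) delayed
by d seconds with width σ_d — plus white Gaussian noise and a slow
sinusoidal baseline wander that emulates respiration and slow motion.
Gaussians were chosen over more physiological templates (log-normal,
gamma-variate) because every per-beat extremum has a cheap closed form:
tests can locate the true systolic peak, inter-beat minimum and diastolic
secondary maximum by evaluating the template on a dense grid, which gives
an independent oracle for the fiducial detector. Per-beat heart-rate
jitter (Gaussian on the beat rate, default 2 bpm) keeps the inter-beat
interval feature non-degenerate.

What this generator deliberately does **not** emulate: dicrotic-notch
morphology distinct from the diastolic bump, pulse-amplitude variation
with respiration, motion artifacts beyond stationary white noise and
sinusoidal wander, sensor saturation, or any optical skin physics. Tests
passing on these signals therefore establish that the pipeline's
arithmetic, detection logic and statistical machinery are correct — not
that the method would reach the same accuracy on real wrist recordings.

GSR panels are drawn per subject from per-channel normal distributions
(location ≈ 260–450 kΩ depending on acupoint, between-subject scale 20%
of location). Left/right channels of the same acupoint share a latent
factor giving a bilateral correlation of 0.9, mirroring the strong
left-right symmetry of real acupoint resistances. Raw 5-s GSR traces are
not simulated; the generator draws the per-acupoint medians directly,
since only medians enter the feature vector.

## Cohort defaults and what they encode

The default two-group parameterization encodes the reported wiry-pulse
effect directions: a narrower systolic peak (width 0.125 s vs 0.140 s), a
diastolic peak closer to the systolic peak (delay 0.32 s vs 0.40 s), a
smaller diastolic component (ratio 0.28 vs 0.45), a slightly higher heart
rate (74 vs 70 bpm, sd 7), weaker second-harmonic content (an emergent
consequence of the delay/ratio contrast: a control delay near half the
beat period feeds the second harmonic constructively), and lower skin
resistance — a global ×0.88 shift on all 24 channels, strongest at the
liver (LV3, ×0.78) and pericardium/heart (PC7, HT7, ×0.85) points,
consistent with a broad sympathetic activation pattern.

The magnitudes are generator design constants, not physiological claims.
They were set, once, so that each modality alone is informative but
imperfect and fusion is genuinely beneficial: with 64 training subjects, a
42-input network estimates its decision rule from few effective samples
(the GSR block is constant within subject, so its 24 dimensions carry one
observation per subject), and two design pitfalls had to be avoided. If
most GSR channels carry no signal they act purely as memorizable subject
fingerprints and the fused model *underperforms* the PPG-only model; and
if the PPG contrast is too large the PPG-only model saturates and leaves
fusion no headroom. The defaults place subject-level cross-validated
accuracy at roughly 0.80 (GSR only), 0.91 (PPG only) and 0.93–0.95
(fused) on 80-subject cohorts. Setting both groups' parameters equal
removes all signal and drives cross-validated accuracy to chance, which
the test suite checks as a null calibration.

## Preprocessing

* **Bandpass**: 4th-order Butterworth, 0.5–8 Hz, applied forward-backward
  (zero phase) so fiducial timings are unshifted; effective attenuation is
  the squared magnitude response. The corners are the standard PPG band.
* **PMAF**: beats are anchored on local maxima of a lightly smoothed copy
  of the signal (the smoothing only stabilizes anchor positions against
  sample noise); each inter-anchor period is linearly resampled to a
  common phase grid, averaged over a centred window of K = 3 periods
  (truncated at the ends), and resampled back. On an exactly periodic
  signal whose period is an integer number of samples the filter is the
  identity; on periodic signal plus independent noise it reduces the noise
  standard deviation by ≈ 1/√K. Callers may pass explicit anchors or a
  beat period; otherwise the period comes from the autocorrelation peak.
  The filter runs once on the full 5-minute trace before windowing.
* **Windowing**: 10-s windows, 1-s hop, starting at t = 0. The window
  count convention is floor((duration − window)/hop), i.e. a 300-s
  recording yields 290 windows; the hop length is a package choice (only
  the window length and the 290 count are fixed externally) and both are
  configurable.

## Fiducial delineation

Systolic peaks use the event-related moving-average scheme with its
standard constants (111-ms peak-scale window, 667-ms beat-scale window,
offset 2% of the mean squared signal); blocks shorter than the peak-scale
window are rejected and the peak is the argmax of the raw segment within
the block (ties break to the earliest sample). Onsets run the same
detector on the negated signal with an inter-beat-minimum fallback. The
diastolic peak is the first local maximum of the inverted, 120-ms-smoothed
second finite difference between the systolic peak and the beat trough,
subject to a prominence floor of 2% of the inverted-curvature range —
beats with no qualifying bump record the point as absent, and absent
points simply drop that beat from the features that need them (f1, f2,
f3, f7). The pulse-wave end is *defined* as the next beat's onset, which
makes the beat partition exhaustive; the final beat of each window, having
no successor, is discarded.

## Features

Amplitudes are min-max normalized per window before any distance is
computed, making f1/f2/f4 and the harmonic amplitudes invariant to device
gain and making the time and amplitude axes commensurable; the f3 angle is
computed on the normalized waveform with the abscissa in sample units
(output in degrees). Per-window heart rate is 60 over the median
inter-peak interval; harmonic amplitudes are 2|X_k|/N at the bin nearest
n·f₀ with no taper (10-s windows give 0.1-Hz bins, and exact-bin test
signals motivate the rectangular window; a Hann taper is available).
Harmonics at or above Nyquist (possible at 25 Hz for C9–C10 at high heart
rates) report 0. Windows that are flat, have fewer than two systolic
peaks, no complete beat, or no diastolic peak anywhere are flagged invalid
and excluded, with counts logged.

## Classifier and evaluation

The network is fixed at 42 → 30 → 30 → 30 → 1 (ReLU hidden layers,
logistic output, cross-entropy, adam). Training hyperparameters are free
choices: learning rate 10⁻³, batch 128, 120 epochs, and L2 penalty
alpha = 5. The unusually large alpha compensates for the 290-fold row
duplication of the subject-level signal — scikit-learn scales the penalty
by the number of rows, while the between-subject information content is
only one observation per subject — and without it the network memorizes
training subjects through their constant GSR block. Features are z-scored
with parameters fitted on training folds only.

Cross-validation is stratified 5-fold **by subject**; splitting by window
would leak both the within-subject dependence and the constant GSR block.
A subject's prediction is the mean of their window probabilities,
thresholded at 0.5 (majority voting gives indistinguishable results; the
mean rule is the package default). Feature importance uses a seeded
500-tree random forest fitted on per-subject feature means (using raw
windows would overstate the evidence 290-fold), with Welch two-sample
t-tests for the group comparisons.

## Numerical conventions and degenerate inputs

0-based half-open indexing everywhere; times in seconds; resistances in
ohms internally (kΩ only in CSV headers). Degenerate cases: all-zero or
flat windows are invalid; a collinear peak triangle yields f3 = 180°; a
constant feature gets importance 0 and no p-value; GSR traces drop
non-positive readings before the median (even-length medians average the
two central order statistics); recordings shorter than three beat periods
refuse PMAF.

## Problem sizes

Default experiments use 80-subject cohorts with 5-minute recordings
(23,200 windows), matching the emulated study design; the fusion-benefit
property is averaged over five seeded cohorts and the null calibration
over ten smaller ones (16 subjects, 1-minute recordings), sizes chosen so
the full suite runs comfortably on a laptop-class single CPU.

## Known limitations

* At 25 Hz a beat is ~20 samples, so fiducial timing is quantized to
  40 ms; f3 in particular compresses toward 180° and group differences in
  it are attenuated.
* The diastolic detector returns the curvature bump, which on merged
  (shoulder-type) beats sits earlier than the true secondary maximum;
  f7 therefore under-reports large systolic-diastolic delays.
* PMAF assumes quasi-periodicity; highly arrhythmic signals would smear.
* The GSR generator draws medians directly and ignores electrode-contact
  drift within the 5-s sampling window.
* Holdout evaluation freezes the scaler and network but not the segment
  validity policy; a holdout subject with zero valid windows would be
  excluded rather than scored.
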