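# Methods

`blowspiro` estimates a person's *lung age group* from the sound of a forced
exhalation recorded by an ordinary microphone. This note documents the models
and procedures the package implements, the choices made where the design was
genuinely open, and what the synthetic test corpus does and does not show.

## Signal model of a blow

When a person blows, the vocal cords are inactive, and the emitted sound is
well approximated by white noise through a band-pass filter set by the mouth
position. Two blow types are distinguished: *hot* blows (as when misting a
window) with energy in 450–1300 Hz, and *cold* blows (as when cooling soup,
and the type a spirometry maneuver resembles) with energy in 1500–4000 Hz.

The amplitude envelope follows the flow-rate curve of a spirometry test:

* **healthy** — linear rise to peak flow at `t_peak` (default 0.2 s), then
  exponential decay `exp(-λ (t - t_peak))` with λ in 1/s;
* **obstructive** — the same rise, then `exp(-(λ (t - t_peak))^p)` with
  `p = 1.6 > 1`, i.e. decay asymptotically faster than exponential;
* **restrictive** — a Weibull(k = 2) density profile whose time-integral is a
  `capacity < 1` fraction of the healthy envelope's (reduced vital capacity).

The generator (`blow_synth`) renders a blow as seeded Gaussian noise filtered
with a 4th-order Butterworth band-pass applied forward–backward (zero phase),
multiplied by the envelope, optionally mixed with broadband floor noise, and
peak-normalized. Default duration is 6 s at 44.1 kHz, consistent with a
forced-exhalation maneuver.

### Age conditioning

Corpora condition the envelope on age through a monotone map
`age → (decay-rate multiplier, total-energy multiplier)`, by default
`1 + 0.01 (age − 17)` and `1 − 0.005 (age − 17)` over the study ages 17–67.
This is a stand-in for testing signal recovery — older lungs exhale with
faster flow decay and less total volume — not a physiological model; the
slopes are configurable (`make_age_effect`), and recovery experiments that
ask whether the *pipeline* can find a signal that is clearly present use a
steeper decay slope (0.05/year) on a healthy-only corpus, so the age effect
is isolated from the disease-envelope confound.

What the generator deliberately omits: room acoustics, environmental noise
events (coughs, speech), microphone nonlinearity, and any quantitative link
between age and acoustics beyond the monotone stand-in. Passing tests
therefore show that the pipeline recovers the acoustic structure it targets,
not that it measures real lung function.

## Spirometer-like features

A Hann-window STFT (default `n_fft` 2048, hop 512 — the de facto audio
defaults, config-exposed) gives a magnitude spectrogram converted to decibels
relative to its own maximum and floored at −80 dB. Referencing the maximum
makes every dB feature invariant to recording gain, which is uncontrolled at
20 cm mouth-to-phone distance. Three scalars approximate the classic
spirometric measures:

* `total_dec` = Σ |dB| over all bins and frames (≈ FVC);
* `total_dec_1st_sec` = the same sum over frames with center time < 1 s (≈ FEV1);
* `max_peak` = max(dB) − min(dB), the spectrogram's dynamic range (≈ PEF).

With a self-referenced dB scale the literal "maximum of the decibels" is
always 0, so the peak feature is defined as the dynamic range, preserving the
peak-flow intent. With the −80 dB floor it saturates at 80 for most
full-length blows; it is kept for completeness and its constancy is handled
gracefully downstream (constant columns are treated as uncorrelated in the
correlation filter).

## Choi–Williams time-frequency analysis

The Wigner–Ville distribution offers maximal joint time-frequency resolution
among quadratic distributions but is afflicted by oscillatory cross-terms.
The Choi–Williams distribution multiplies the ambiguity function (the 2-D
Fourier dual over doppler θ and lag τ) with `exp(-(2π)² θ² τ² / σ)`, which is
1 on the axes (preserving both marginals and the total energy) and decays
off-axis (suppressing cross-terms). σ defaults to 1, the common choice;
larger σ approaches the raw Wigner distribution.

Discretization: frames of 1024 samples (hop 512) are made analytic (Hilbert
transform), the instantaneous autocorrelation `K[n, m] = x_a[n+m] x_a*[n−m]`
is formed over 512 lags, and a DFT over the lag axis yields 512
positive-frequency bins `f_k = k · fs / 1024` on [0, Nyquist). The kernel is
applied in the ambiguity domain with θ in cycles/sample and τ the physical
lag in samples (2m). The matrix is normalized to unit sum.

The marginal densities `mtN` (time) and `mfN` (frequency) are computed
directly from the analytic signal — instantaneous power `|x_a(t)|²` and the
periodogram — rather than by summing the smoothed matrix. These are the
Wigner distribution's theoretical marginals, and computing them directly
guarantees non-negativity, so every logarithm in the entropy and information
features is defined. Densities inside logarithms are floored at
`eps = 2⁻³⁰` (≈ 30 bits of information for an empty bin).

### Whole-recording marginals, frame-wise matrix

The time marginal is the exhalation's flow profile: its entropy, kurtosis
and moments only mean something when taken over the *whole* maneuver — over
a 23 ms frame, a normalized instantaneous-power density is blind to the
envelope decay that distinguishes lungs. All marginal-based features are
therefore computed from whole-recording marginals, aggregated onto a fixed
grid of 1024 equal time cells × 512 frequency bins (bin width fs/1024).
The fixed grid keeps `H_tf = H_t + H_f ≤ log₂ 1024 + log₂ 512 = 19 < 20`
bits for any recording length.

The 2-D smoothed matrix itself is another matter: a full-signal Wigner
distribution at 44.1 kHz × several seconds is O(N²) and infeasible, so the
`momC` moments — the only features needing the matrix — are computed
frame-wise (1024-sample frames, hop 512, each frame's distribution
normalized) and averaged across frames. A `max_frames` cap (default 16)
uniformly subsamples the frame grid, so the across-frame mean stays an
unbiased estimate of the all-frames mean at a fixed per-recording cost
(~0.7 s per 6-s recording on one CPU).

## The 38 time-frequency features

Over seven fixed bands (0–80, 80–250, 250–550, 550–900, 900–1500, 1500–3000,
3000–Nyquist Hz; half-open, chosen around the cold-blow range), using the
separable joint density `pD(f,t) = mfN(f) · mtN(t)`:

* `e_bn1..7` — mean over time of the in-band *share* of the spectrum at each
  instant. Defining the instantaneous energy as a per-time share makes the
  seven features partition to exactly 1, a conservation law the tests assert.
* `f_cres1..7` — mean instantaneous frequency peak: the in-band arg-max of
  `pD(f,t)`, ties broken toward the lowest bin, instants with no in-band
  energy above `eps` excluded, silent bands reported as 0.
* `f_med1..7` — mean instantaneous frequency: the energy-weighted in-band
  mean, same exclusion rules; always inside the band.
* `ie_bn1..7` — mean spectral information `−log₂ mfN(f)` over the band's bins
  (bits).

Over the full range: the Shannon entropies `H_t` and `H_f` of the marginals
and their sum `H_tf` (an exact identity); at the default discretization
`H_tf ≤ 19 < 20` bits. `K` is the Pearson kurtosis `μ₄/μ₂²` of time under `mtN`
(Gaussian → 3, uniform → 9/5). Six joint moments `tⁿ fⁿ`, `n ∈ {1, 7, 15}`,
with both axes normalized to [0, 1] to prevent overflow at order 15: `momC`
over the signed Choi–Williams matrix, `momM` over the product of the
marginals. On a separable distribution `momC = momM` exactly; their
differences measure time-frequency coupling that survives smoothing, which is
why `momC` is taken on the smoothed matrix and not on the (always separable)
product density.

## Prescreening

1. **Correlation filter** (threshold 0.9): of every feature pair with
   |Pearson r| above threshold, the later column in canonical order is
   dropped; gender is never dropped; constant columns are treated as |r| = 0
   with a warning.
2. **PCA feature selection** (target 99.9% explained variance): PCA on
   standardized columns; components retained to the cumulative target; each
   original feature scored by Σ_c EVR_c · loading²; the smallest
   score-descending prefix reaching the target share of total score is kept.
   Selecting original features (not components) preserves named-feature
   interpretability; the loading-score rule is one defensible realization and
   is config-replaceable.
3. **SMOTE**: minority classes are topped up to the majority count by convex
   interpolation between a class member and one of its k = 5 nearest
   same-class neighbours (k reduced for tiny classes), seeded and
   deterministic. By default SMOTE runs *inside each training fold*, so no
   synthetic neighbour of a held-out row ever reaches training; the
   `presplit_smote` option balances the whole table before splitting, which
   inflates metrics through leakage — the test suite demonstrates the
   ordering, and reports always record which mode produced them.

## Classification and evaluation

Ages are binned into half-open groups of width 1, 2, 3, 4, 5 or 10 years
anchored at age 17. Eight classifiers are compared at canonical defaults:
K-NN (k = 5), C-SVC (RBF, C = 1), random forest (300 trees), decision tree,
Gaussian naive Bayes, logistic regression (L2), LDA, and QDA. The QDA is a
package-local implementation with Ledoit–Wolf-shrunk per-class covariances:
with ~11 classes from a few-hundred-row table, classes routinely have fewer
members than features, where the sample covariance is singular; Ledoit–Wolf
shrinkage is the standard parameter-free estimator for that regime.

Evaluation is stratified 10-fold cross-validation (folds reduced to the
smallest class size when needed), features standardized per training fold,
one experiment seed driving fold shuffling, SMOTE and forest randomness.
Metrics: accuracy (trace/total), and one-vs-rest sensitivity and specificity
macro-averaged over classes present in the truth. Classifier pairs are
compared by two-sided paired t-tests on fold-wise accuracy at a
Bonferroni-corrected level α/28; zero-variance differences are treated
exactly (p = 1 for zero mean difference, p = 0 otherwise).

## Numerical and degenerate-input conventions

All-zero signals and frames raise degenerate-input errors (the dB reference
and the distribution normalization are undefined); all-zero frames inside an
otherwise valid recording are skipped. Arg-max ties break toward the lowest
frequency bin. Silent bands yield 0 for their features. Zero-variance
columns standardize to zero (not NaN) before PCA. Kurtosis of a single-point
mass raises rather than returning infinity.

## Problem sizes

The test suite and the reproduction script use synthetic corpora of 20–300
recordings of 1.5–6 s; these sizes mirror the few-hundred-sample scale of a
realistic single-site exhalation corpus while keeping a full run on one CPU
in minutes. The recovery experiment uses 300 healthy-only recordings with
the steep (0.05/year) age slope, isolating the age effect from the
disease-envelope confound so the test measures the pipeline, not the
generator's subtlety.

## Known limitations

* No calibration to litres or litres/second; features approximate spirometric
  quantities only in rank, not scale.
* The Choi–Williams σ, window and normalization conventions of prior art
  vary; results are documented for this package's conventions.
* `max_peak` saturates at the dB floor for most full-length recordings.
* The synthetic corpus cannot validate clinical claims; it validates the
  pipeline's mechanics.
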