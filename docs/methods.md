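# Methods

## Signal model and generator

Each simulated trial is a 5-s, fs = 256 Hz multichannel segment

x_c(t) = g_c · Σ_{tags f} w_f · Σ_{n=1..3} ρ^{n−1} · sin(2π n f t + φ_f) + σ · ε_c(t)

with tag frequencies f ∈ {8.57, 12} Hz, harmonic rolloff ρ = 0.5 per
order, a per-trial tag phase φ_f ~ U(0, 2π), channel gains g_c
(occipital O1/O2/Oz at 1.0, the 16 centro-parietal/frontal sites at 0.2)
and noise ε_c that mixes 1/f^β pink noise (β = 1) with a white Gaussian
floor (20 % of the noise variance), independently per channel. The
attention state sets the weight pair: the attended tag receives
`attention_weights[0]` (default 1.0) and the unattended tag
`attention_weights[1]` (default 0.3); `snr` is the attended fundamental's
amplitude at unit gain divided by σ (default 1.0; `None` disables noise).
Feedback-phase trials are generated with attend-Gabor weights, since the
instruction during that phase is to attend the Gabor.

Defaults were chosen once as a plausible high-contrast regime — an
attended:unattended amplitude ratio of about 3:1 with tag amplitude equal
to the broadband noise SD. Over a 5-s window the 0.2-Hz-resolution spectrum
concentrates the tag into a handful of bins, so this regime is strongly
decodable by design; no published amplitude or SNR figures exist for the
task to anchor these numbers.

Per-trial randomness derives from `numpy.random.SeedSequence(seed).spawn`,
so a session is bit-reproducible and trials are independent.

What the generator deliberately does *not* emulate: ocular/EMG artifacts,
volume conduction and realistic topography, non-stationary attention within
a trial, inter-trial intervals, or inter-individual spectral idiosyncrasy
beyond the weight/SNR knobs. Consequently, green simulation-based tests
demonstrate that the pipeline is correct and recovers planted contrasts —
not that real adolescent EEG would reach the same accuracies.

### Tag phase

The per-trial uniform phase matters: the cosine-correlation feature uses a
fixed zero-phase template, so its expected value over trials is phase-washed
and its single-trial values fluctuate in sign. That feature family scoring
worse than band-power families on simulation is therefore an honest
reflection of its phase sensitivity, not a bug.

## Preprocessing

The band-pass is a type-I (odd-length) linear-phase FIR designed with a
Kaiser window for 50 dB stopband attenuation and a 1 Hz transition centred
on the [1, 40] Hz edges (751 taps at 256 Hz). It is applied
forward-backward (`filtfilt`), which cancels phase distortion — relevant
because tag phase carries information for the cosine features — at the cost
of squaring the magnitude response; that only deepens the stopband and
leaves the passband ripple far below 1 dB. Recordings must exceed three
filter orders. Epochs start exactly at the marker sample, span
N = round(fs·duration) samples, and receive no baseline correction.

The native container is a `.npy` array plus a JSON sidecar (fs, channel
labels, markers); round-trips are bit-exact. EDF import is available when
`mne` is installed. The acquisition montage lists 16 sites without
O1/O2/Oz while features are defined on O1/O2/Oz; the package carries the
19-site union and treats the montage question as open.

## Features

All families use an FFT of length N = 1280 (0.2 Hz bins, no zero padding).
8.57 Hz falls between bins (42.85 bin widths); band membership is decided
purely by bin-center inclusion in the closed interval [n·f̂ − f₀, n·f̂ + f₀],
with no interpolation — deterministic and directly checkable against a
brute-force DFT.

- PSD: channels averaged in the time domain first, then (1/N)|X(f)|² over
  one-sided bins in [1, 40] Hz (196 features).
- Power bank: per channel × tag × harmonic, band power divided by the total
  one-sided power excluding DC. On band-passed input the DC exclusion is
  immaterial; it guarantees ratios in [0, 1] on arbitrary input.
- Cosine correlation: normalized as a Pearson r (bounded, scale-free)
  rather than a raw inner product; only cosine-phase templates are used,
  with time base t = (0..N−1)/fs and phase 0. A zero-variance channel
  yields r = 0 with a warning.

Positive scaling of an epoch leaves power-bank and cosine features
unchanged and scales PSD quadratically; this invariance is property-tested.

## Decoder

`AttentionDecoder` wraps an SVM (scikit-learn `SVC`) behind a
standardization step. Hyperparameters are fixed, logged defaults: C = 1,
polynomial degree 3 with coef0 = 1, RBF gamma = 1/(n_features · var).
attend-Gabor is the positive class everywhere.

`fit(seed)` performs a stratified 80/20 split (48/12 trials on a full
baseline), fits the SVM on the 80 %, fits the Platt sigmoid on the decision
values of the held-out 20 %, and measures stratified five-fold CV accuracy
within the training portion. All splits and folds are seeded; identical
seeds give identical models and probabilities.

Platt calibration maximizes the regularized likelihood with the standard
shifted targets (N₊+1)/(N₊+2) and 1/(N₋+2) via Newton iterations with
backtracking; the solution is verified in tests against an independent
derivative-free optimizer of the same objective. The shifted targets cap
extreme probabilities at (N+1)/(N+2) — with 6 validation trials per class
the cap is 0.875, which is why simulated feedback scores saturate near 0.87
rather than 1.0 even on perfectly separable data. This is a deliberate
property of small-sample calibration, not a fitting failure.

Forward feature selection reads "iteratively adds random features until the
misclassification rate is minimized" as: candidates visited in a seeded
random order each round, the best strict improvement in CV
misclassification joins the bank (ties to the lowest feature index), growth
stops when nothing strictly improves, and the subset with the minimal
observed rate is returned. Folds are held fixed across candidate
evaluations so subsets are compared on equal terms.

`profile_configurations` sweeps the 14-configuration menu (PSD ± FS; power
bank n ∈ {1,2,3} × f₀ ∈ {1.5, 2} plus FS variants at n = 3; cosine
correlation n ∈ {1,2,3} plus FS at n = 3) against the three kernels,
reporting the mean ± SD of participant-level CV accuracies per cell
(fold-level SD for a single participant) and wall-clock training time
(reported only, never asserted — FS cells are an order of magnitude slower,
which is exactly why the deployment rule can exclude them).

## Protocol

Schedules are seeded: face order is permuted per phase; each feedback epoch
samples 10 of the 30 faces without replacement, independently per epoch
(whether the same 10 faces recur across epochs is unspecified in the source
protocol; independent sampling is the choice here). "First vs second half"
of the feedback phase means trials 1–75 vs 76–150 in presentation order.
Inter-trial intervals and feedback display are not modeled; the loop is
strictly offline, scoring each trial from its own epoch only.

## Statistics

- Guttman λ₄ = 2·(1 − (V_odd + V_even)/V_total), where each unit
  (participant) contributes the mean of its odd-position and even-position
  trials, and variances are taken across units (V_total is the variance of
  the summed half-scores). Aggregation by sums instead of means is
  available; with equal half sizes the coefficient is nearly identical.
  The coefficient needs between-unit variance: the reliability test cohort
  gives simulated participants heterogeneous attention contrasts, mirroring
  the stable individual differences the statistic is meant to capture. With
  identical participants the total variance collapses and λ₄ is undefined
  (reported as an error).
- The replication rule is a relative band [ref·(1−tol), ref·(1+tol)],
  tol = 0.10; the reference trivially replicates itself for tol > 0.
- Cohen's d for the baseline contrast is the paired dz = t/√n (consistent
  with the published value); the pooled-SD between-condition variant is not
  used. Identical pairs yield t = 0 (scipy's NaN for zero-variance
  differences is overridden).
- The 2×5 repeated-measures ANOVA uses the classical univariate
  within-subject decomposition (statsmodels `AnovaRM`; an explicit
  sums-of-squares oracle cross-checks it in tests), no sphericity
  correction, and ηp² = F·df₁/(F·df₁ + df₂). With 5 participants the
  design gives Time (1, 4) and Trial / interaction (4, 16) degrees of
  freedom; published F(4,4) notation for the latter two conflicts with
  their published ηp² values, which imply df₂ = 16, so dfs here follow the
  design.
- Acceptability correlations are plain Pearson r per questionnaire item
  (1–5 Likert), no multiplicity correction, undefined (flagged) under zero
  variance.

## Problem sizes and numerics

Simulation-backed tests use a compact 3-channel occipital montage —
identical code paths to the 19-channel default, one sixth the samples.
Cohort-level checks run 5 simulated participants per cohort and two cohorts
for the replication harness; chance-level and monotonicity checks average
20 seeds. Oracle comparisons use 1e-9 (DFT band powers, ANOVA F) or 1e-12
(Pearson, λ₄, ηp² identity) absolute tolerances; Platt agreement with the
reference optimizer is asserted at 1e-6 in probability. Filter attenuation
is measured on FFT band powers after trimming one filter order from each
edge.

## Known limitations

Simulator realism as above; no artifact rejection or re-referencing; no
online/incremental decoding; no CCA-family feature baselines; calibration
quality is bounded by the 12-trial validation split (the Platt cap); the
profiling grid's absolute accuracies on simulation exceed those attainable
on real EEG and should be read only through the relative orderings and
properties the tests assert.
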