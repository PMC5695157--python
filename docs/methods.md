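# Methods

## Model

The decoder is a bank of spatiotemporal LCMV beamformers.  A segment of
multichannel EEG **S** ∈ ℝ^{m×n} (m channels, n samples) is flattened
channel-major (channel 1's n samples, then channel 2's, …) into a row
vector of length mn; this convention is fixed throughout because weight
vectors are only interpretable under one flattening.  Given an activation
pattern **A** ∈ ℝ^{m×n} with **a** = vec(**A**) and the pooled sample
covariance **Σ** of the flattened training segments, the weights

    w = Σ⁻¹ a / (aᵀ Σ⁻¹ a)

solve  min_w wᵀΣw  subject to  aᵀw = 1.  The constraint calibrates the
filter (a segment equal to **A** scores exactly 1); the variance
minimisation suppresses background EEG and the responses of the other
simultaneously presented targets, *to the extent they vary across training
segments*.  The spatial-only form (n = 1) is included and is verified to
coincide with the spatiotemporal formula on single-sample patterns.

The covariance is the unbiased sample covariance (divisor r − 1, mean
subtracted across segments).  The scalar normalisation cancels in the
weight formula, but intermediate quantities stay reproducible.  The
covariance is pooled over *all* training segments — targeted and
non-targeted — because the mn × mn estimate is otherwise hopeless at the
available segment counts (dimension 380–630 versus hundreds to a few
thousand segments).

### Inversion policy

Band-pass filtering confines the data to a small spectral subspace, so the
pooled covariance is routinely rank-deficient at working precision (for
the SSVEP configuration the effective rank is ≈ 60 of 340, with trailing
eigenvalues at 10⁻¹⁵ of the largest).  A plain linear solve on such a
matrix silently amplifies float noise into the weights and destabilises
the off-target beamformer outputs.  The zero-ridge path therefore
eigendecomposes Σ, discards eigenvalues below dim·eps relative to the
largest (the standard numerical-rank convention), and inverts only the
retained eigenspace; results flag this with `used_pinv`.  An absolute
diagonal loading `ridge` is available and is applied at inversion time
only.  If even the pseudo-inverse leaves the constraint direction without
response (an exactly zero covariance), the minimum-norm feasible solution
w = a/(aᵀa) is returned — every feasible vector is then equally optimal.
Constraint residuals |aᵀw − 1| are ≤ 10⁻⁸ on the full-rank path and are
reported on the results object in all cases.

## Paradigm constructions

**P300 (serial highlighting, 9 targets).**  Trials contain 15 highlights
per target at 0.2 s onset asynchrony.  Epochs span [0, 0.6) s after each
highlight onset and are baselined with the mean of the 0.1 s pre-onset
span.  One pattern — mean target epoch minus mean non-target epoch — and
one beamformer are built; the covariance pools all 135 epochs per training
trial.  Per test trial, epochs are averaged per highlighted target and the
beamformer output of each average is that target's score.  At 64 Hz the
epoch has floor(0.6·64) = 38 samples, so the covariance is 380×380.

**SSVEP (flicker, 4 targets at 12/15 Hz × 0/π).**  Per target i, trials
are cut into single-period segments of floor(fs/fᵢ) samples (42 or 34 at
512 Hz → covariance 420 or 340), after discarding the first 120 ms where
the response has not stabilised.  Segment s starts at
floor(skip·fs + s·fs/fᵢ): each segment is aligned to the true period
boundary and the fractional remainder of the period is dropped *per
segment*.  The alternative — strictly consecutive floor-length segments —
accumulates the fractional remainder as a phase drift of
2π(floor(fs/f)·f/fs − 1) per segment; at 12 Hz this attenuates the 59-segment
average of a 5-s trial to 8 % of its amplitude (a Dirichlet-kernel zero)
and measurably *reverses* the accuracy-versus-length trend.  Period
alignment keeps every printed dimension and segment count and restores
monotone behaviour.  The pattern for target i averages the cued-trial
segments; the covariance pools the segments of all training trials cut at
fᵢ's period (a `pool_all_trials=False` switch restricts pooling to cued
trials).

**cVEP (63-bit m-sequence at 120 Hz, 32 targets).**  Targets show lagged
copies of one maximum-length sequence (default taps x⁶+x⁵+1; lags
floor(63·i/32) frames — the interface's lag layout is a modelling choice).
Trials are cut into the maximal number of one-cycle segments of
round(fs·63/120) samples (63 at 120 Hz → covariance 630).  Patterns are
per-target cued-segment averages, estimated independently rather than
derived by circularly shifting a single template; one pooled covariance
serves all 32 beamformers.  Per test trial *all* segments are averaged
once and every beamformer is applied to that single average.

## Decoding and evaluation

The default rule is maximum selection (argmax yᵢ; ties — measure-zero on
real data — break to the lowest index).  Classifier backends over the
feature vector are 1-nearest-neighbour (Euclidean, k configurable), LDA
(default solver), and a linear-kernel SVM (C = 1, one-vs-one multiclass);
all deterministic given the seed.

Cross-validation is stratified by cued target (4 folds for P300, 5 for
SSVEP/cVEP), seeded.  Patterns, covariances and beamformers are fitted per
fold on the *full-length* training trials; test trials are truncated to
each evaluated stimulation length (highlight repetitions, seconds, or code
repetitions) before feature extraction, and classifier backends are
trained on training-trial features extracted at the same length so the
feature distributions match.  A `truncate_training=True` switch instead
truncates training trials too; this was rejected as the default because in
the short-length regime it starves the pooled covariance — for cVEP, four
repetitions give ≈ 640 segments for 630 dimensions, a just-above-full-rank
estimate whose inverse is dominated by noise, and measured accuracy
collapsed below its one-repetition value.  Fold accuracies are pooled
(total correct / total tested) per rule and length.

Rule comparisons use the two-tailed Wilcoxon signed-rank test on paired
accuracies with the Bonferroni-corrected threshold 0.05/6 ≈ 0.0083 (six
pairwise comparisons among four rules).  When all paired differences are
zero the statistic is undefined and the comparison is reported as "no
difference" with the significance flag false.

## Synthetic data generator

Each preset reproduces one study protocol: P300 — 9 targets × 4 cues = 36
trials, 15 highlights per target per trial in per-repetition random
permutations at 0.2 s SOA; SSVEP — 4 targets × 15 cues = 60 trials of 5 s;
cVEP — 32 targets × 5 cues = 160 trials of 10 code repetitions (5.25 s).
Clean responses are: a canonical P300 template (centro-parietal positivity
peaking at 300 ms, ~200 ms wide, plus a smaller occipital negativity at
200 ms) added at cued-target highlight onsets; an occipital sinusoid at the
cued frequency/phase with a 0.15 s onset ramp emulating the unstable
initial response that motivates the 120 ms skip; and the cued lagged code,
frame-expanded and circularly convolved with a short biphasic kernel, on
parieto-occipital channels.  The decoder never sees the scalp maps or
template shapes — they are modelling choices it must not depend on.

Noise is 1/f-amplitude ("pink") by default, matching the colored spectrum
of background EEG; white noise is available for analytic checks.  SNR is
defined as RMS(clean response on its active channels) / RMS(noise on those
channels) over the whole trial, and the default is 0.25: single-trial
evoked responses are a fraction of the background (a few microvolts
against tens).  Generator rates are 256/512/360 Hz (integer multiples of
the 64/512/120 Hz analysis rates).  A seed fixes all randomness;
identical configurations are bit-identical.

What the generator does *not* emulate: volume-conduction mixing of noise
across channels (a mixing matrix hook exists but defaults to identity),
latency/amplitude jitter of single responses, harmonics of the SSVEP
response, eye and muscle artifacts, and between-subject variability.
Passing tests therefore demonstrate the correctness and internal
consistency of the decoding machinery under the stated protocols — not
expected accuracy on real recordings, where templates are noisier and
single-trial SNR varies.  On this synthetic data the decoders saturate
near-perfect accuracy at the default SNR for most stimulation lengths;
the informative dynamic range appears at short lengths and in the cVEP
paradigm (32 classes, accuracy rising from ≈ 0.40 at one code repetition
to ≈ 0.95 at ten).

## Problem sizes and numerical defaults

Simulation-based checks use the preset protocols for training and
generate independent test sessions: ≥ 200 test trials per paradigm for
accuracy end-points, 20 seeds for the accuracy-versus-length trend (with
reduced cue counts per seed), and ~100 test trials per paradigm for the
rule-gap comparison.  Filters are 4th-order Butterworth applied
forward–backward; decimation is anti-aliased FIR in stages of ≤ 10 with
output length floor(n·target/fs).  Epoch windows are half-open with floor
rounding of event times; the continuous data are decimated *before*
epoching (events rescaled by integer division), which keeps epoch geometry
exact — 0.6 s at 64 Hz is 38 samples.  Out-of-bounds epoch windows raise
by default (a lenient mode skips and counts them).  Preprocessing is fully
deterministic.

## Known limitations

- The cVEP target-lag layout and the m-sequence taps of the original
  32-target interface are not public; the evenly spaced default is a
  stand-in with the same code-orthogonality properties.
- Covariance estimation beyond a single ridge term (shrinkage and friends)
  is out of scope; the rank-truncated pseudo-inverse is a numerical
  safeguard, not a tuned estimator.
- Decoding is synchronous only: trials must be time-locked to stimulation
  onset.  No sliding-window/asynchronous mode is provided.
- Recordings are read from the package's plain-text session format;
  BDF/EDF ingestion is left to external converters.
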