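# Methods

This note documents the models, parameter choices, numerical conventions and
known limitations of `tactile2p`. It is the design record for maintainers;
empirical claims here are limited to what the test suite and
`scripts/acceptance.py` actually compute.

## Task model

The pipeline assumes a head-fixed Go/No-Go vibrotactile detection task.
Sessions contain pseudorandomized trials; Go trials deliver a 500-ms sinusoid
at one of several amplitudes and open a 2-s response window in which a lick
is rewarded (Hit) or withheld (Miss); No-Go (catch) trials deliver no
stimulus, and licks are false alarms. A small fraction of Go trials is
cancelled by pre-stimulus licking (timeouts); these carry no stimulus and are
excluded from Hit-rate denominators, with their fraction reported as the
spontaneous-licking rate. Testing sessions default to 300 trials, a 90:10
Go:No-Go ratio and six amplitudes (2–12 µm at 10 Hz); training sessions use
75:25 with a single 15-µm, 40-Hz stimulus.

## Behavioral statistics

- **Psychometric fit**: binomial GLM with logit link of Hit counts on
  amplitude (statsmodels). No lapse/guess parameters — the fit has two
  degrees of freedom, matching the sigmoid-inflection threshold definition
  `a₅₀ = −β₀/β₁`. Perceptual accuracy is the maximum derivative of the
  fitted curve, `β₁/4`. Degenerate data (all rates ≈0 or ≈1, or β₁ ≤ 0)
  yield an undefined-threshold flag rather than an extrapolated number.
  Perfect separation is detected via the linear predictor saturating
  (|η| > 30 at observed amplitudes) and triggers an L2-regularized refit
  (`alpha = 1e-3`), flagged in the result.
- **Criterion c′** uses normal quantiles of Hit and FA rates clipped to
  [1/(2n), 1 − 1/(2n)] — the standard correction for extreme rates; equal
  quantiles (hit = fa) are flagged undefined instead of dividing by zero.
- **Trial-by-trial variability** is the population (ddof = 0) variance of the
  Hit indicator per amplitude, so every value respects the Bernoulli bound
  p(1−p) ≤ 0.25. The normalized triplet reads the profile at the nearest
  delivered amplitudes to threshold − 2, threshold, threshold + 2 µm.
- **Subgrouping**: scikit-learn k-means, k = 2, `n_init = 10`, fixed seed.
  The cluster with the lower mean hit rate is labelled hyposensitive-like.
  Identical profiles make the partition degenerate; flagged, not raised.
- **Learning criteria**: 3-day rolling means; training passes at ≥ 80% Hits
  and < 30% FAs, pre-training at ≥ 80% Hits and < 40% spontaneous licking.
  The thresholds are arguments, so stricter or looser conventions (e.g. a
  70% Hit criterion) are one keyword away.

## Fluorescence processing

- Neuropil correction `F − 0.7·F_neu` (coefficient configurable).
- Baseline per neuron: sliding 10-s window (stride 1 frame), the window with
  the lowest SD wins, ties go to the earliest window; baseline = that
  window's mean. Non-positive baselines exclude the neuron (flagged).
- z-scores use µ and σ of the *pooled* 1-s pre-stimulus frames across all
  alignable trials, per neuron — one scale per neuron per session. σ = 0
  flags the neuron as constant and excludes it.
- Window geometry at 30.96 Hz: 31 pre + 15 stim + 15 post frames, half-open
  intervals, onset frame = first frame at/after onset time (0-based).
- The validity mask goes False from the first-lick frame onward; trials with
  fewer than 2 valid stimulation frames are flagged and excluded from
  stimulus-window statistics. No downstream statistic reads masked frames.
- Savitzky–Golay smoothing (window 10, order 3) exists for display only and
  feeds nothing.

## Recruitment test

Per neuron, the null distribution is built once per session from 1,999
frames sampled uniformly without replacement from frames outside stimulus
periods and outside the 2-s post-stimulus response window of rewarded
trials. One frame sample is shared across neurons, since eligibility is a
property of the recording. A neuron-trial is activated when the 85th
percentile of its valid stimulation-window z exceeds the null's 95th
percentile. For inhibition the implemented default compares the 10th
stimulus percentile against the null's **5th** percentile — the symmetric,
two-sided-p < 0.05 reading. A literal mode comparing against the 95th
percentile is provided (`inhibition_mode="literal"`), but note it labels
nearly every quiescent neuron-trial inhibited and is retained only for
comparability. When both rules fire, the larger percentile exceedance wins;
exact ties yield 0, so labels are strictly trinary.

On signal-free standard-normal inputs the activation rule fires on ~3.6% of
neuron-trials and the inhibition rule on ~9% (the 85th percentile of 15
frames is a noisier statistic than a single draw, and the 10th percentile of
15 frames sits low); these rates are pinned as regression values in the test
suite with ±2 Monte-Carlo SE tolerances.

`d′` between detected and non-detected trials uses the per-trial mean valid
stimulation-window z and the equal-weight pooled-SD form
`(µ_det − µ_non)/√((v_det + v_non)/2)`; classes need ≥ 2 trials each and
positive pooled variance.

## Population statistics

Catch-trial analysis windows sit at the scheduled (sham) stimulus time of
each No-Go trial, giving stimulus-free windows with identical geometry.
All-zero trinary vectors have no direction and are excluded from cosine
means (count reported) rather than counted as 0, which would dilute
coordination estimates. E/I ratios with zero activated interneurons are
excluded and counted, not clamped. Condition aggregates are computed per
animal first; the animal is the statistical unit.

## Decoding

Features are raw ΔF/F values, one scalar per neuron per frame (a z-scored
variant is a flag away). Undersampling to the minority class happens once
per session before fold assignment. Outer 4-fold stratified CV is shared
across frames; the inner 3-fold stratified search selects C per outer fold
from {1e-4, 1e-3, 1e-2, 1e-1, 1} without touching outer test data. Reported
per frame from pooled outer-fold predictions: overall accuracy,
`P(pred Hit | Hit)` and `P(pred Hit | Miss)`. Chance curves rerun the
identical pipeline with training labels permuted within each outer fold.
Window averages cover round(duration × frame rate) frames — 15 frames for
0–500 ms, 6 for −200–0 ms. Degenerate training folds (one class or zero
feature variance) fall back to majority-class prediction.

Cross-validated accuracy under permuted labels has a small pessimistic bias
at small n (the classifier anti-generalizes fold-specific noise), so chance
estimates based on a single permutation are noisy and slightly below 0.5.
The acceptance script therefore averages 48 independent permutation runs on
a ~150-trial balanced session, which centers the estimate on 0.5 with a
Monte-Carlo SE well under the ±0.05 tolerance.

## Synthetic generator

The generator emulates the statistical structure the analysis assumes, not
the biophysics of any real recording:

- **Behavior**: `P(lick | a) = (1 − lapse)·σ(slope·(a − threshold))`,
  default lapse 0 so generator and fitter share a model family; No-Go licks
  at a fixed FA rate (default 0.15); first licks uniform on
  [onset + 0.1 s, onset + 2 s], so a realistic share of licks falls inside
  the 500-ms stimulation window and exercises the masking path.
- **Recruitment**: per trial and neuron, Bernoulli with
  `p = p_catch + (p_max − p_catch)·σ((a − a_n)/w)`, halved on non-detected
  trials; catch trials recruit at `p_catch = 0.05`. Defaults:
  `p_max = 0.35`, `a_n = 4 µm`, `w = 2 µm`.
- **Transients**: instantaneous rise, single-exponential decay with
  τ = 0.2 s (fast-indicator regime), amplitude scaled by stimulus amplitude
  and per-neuron lognormal gains; latency 40 ms ± 20 ms jitter. A fixed 15%
  of cells respond with negative-going transients.
- **Shared gain**: a unit-variance Gaussian process low-passed at ~1 Hz,
  loading set by `shared_gain_loading`; this is what pairwise cosine
  similarity picks up beyond stimulus-locked coincidence.
- **Neuropil**: `F_neu` carries a common contaminant plus independent noise,
  and `F` carries 0.7 × the contaminant, so `F − 0.7·F_neu` removes it in
  expectation by construction.
- **Hyposensitive-like preset**: +4 µm behavioral and neural threshold,
  ×0.6 recruitment ceiling and evoked gain, +60 ms latency, ×0.5 shared
  gain. These encode the *direction* of group contrasts, not magnitudes —
  no quantitative generative model of real cortical data is claimed.

What passing tests on this generator show: the pipeline recovers parameters
it is pointed at (thresholds to ±0.5 µm at 600+ trials, recruitment
probabilities to ~3 SE, subgroup labels at ≥ 95% under 0.3 hit-rate
separation) and orders groups correctly under directional contrasts. What
they do not show: robustness to motion artifacts, slow drift, spike-to-
calcium nonlinearity, overlapping ROIs or non-stationary behavior, none of
which the generator produces.

## Problem sizes and determinism

Tests and the acceptance script use compact study conditions chosen to keep
statistical power while staying lightweight: sessions of 50–160 trials,
25–60 neurons, cohorts of ≤ 5 mice per group and 10 replicates for the
directional-contrast check. All randomness flows from explicitly passed
`numpy.random.Generator` objects; cohort generation spawns one child stream
per mouse from a single `SeedSequence`, so results are reproducible from
config + seed and invariant to analysis order.

## Known limitations

- The literal inhibition comparator is implemented but statistically
  degenerate (see above); cross-study comparisons should state which rule
  they used.
- The psychometric fit pools trials; averaging session-level fits is not
  implemented.
- Population SNR is undefined for sessions whose catch trials recruit
  nothing; the add-one smoothing alternative is config-gated but off by
  default.
- The decoder reports pooled-prediction rates; fold-averaged rates can
  differ slightly at small n.
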