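# Methods

This note documents the models, conventions and design choices behind
`wearadetect`: what the synthetic generator emulates, how each feature
is defined, the numerical conventions the implementation fixes where
the underlying method descriptions leave them open, and what the test
suite's results do and do not establish about real wearable data.

## The synthetic cohort generator

The generator produces two classes of subjects — DM (label 1) and
no-DM-DX (label 0) — over a default calendar span of 2020-04-22 up to,
exclusively, 2020-08-29 (129 nights; the inclusive span is 130 days and
the final date is treated as exclusive to honour the 129-night
denominator used for completeness).

**Scalar summaries.** Nightly heart rate, RMSSD, total sleep time and
diurnal distal-temperature amplitude follow truncated-normal marginals
(truncation at zero) with per-class location/scale defaults equal to
the published class moments:

| feature | no-DM-DX (loc, scale) | DM (loc, scale) |
|---|---|---|
| HR (BPM) | 62.713, 8.852 | 67.819, 9.569 |
| RMSSD (ms) | 42.944, 24.973 | 30.141, 17.180 |
| TST (h) | 7.946, 1.726 | 7.649, 1.990 |
| amplitude (°C) | 7.261, 2.848 | 6.008, 2.438 |

Each nightly value decomposes as class location + subject random effect
+ night noise, with `subject_effect_fraction` (default 0.35) of the
variance persistent at the subject level. The marginal distribution is
unchanged by this split; what it adds is within-subject correlation
across nights, which is what makes multi-night windows more informative
than single nights. The nominal between-class Cohen's *d* implied by
the configured moments (pooled-SD formula) is ≈ 0.575 for HR; the
published *d* of 0.607 is not recoverable from the published moments
under standard pooled-SD formulas, so the generator targets its own
nominal effect, not the printed one.

**Hypnograms.** 30-s epochs in {wake, light, deep, REM} spanning the
sleep episode (onset to final wake onset, so the hypnogram begins and
ends asleep). Sleep bouts terminate with a per-epoch fragmentation
hazard (default 0.005 control / 0.009 DM); wake bouts are typically
~1 min, but with a per-class probability a wake bout is a long
(≥ 60 min) gap that splits the night into detached sleep spans — the
insomnia-like phenotype the secondary sleep features are designed to
see. A log-normal subject-level multiplier (log-SD 0.5) plus nightly
jitter keeps the per-night fragmentation effect size moderate
(d ≈ 0.4–0.6) rather than trivially separable.

**Temperature.** Each 24-h day is anchored at noon so one sleep episode
sits wholly inside one day (the day boundary is a package convention;
the source describes none). The series is a baseline (33 °C) plus a
sinusoid of peak-to-trough range equal to the night's amplitude draw,
peaking mid-sleep (distal temperature rises at night), plus stationary
AR(1) noise. The noise autocorrelation differs by class (0.86 control
vs 0.93 DM, with subject-level SD 0.04): smoother DM noise yields lower
complexity indices, encoding the hypothesis that autonomic dysfunction
flattens the fine structure of nocturnal thermoregulation. With zero
noise the realised max − min equals the drawn amplitude exactly, which
the tests exploit.

**Missingness** is per-night independent Bernoulli (default 0.35,
matching the published 60–66 % completeness range); there is no
informative-missingness model because none is described. **Chronic
conditions**: a configurable fraction (default 0.2) of control subjects
carries another chronic condition, shifting their HR/HRV/sleep
parameters halfway toward DM values while leaving temperature
parameters untouched — encoding the finding that temperature features
differentiate DM from other chronic conditions. **Label noise**: a
fraction (default 0.1) of DM-labelled subjects is generated from
control physiology, emulating self-report noise and supplying the
false-negative population the profiling analysis studies.

All randomness flows from one root seed through per-subject child
streams, so cohort composition is invariant to subject ordering and
identical configurations produce byte-identical output files.

## Feature definitions and numerical conventions

**Sleep windows.** Long windows are contiguous-sleep spans > 6 h, short
windows < 3 h; spans of 3–6 h are classified `other` and counted in
neither aggregate (the source is silent on them). The two published
rules — internal wake runs ≤ 10 min, windows separated by ≥ 60 min of
wake — contradict each other for wake runs of 10–60 min; the default
resolves in favour of the separation rule (such gaps are absorbed into
one window, counted as wake time), and a strict mode splits at any
wake run > 10 min instead. `sleep_percentage` defaults to
sleep/(sleep+wake) — the literal "sleep divided by wake" reading is a
ratio, not a percentage, and is available behind a switch.
`wake_up_count` (wake runs inside the sleep period), `got_up_count`
(wake runs ≥ 5 min), `restless` (transitions into wake) and
`onset_latency` (constant 0 in synthetic data) are surrogates for
proprietary device summaries and are named as such.

**Percentile filter.** Per 24-h period, values strictly below the 5th
or strictly above the 95th percentile are discarded before the diurnal
metrics. Percentiles use linear interpolation between order statistics
(no method is named in the source; the choice is recorded here and in
output metadata). Nights with fewer than 20 valid minutes yield null
temperature features.

**Complexity.** The complexity index z-scores with the population SD
and normalises by the length of the (grained) series being scored —
both unstated in the source and fixed here. Zero-variance series have
CI 0 by convention; series shorter than 2 are null. The 256-minute
block is strictly centred on the sleep-episode midpoint (128 minutes
each side); if missingness or a short night intrudes, the features are
null rather than the block shifting toward onset/offset, whose variance
the features deliberately avoid. The block is taken from the
*unfiltered* series: the percentile filter removes ~10 % of in-sleep
minutes and would void the contiguity requirement on essentially every
night. Coarse-graining uses block means of width 2^s with the trailing
remainder dropped.

**Baseline deviations.** `temperature_deviation` is the night's mean
filtered temperature minus the subject's trailing 30-night baseline
(preceding nights only; null before any baseline exists);
`temperature_trend_deviation` subtracts its own trailing 3-night moving
average. Both are surrogates for proprietary summaries.

## Windowing and evaluation protocol

Window quality caps are 0/2/2/4/6 missing nights for L = 1/3/7/14/21,
plus at most 2 missing in every aligned, non-overlapping 7-night block
from the window start (the sliding-week reading would be stricter than
the stated per-length caps and is rejected). Valid 21-night start dates
anchor all other lengths. With missing nights present, a shorter
window at an anchor can fail its own cap, so each length's key set is a
subset of the anchor set; the sets coincide exactly when no nights are
missing. Windows are flattened night-major (night 1's 36 features,
then night 2's, ...), and the layout is recorded so importance
aggregation can invert it.

Splits are subject-disjoint, stratified by (label, age bin); 3-fold
hyperparameter cross-validation groups folds by subject — not stated in
the source protocol, but required to prevent overlapping windows of one
person straddling a fold boundary. The scaler is standardisation fit
on observed training cells only; zero-filling afterwards is sensible
precisely because 0 is then the training mean.

The imbalanced protocol keeps the DM pool whole, resamples controls
age/sex-balanced to the DM pool's strata (proportional allocation,
largest-remainder rounding) to a 17.9 % subject prevalence, samples 10
windows per subject (with replacement only when a subject has fewer),
and summarises 100 repetitions by pointwise medians and 25–75 % bands
on fixed 101-point FPR/recall grids (the source shades IQR without
stating an interpolation rule). Score ties are handled by thresholding
at unique scores with ≥ predictions.

**Ablation.** All 31 nonempty combinations of the five feature sets are
retrained (columns removed, not zeroed); orderings collapse to
combinations because model output depends only on the feature set. The
marginal gain of a set is the mean over the 16 subsets of the other
four sets of the AUROC difference, with the empty prefix scored at
chance (0.5) — a featureless model is chance, and the baseline for the
empty prefix is otherwise undefined. Importances are normalised to sum
to 1, which makes the sum-vs-average-over-nights distinction immaterial
to ranking.

**Statistics.** Cohen's *d* uses the pooled-SD denominator without
small-sample correction. Dunn's posthoc test is implemented in-package
(pooled mid-ranks, tie correction, two-sided normal p-values) and
verified against an independent brute-force implementation;
Benjamini–Hochberg adjustment comes from statsmodels. The commonly
used features are quantile-filtered before population testing (HR
outside 5/95 %, RMSSD above 98 %, TST outside 1/99 %; amplitude
unfiltered).

## Problem sizes

The default study-scale cohort is 120 subjects per class over 129
nights, chosen so that the full pipeline (simulation, extraction,
five window lengths × two families, 100-repetition imbalanced
protocol) completes in about a minute on one CPU while keeping enough
training subjects for the gradient-boosted trees to generalise: with
substantially fewer subjects the trees memorise subject identity
through the ~100 highly correlated windows each subject contributes,
and held-out performance degrades with window length — an artifact of
cohort size, not of the method. Unit and property tests use 12–16
subjects per class over 40–50 nights. Marginal-distribution recovery
checks use 10,000 i.i.d. nightly draws.

## What the synthetic results do and do not show

Passing tests establish that every pipeline stage implements its
stated contract, that the metrics agree with independent oracles and
closed forms, and that the pipeline recovers the structure the
generator plants — including the qualitative findings: performance
rises with window length, the imbalanced-protocol median AUROC tracks
the balanced AUROC, temperature features carry DM-specific signal, and
missed DM subjects look like controls. They do not establish
real-data performance: the generator draws independent truncated
normals with a single variance split and has no seasonality, weekday
structure, menstrual cycles, device artifacts, geography/climate
effects or informative missingness, and its class separations are
configured, not discovered. Absolute AUROC values on synthetic
cohorts therefore exceed what heterogeneous real populations yield and
should be read as pipeline verification, not as clinical performance.

## Known limitations

* Proprietary device summaries (Sets 1, 2, 4) are emulated by
  surrogates; their real counterparts come from undisclosed algorithms.
* The generator's hypnograms use a simple semi-Markov bout model; stage
  architecture (REM cycling, deep-sleep decline across the night) is
  not realistic and stage-specific features beyond the RMSSD
  passthrough should not be derived from it.
* No probability calibration, cost-sensitive thresholding, deep
  learning models, or per-condition subgroup analysis beyond the pooled
  "other chronic condition" group.
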