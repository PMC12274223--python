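# Methods

This note documents the models, parameter choices and numerical conventions
behind `atas`, and what the synthetic-data tests do and do not establish
about real recordings.

## Event detection model

The detector treats a preprocessed recording as a binary process in time —
speech is being produced or it is not — and estimates the change points with
two short-time features on a 50-ms window / 1-ms hop grid:

* **RMSE** (sqrt of the mean squared amplitude in the window), compared
  against the mean RMSE of the surrounding 3-s segment. The per-segment mean
  makes the threshold adaptive to slow loudness drift and independent of the
  overall recording level.
* **ZCR**, counted as *strict* sign changes: `sign(0) = 0` and a transition
  into or out of an exact zero never counts. With this convention gated
  silence has ZCR exactly 0, which is the property the labeling rule relies
  on. (An alternative printed form of the ZCR applies a square root to the
  averaged absolute sign differences; since every decision in the pipeline
  reduces to zero vs non-zero ZCR, any monotone transform is immaterial and
  the raw crossing count is computed.)

A frame is non-silent when RMSE is above the segment mean *and* ZCR is
non-zero, silent when RMSE is below the mean *and* ZCR is zero; frames
matching neither conjunction — including RMSE exactly at the mean — are
resolved by ZCR alone. RMSE comparisons are strict, so ties fall into the
ambiguity rule. In practice the composite rule coincides with the ZCR
criterion, but the full conjunctions are implemented and tested as stated.

**Frame grid and segment boundaries.** Frames are emitted wherever the full
50-ms window fits inside the *signal* (no padding: padded windows distort
RMSE at the edges). The 3-s segmentation defines only the blocks over which
the adaptive mean-RMSE threshold is computed; same-label runs are merged
across segment boundaries before temporal thresholding, so an event
straddling a boundary is never split. A trailing remainder shorter than one
window is merged into the previous segment and the segment's own mean is
used.

**Region boundaries.** A window is silent only when it lies entirely inside
silence, so a run of silent frames under-covers the true silent stretch by
(window − hop) at its right edge. After run-length encoding, each
silent→non-silent boundary is therefore shifted right by (window − hop) and
the final region is extended to the end of the analyzed span. On clean
synthetic audio this makes region edges exact to the hop grid (±1 ms);
non-silent runs squeezed to non-positive length by the shift (isolated
glitch frames) are dropped and their silent neighbours merged.

**Temporal thresholds.** Silent regions ≥ 50 ms become pauses; non-silent
regions > 100 ms become vocal events; sub-threshold regions are absorbed
leftward into the running event (a sub-threshold prefix merges rightward
into the first event). Absorption is deterministic and order-independent
under sequence reversal, which the suite checks by enumeration. Pauses of
50–150 ms are *short* (the 150-ms boundary is inclusive to short, because
*long* is strictly "> 150 ms"); longer pauses are *long*. Threshold
comparisons on float durations carry a 1e-6-ms tolerance so grid-exact
durations are classified stably.

Degenerate recordings (all silent, all voiced) yield a single event; metric
statistics over empty subsets are emitted as missing, never zero.

## Noise reduction

Spectral gating with a two-stage design:

1. STFT (Hann 256, hop 64); bins whose magnitude does not exceed the
   per-frequency noise threshold (profile mean + 1.5 SD) are attenuated by
   the gate strength (default 1.0 = gated to zero), with a 3×3 smoothing of
   the binary mask to limit musical noise.
2. A time-domain squelch zeroes stretches whose 5-ms peak envelope stays
   below 1.5× the noise-profile RMS.

The squelch is what guarantees the detector's "silence has ZCR = 0"
premise: ISTFT reconstruction alone always leaves a low-level residue whose
sign fluctuates. The noise-only profile, when not supplied, is detected
automatically as the concatenation of the lowest-energy 50-ms frames (up to
500 ms total) whose energy is within 4× of the quietest frame — scattered
frames rather than one contiguous window, so the profile stays noise-only
even when no single silence is long.

These gating parameters (FFT size, threshold SDs, squelch factor) are
package choices; they are exposed as module constants and validated by the
contract tests (silent-interval RMS reduced > 90%, voiced-interval RMS
preserved ≥ 80% under a 4:1 speech-to-noise amplitude ratio), not asserted
against any external reference.

## Fluency metrics

Speech rate divides the passage word count (236 by default) by the full
trimmed recording duration — vocal *plus* pause time. With the word count
fixed by the passage, this gross rate is the quantity through which
increased pausing (rather than slower articulation) lowers the rate; the
alternative denominator (speaking time minus pauses) is available by passing
`duration_s` explicitly. Variability metrics are coefficients of variation
with the sample (n−1) standard deviation, chosen because event counts per
recording are small; CVs are unit-invariant and require n ≥ 2 (missing
otherwise).

## Cohort statistics

Reference levels are AWNS (group) and female (sex); the group coefficient is
the AWS-minus-AWNS difference. Assumption checks at α = .05 drive the model
plan:

* Shapiro–Wilk per metric; if rejected and all values are positive, the log
  transform is applied and re-tested. A metric fixed by the log transform is
  modeled as Gaussian on the log scale; a positive metric *not* fixed by it
  is assigned the gamma family with log link (positive support,
  multiplicative group effects).
* Breusch–Pagan (LM = n·R² of the squared-residual auxiliary regression,
  chi-square with p degrees of freedom) flags a metric for weighting.
  "Weighted" fits use inverse-fitted-variance weights from a one-pass
  log-linear regression of squared OLS residuals on the predictors — the
  standard remedy matching the diagnosis; the scheme is deliberately
  non-iterated to keep it deterministic and transparent. Note the test's
  power at n = 35 is modest (the auxiliary R² is bounded near 1/3 for
  Gaussian errors), which the suite documents by measuring power at n = 35
  and n = 200.
* Counts are checked for overdispersion with the Pearson dispersion
  (chi-square/df of a Poisson fit) plus the Cameron–Trivedi auxiliary
  regression of ((y−μ)² − y)/μ on μ without intercept (one-sided t on the
  slope, which is itself a moment estimate of the NB2 α). Overdispersed
  counts get the NB2 negative binomial, whose α is estimated by maximum
  likelihood with a standard error; non-overdispersed counts fall back to
  Gaussian.

Group p-values across the 13 metrics are corrected with the
Benjamini–Hochberg step-up procedure at q = 0.1 (implemented directly and
cross-checked against an independent brute-force restatement and against
statsmodels). %SS correlations are Pearson, computed both over all rows with
%SS defined and over AWS rows only, labeled — which rows enter the battery
is a genuine design fork, so both variants are reported. Missing metric
values are dropped listwise per metric, never imputed.

## Classifiers

* Decision tree on all 13 metrics; random forest (100 trees) on the 7
  group-separating metrics (speech rate, total pause time, pause count, mean
  pause duration, vocal duration variability, mean short pause duration,
  long pause count). Validation: 10 repetitions of stratified 80/20
  resampling plus stratified 3-fold cross-validation, all driven by one
  explicit seed; "3-fold leave-one-out" is internally contradictory, so
  stratified 3-fold is the implemented reading.
* Sequence classifier: recordings are assigned to train/test/validation
  (29/4/2 proportions, stratified by group) *before* windowing; each
  recording is cut into non-overlapping windows of 20 consecutive events
  with 9 features per event (the 7 recording-level metrics, an event-type
  code — vocal = 1, short pause = −0.5, long pause = −1 — and the event
  duration in ms). Features are z-scored with training-set statistics only;
  training windows are augmented by circular rotation of the event order
  (shifts 5, 10, 15; a shift of 20 is the identity and excluded). Windows
  are classified by a multilayer perceptron (one hidden layer of 64 units)
  on the flattened 20×9 block, and window predictions aggregate to a
  recording prediction by majority vote with ties resolved toward AWS, the
  clinically conservative direction. Accuracy and F1 (AWS positive) are
  reported per split over 5 recording-level splits.

The no-leakage property (normalization, augmentation and feature selection
strictly inside training folds) is asserted by perturbing held-out rows and
checking that training-fold tensors and statistics are bit-identical.

## Synthetic data

`make_synthetic_utterance` renders an alternating voiced/silent plan:
voiced intervals are 440-Hz tone bursts by default (ZCR analytically
predictable: ≈ 2·f·window) or sign-alternating noise bursts (a crossing
between every sample pair, making detected region edges exact on the
millisecond grid — used for short/long boundary cases). 5-ms raised-cosine
ramps sit *inside* each voiced interval, so the exact interval edges are the
ground-truth boundaries; ambient noise is uniform with the constraint that
voiced amplitude exceed 4× the noise amplitude (the detectability guarantee
the recovery tests rely on). Ground truth is produced by running the
detector's own temporal thresholding on the exact intervals, so
sub-threshold intervals are absorbed identically.

`make_synthetic_cohort` has two modes:

* **table** — each metric drawn from its group's marginal: truncated normal
  for continuous metrics (bounds: rates > 0, CVs > 0, means above their
  subtype thresholds, short-pause means inside [50, 150] ms), with location
  and scale solved numerically so the *truncated* distribution hits the
  target mean and SD (without this, a marginal like AWS total pause time,
  30.68 ± 22.40 s truncated at 0, would come out ~3 s high); negative
  binomial for the counts at the published dispersion scale (α 0.18 long /
  0.13 short), with pause count = long + short by construction. Ages use
  plain truncation to the published ranges (their published mean/SD/range
  are jointly infeasible for a moment-matched truncated normal).
* **mechanistic** — an event sequence is generated per participant
  (negative-binomial pause counts; log-normal long-pause and vocal
  durations at the group mean/CV; truncated-normal short pauses on
  [50, 150] ms; pauses interleaved in random order between vocals) and the
  metrics are *computed* from it. This induces realistic within-participant
  correlations (e.g. speech rate falls mechanically as pausing rises) and
  provides the event sequences the sequence classifier needs. Its marginal
  means consequently drift from the table moments for derived quantities
  like speech rate — that is the point of the mode, not an error.

%SS is generated for AWS rows as 1.0 + 0.09 × long-pause count + N(0, 1.5),
clipped to [0, 100]: a single-driver linear model chosen to put the
long-pause-count association at the r ≈ .85–.9 scale. AWNS rows have %SS
missing by default.

**What the synthetic tests show — and don't.** Passing recovery tests show
the detector implements its stated rules exactly and is robust to stationary
ambient noise at a 4:1 amplitude ratio. They do not show robustness to
non-stationary noise, reverberation, breath noise, or the spectral
complexity of real speech (formants, voiced/unvoiced consonant structure);
fixtures model temporal structure only. Likewise the cohort generators
reproduce group *moments*, not the full joint distribution of real AWS/AWNS
metrics, so classifier accuracies on synthetic cohorts calibrate the
pipeline's mechanics, not clinical performance.

## Problem sizes and seeds

The suite's simulation tests use 500 replicates for GLM
recovery/uniformity, 2000 for the assumption-check calibrations, 50 seeds
for classifier sanity, and 100 random utterances for event recovery —
sizes at which the measured rates have standard errors comfortably inside
the asserted tolerances. `scripts/acceptance.py` uses 30 utterances and 100
cohort replicates and finishes in well under a minute; every random draw
derives from the single `--seed` argument.

## Known limitations

* No word/phoneme alignment, no disfluency-type labeling, and no
  filled-pause vs silent-pause discrimination: a filled pause ("um") is a
  vocal event by construction.
* The detector assumes stationary ambient noise; the gate has no mechanism
  for impulsive or speech-like interference.
* No resampling is performed; all time parameters are converted to samples
  per file, so recordings below 8 kHz are rejected rather than upsampled.
* The weighted-GLM weighting scheme and the spectral-gate parameters are
  reasonable defaults, not estimated quantities; both are configurable.
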