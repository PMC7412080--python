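# Methods

## Problem and approach

Wearable-sensor activity recognition pipelines are usually built and
evaluated on clean, gap-free accelerometer streams, but field deployments
(care homes, wireless sensor networks) lose samples routinely. `actigap`
studies classification under *missing-at-random* (MAR) data loss and
implements a deliberately imputation-free remedy: induce the same
percentage of random missingness in the **training** stream that the model
will face at test time, so the classifier learns the feature distribution
of corrupted windows directly. The pipeline is

1. raw series → MAR masking (whole rows, `NA` on disk, an explicit flag in
   memory),
2. overlapping fixed-duration windows (timestamp-driven, half-open
   intervals),
3. seven statistics per axis over each window's *valid* rows only,
4. SVM-RBF or 500-tree random-forest classification on the feature table.

## The MAR mechanism

A mask of exactly `round(rate × n)` row indices (banker's rounding) is
drawn uniformly without replacement; a masked timestep loses all channels
at once, and timestamps are retained. Formally the masking probability
given the observed data does not depend on the masked values,
`P(r | D_obs, D_miss) = P(r | D_obs)`; the unit tests verify this
empirically (no positional trend by chi-square; no correlation between
masking and signal amplitude). Gaps longer than 5 nominal periods are
treated as outages, a different loss mechanism, and excluded from MAR
ratios in the timestamp-gap diagnostics.

The gap diagnostics (`gap_histogram`) invert the mechanism from received
timestamps alone: on a stream with nominal period `p` (default jitter
tolerance `0.1 p`), an inter-sample gap of `k·p` implies `k−1` consecutive
missing samples; the per-bin and overall missing ratios follow as
`implied_missing / (received + implied_missing)`.

## Features (the 21-statistic table)

Per axis: mean, variance, skewness, kurtosis, max, min, MAD — 21 columns
for tri-axial input, ordered statistic-major (mean-x, mean-y, mean-z,
var-x, …). Conventions are followed exactly as defined, even where they
mix divisors:

* variance is the population form (divide by `n`);
* skewness and kurtosis are the adjusted sample forms
  (`n/((n−1)(n−2)) Σ z³` and
  `n(n+1)/((n−1)(n−2)(n−3)) Σ z⁴ − 3(n−1)²/((n−2)(n−3))`) with
  `z = (x−x̄)/S`, `S` the `n−1` standard deviation;
* MAD is the **mean** absolute deviation about the median, `Σ|x_i − M|/n`
  — the definition used here, despite the customary reading of the
  acronym. The plain median is available as an optional extra column, off
  by default.

Every statistic is computed over the valid rows only; the module's core
contract (tested exhaustively) is *masking equivalence*: the features of a
masked window equal those of the explicitly subsetted valid subsequence,
bit for bit. A statistic whose preconditions fail (fewer than 3/4 samples
for skewness/kurtosis, zero spread, fewer than `min_valid_samples = 4`
valid rows in the window) is flagged undefined. Undefined entries are
filled, just before classification, with the per-feature **training-set**
median, computed once and frozen — no test-set leakage and no raw-signal
imputation; the policy only keeps feature matrices rectangular.

## Windowing

Windows are `[start, start + window_s)` anchored at the recording's first
timestamp and advanced by `slide_s` (default `window_s/2`). The window
count follows `floor((T − window_s)/slide_s) + 1` with
`T = t_last − t_first + p` (`p` the nominal sample period), so a 20 s
recording with 2 s windows sliding by 1 s yields 19 windows. Segmentation
is timestamp-driven — identical physical boundaries at any sampling rate —
and never crosses recording boundaries. Window labels are the modal
per-row label, ties broken by earliest appearance, deterministically.

## Classifiers

* SVM with RBF kernel: features standardized with training-set statistics
  only, `C = 1`, `gamma = 1/(n_features · Var)` ("scale").
* Random forest: 500 trees, `sqrt(n_features)` candidate features per
  split (the classification default of the Breiman algorithm); 500 trees is
  enough for stable out-of-bag behaviour on feature tables of this size.

Both are deterministic given their seed. For real datasets,
leave-one-person-out cross-validation splits are provided (one fold per
subject); for the single-chest data a stratified window-level split is a
configurable alternative, since no protocol is canonical there.

## The synthetic three-waveform experiment

Three periodic classes — sine, sawtooth, square — each contribute 400
samples (1200 total), generated at 50 Hz with frequency 1 Hz, amplitude 1
and additive Gaussian noise of sd 0.05. 80% of each class forms one
training sequence; the remaining 20% forms an independent test sequence
with its own noise seed. The experiment windows these sequences at 0.3 s
with a 0.1 s slide.

These choices are the package's operating point for the simulated study,
picked once, by construction rather than by sweep, to realize the
qualitative regime the experiment is meant to probe:

* **Clean separability.** On clean data the three classes are perfectly
  separable on windowed variance/kurtosis (asserted as an invariant), so
  clean-train/clean-test accuracy is 100% and any degradation is
  attributable to missingness.
* **Sensitivity to missingness.** Sub-period windows (0.3 of a waveform
  period, 15 samples) make the windowed statistics phase-dependent and
  leave few enough samples per window that deleting rows visibly perturbs
  the statistics; with full-period windows the statistics are nearly
  invariant to subsampling and the effect under study disappears.
* **Learnability.** The dense slide gives the training side many windows
  (and many distinct local mask realizations), so a model trained on
  masked data can actually learn the corrupted feature distribution.

Under this operating point the traditional protocol (clean train, masked
test) degrades steadily with the missing rate and collapses beyond ~60%
missingness, while the proposed protocol (both sides masked at the same
rate, independent masks) stays above it at every rate — the protocol
ordering and the degradation trend are asserted statistically in the test
suite (one-sided paired tests over ≥10 replicates, Spearman trend over
rates 0–60%).

What the generator does *not* emulate: multi-axis correlation structure,
activity transitions inside a sequence, label noise, sensor drift, and
non-random (bursty or state-dependent) loss. Passing the synthetic suite
therefore demonstrates the mechanism — train-time corruption confers
test-time robustness under MAR — not field performance on real wearables.

## Numerical and degenerate-input choices

* Mask size `round(rate·n)` uses ties-to-even; rates outside `[0, 1)` are
  rejected.
* Window arithmetic uses a 1e−9 epsilon against float drift in
  `floor((T − w)/s)`.
* An all-missing or sub-`min_valid` window yields an all-undefined feature
  vector (later median-filled), never NaN arithmetic.
* Serialization uses the literal token `NA`; a partially-`NA` row is a
  format error (a missing timestep loses all channels by definition), and
  parse errors name file and line.
* The canonical CSV writer emits minimal round-tripping float reprs, so
  write → read → write is byte-identical.
* Every stochastic step (noise, masks, classifier) draws its seed from a
  single root via seed sequences; identical seeds give bit-identical runs.

## Known limitations

* The proposed protocol's advantage is bounded by the Bayes rate of the
  corrupted feature distribution; at extreme rates (≥70% here) both
  protocols converge and the comparison is reported but not asserted.
* The benchmark readers (HASC-style and single-chest-style CSV) are tested
  on constructed files only; dataset-release quirks (label-track layouts in
  particular) are absorbed in one documented place but not exhaustively
  covered.
* No imputation baselines are implemented — by design, the method is
  imputation-free — so comparisons against recovery-based approaches are
  out of scope.
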