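# Methods

This note records the modelling conventions, numerical choices and
open-design decisions behind ethoclass, and what the synthetic tests
do and do not demonstrate about real accelerometer data.

## Signal model and segmentation

Acceleration is measured in g (1 g = 9.8 m/s²) on three sensor axes
x/y/z; the mapping to body axes (surge = longitudinal, sway = lateral,
heave = vertical) depends on how the tag is attached and lives in
`DatasetConfig.axis_map`, never in the file format. Time is seconds
from stream start; wall-clock timestamps are converted on read because
every downstream computation is relative.

Segmentation uses consecutive, non-overlapping windows of
`bout_len_records` starting at sample 0. Overlapping or sliding
windows would leak information between cross-validation folds and
inflate accuracy, so they are deliberately not offered. The trailing
partial window is discarded rather than padded (features assume a full
bout). A window is retained only if every sample carries the same
behaviour label under the half-open interval rule `t_start <= t <
t_end`; unlabelled time (no observation interval) always prunes the
window. For burst-mode recorders each burst can be treated as one
candidate window via the bout-table input. For recordings whose native
bursts span several behaviours, halving the window first and testing
label purity second is the implemented order.

## Feature conventions

The full catalogue has 78 features in a fixed order (groups of
30 + 12 + 13 + 2 + 6 + 6 + 9). Where a summary statistic admits
several textbook estimators the package uses one convention
throughout:

* **Static/dynamic decomposition.** The static component is a centred
  moving average with a configurable window; the default window is the
  whole bout, i.e. static = per-axis bout mean. Bouts short enough to
  contain a single behaviour rarely contain a posture change, and the
  bout mean is the simplest estimator of the gravity projection; a
  2-s running mean is available through the `window` argument for long
  bouts.
* **ODBA** is the *mean* over samples of the summed absolute dynamic
  acceleration of the three axes (not the sum over samples), making it
  invariant to bout length and comparable across datasets recorded at
  different rates. For a single-axis sinusoid of amplitude *a*, ODBA
  converges to 2a/π.
* **Pitch and roll** use the arctangent form: pitch =
  atan2(mean_surge, √(mean_sway² + mean_heave²)), roll =
  atan2(mean_sway, mean_heave), reported in degrees. The arcsine
  convention differs only in normalisation; the atan2 form is total
  (defined for any non-zero mean vector). A zero mean vector yields
  (0, 0) with a warning.
* **Moments.** Variance, sd and covariance use the n−1 denominator.
  Skewness is the third standardised moment m₃/m₂^{3/2}; kurtosis is
  the excess m₄/m₂² − 3 (both with population moments, matching the
  common default estimators). A zero-variance axis scores 0 for
  skewness, kurtosis, CV and any correlation involving it — never NaN,
  so classifiers always receive finite inputs (constant bouts are
  normal for resting behaviours).
* **Successive differences.** "Mean difference of continuous points"
  is the mean *absolute* successive difference (the signed mean
  telescopes to ≈ (last−first)/n and carries almost no information);
  its variance uses signed differences.
* **Spectral features.** The DFT is taken on the mean-removed signal
  (the DC bin would otherwise dominate through posture, which the mean
  features already capture); the dominant non-DC bin gives the main
  frequency, with ties resolved to the lowest frequency, and its
  amplitude is scaled by 2/N so a unit sinusoid on an exact bin scores
  1 g. An effectively constant signal reports amplitude 0 at the first
  non-DC bin.
* **Quartiles** use linear interpolation (the "type 7" convention,
  the default of mainstream statistics environments).

The simplified sets are strict sub-vectors of the full catalogue under
the axis map: {mean, sd} × {surge, heave} + ODBA for back/collar/leg
mounts, {mean, sd} × {heave} + ODBA + heave main frequency for ear
tags (the frequency term picks up jaw movement in ruminants).

## Classifiers

scikit-learn and xgboost provide the fitting backends; the surrounding
conventions are the package's own:

* **LDA** first removes correlated features: iteratively take the pair
  with the largest |Pearson r| above the 0.7 cutoff and drop the
  member with the larger mean absolute correlation against all
  remaining features (ties keep the earlier column). Constant columns
  have their undefined correlations treated as 0 and are never removed
  for constancy alone. The procedure is idempotent and the retained
  subset is stored on the model.
* **SVM** is RBF-kernel only, with features standardised (centre/scale
  stored on the model and re-applied at prediction). Multiclass is
  one-vs-one vote counting; vote ties resolve to the alphabetically
  first class.
* **DT** maps the complexity parameter `cp` to cost-complexity pruning
  (`ccp_alpha`).
* **RF** predicts by majority vote over the per-tree predicted classes
  with the alphabetical tie-break — the classical forest voting rule —
  rather than by averaging tree probabilities. This keeps the
  library's prediction semantics identical to the exported on-board
  engine while the two code paths (backend tree evaluation vs scratch
  node-array traversal) remain independent checks of each other.
  `mtry = 0` selects the backend default (√p features per split).
* **ANN** is a single hidden layer of logistic units with softmax
  output, L2 weight decay from the grid, maximum 500 iterations of a
  quasi-Newton solver, no skip-layer connections.
* **XGBoost** uses the softmax multiclass objective, depth 6, default
  learning rate, and a fixed base margin of 0.5.
* Default ensemble sizes follow the on-board model-shrinking
  convention: ntree = 800 / nrounds = 10 with the full feature set,
  ntree = 20 / nrounds = 5 with the simplified sets.
* **Tuning** is an exhaustive grid search maximising mean
  stratified-CV overall accuracy, with ties broken toward the simpler
  model (smaller size/ntree/cost/gamma/mtry/nrounds, larger decay/cp).
  The default grids are small and config-exposed; they are starting
  points, not recommendations.

Seeds are explicit arguments everywhere; there is no hidden global RNG
state.

## Validation metrics

Stratified 10-fold CV partitions the bouts so that within every class
the fold sizes differ by at most one; remainder bouts are dealt to
folds in seeded-shuffled order ("semi-random" proportional
allocation). A class with fewer than k members raises an error that
suggests merging rare behaviour categories — the standard field remedy
— instead of silently unbalancing folds. Per fold, the held-out data
never enters training (feature standardisation is fitted inside each
training split).

Overall accuracy is reported as trace/total of the confusion matrix,
which is algebraically the one-vs-rest (TP+TN)/(TP+TN+FP+FN) averaged
over classes; the identity is exercised in the tests. F1 degenerates
to 0 (not NaN) when a class is never predicted and never recovered.
The 95 % CI over folds uses Student's t with k−1 degrees of freedom
rather than the normal 1.96 factor — at k = 10 the conservative
choice.

## Compact export and scratch engines

The four exportable methods reduce to: support vectors + dual
coefficients + pairwise intercepts + scaling (SVM); two dense weight
matrices + biases + scaling (ANN); flat arrays of
(feature, threshold, left, right, leaf) nodes (forest and boosted
trees, the latter carrying additive leaf scores grouped round-major by
class). The engines use only numpy scalars/loops so they can be
transcribed to embedded C.

Numerical conventions that make engine-backend agreement exact rather
than approximate:

* Tree traversal branches left on **strict less-than**. The exporter
  converts scikit-learn's `<=` thresholds with `nextafter(t, +inf)`,
  which is float-exact; xgboost already uses `<`.
* Feature values are compared in **single precision** (as both
  backends and a microcontroller hold them); without this, a value
  landing between the float32 and float64 reading of a threshold
  occasionally takes the other branch.
* Boosted margins are reconstructed from the model dump, which round
  trips float32 exactly, but the backend accumulates in a different
  order; the equivalence oracle therefore excludes margin near-ties
  (gap < 1e-5) alongside genuine vote ties. In the shipped study this
  excludes a handful of bouts out of 500 at most.
* Every tie (SVM votes, forest votes, argmax) resolves to the
  alphabetically first class, in the library and in the engines,
  making the oracle's exclusions auditable.

Storage accounting defaults to 4-byte values; tree nodes cost 4 values
each (feature index, threshold or leaf payload, two child references).
The deployment arithmetic is exact rational arithmetic: compression =
(records × axes × value_bytes)/label_bytes, and storage days =
⌊memory / (label_bytes × 86400/bout_seconds)⌋.

## Synthetic data

Each behaviour is modelled as posture (a unit gravity-projection
vector) + per-axis sinusoid (amplitude, one shared frequency, random
phase per episode/bout) + white Gaussian noise, with exponential dwell
times between behaviour switches. This gives closed-form expectations
(mean ≈ posture, ODBA ≈ (2/π)·Σ amplitudes, main frequency = driving
frequency) that the tests check against.

Two presets ship. "stork": a back-mounted bird at 10.54 Hz with
40-record (3.8 s) bouts and four behaviours — standing (upright, no
dynamics), walking (slightly pitched, 2 Hz gait), passive_flight
(pitched down, low-amplitude 0.8 Hz), active_flight (pitched up,
high-amplitude 3.9 Hz flapping). "cow": an ear tag at 25 Hz with
1500-record (1 min) bouts and three behaviours — eating (head down,
1.2 Hz jaw), ruminating (head level, 0.9 Hz jaw, lower amplitude),
other. Postures, amplitudes and frequencies were chosen once as
field-plausible magnitudes (wingbeats of a large soaring bird sit near
3–4 Hz, walking gaits near 2 Hz, chewing near 1 Hz; noise at
0.03–0.10 g) and are fixed.

What the generator does **not** emulate: inter- and intra-individual
variation, tag migration on the animal, behaviour-dependent noise
spectra (real dynamics are not single sinusoids), transitional
movement between behaviours, and class imbalance beyond dwell-time
differences. Consequently the near-perfect synthetic cross-validation
accuracies demonstrate correctness of the pipeline — segmentation,
features, training, validation and export are wired correctly and the
classifiers recover known structure — not expected field performance,
which is dominated by exactly the omitted factors. The deliberately
confusable twin-behaviour scenario in the tests (shared posture and
amplitude, differing only in frequency, classified without frequency
features) restores the realistic failure mode: misclassification
concentrated between one behaviour pair.

## Problem sizes

The shipped study uses 4 behaviours × 200 bouts per class for
training, 10-fold CV on both feature sets for the four exportable
methods, and 500 held-out bouts for engine-backend agreement — sizes
at which every estimate above is stable across seeds while the whole
study re-runs in well under a minute.

## Known limitations

* Variable-length (change-point) segmentation is out of scope.
* The packed little-endian binary deployment image is not emitted;
  compact models serialise to JSON, which carries the same content.
* LDA and DT have no compact engines (they were not candidates for
  on-board use here).
* Storage figures depend on the chosen value width and on the fitted
  model (support-vector counts, node counts), so only the accounting
  structure — not any particular kB figure — is asserted.
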