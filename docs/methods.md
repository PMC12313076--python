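# Methods

This note documents the models, the synthetic cohort, the numerical
choices, and the limitations of `ctgaug`. It states no empirical result
beyond what the test suite and `scripts/acceptance.py` themselves compute.

## The synthetic cohort

No imbalanced CTG + maternal-clinical cohort of the kind this pipeline
targets is publicly deposited, so the `fixtures` module generates one. It
emulates a hospital monitoring cohort of 42,000 cases with the class mix
train 27,930 normal / 970 suspicious / 500 pathological and test
12,222 / 265 / 113 (a 7:3 partition; a further 8:2 train/validation split
is carved per class out of the training side). Generation inverts the
clinical labeling rule: first the set of non-reassuring features is drawn
(none for normal; one uniform feature for suspicious; a uniform subset of
size ≥ 2 — 11 possibilities — for pathological), then each feature is
sampled uniformly from the matching interval:

| feature | reassuring | non-reassuring (sampling bounds) |
|---|---|---|
| FHR baseline (bpm) | 110–160 | [60, 109] ∪ [161, 210] |
| baseline variability (bpm) | 5–25 | [0, 4.5] ∪ [25.5, 40] |
| accelerations / 20 min | ≥ 2 (sampled 2–6) | {0, 1} |
| deceleration | none, early, variable | regular, late, prolonged |

Reassuring interval endpoints are inclusive; the non-reassuring side is the
strict complement, truncated to physiologic extremes because the clinical
inequalities are open-ended. Maternal clinical features (blood pressure
139/89, heart rate < 90, SpO₂ ≥ 90 %, temperature 97–99 °F) are sampled
from their normal ranges for every class, since the labeling rule reads
only the CTG features. Every emitted record satisfies
`label_case(features) == label` by construction, and this is re-verified
property-style in the tests.

**What this fixture does not emulate.** Because the reassuring and
non-reassuring intervals are disjoint with wide gaps and labels are a
deterministic function of the features, the three classes are (almost
linearly) separable. Real extracted CTG features carry measurement noise,
borderline values and inter-observer ambiguity, which is precisely what
makes minority classes hard in practice. Consequences are discussed under
*Limitations*.

Raw-trace fixtures (`generate_trace`) synthesise a piecewise-constant
baseline (120 s plateaus within ±2 bpm of the record's FHR baseline),
additive uniform variability of the record's amplitude, and the record's
accelerations/decelerations as trapezoidal excursions of ±25 bpm —
comfortably clearing the summariser's 15 bpm threshold at full variability.
Missing segments (~2 s) are inserted to an exact target fraction, never at
the first sample.

## Preprocessing

* **Edge trimming** removes maximal leading/trailing runs outside a
  configurable validity interval, default [50, 210] bpm (the literature
  does not fix this; 50–210 brackets plausible fetal rates). Interior
  out-of-range samples become missing.
* **Prefix-median imputation**: each missing segment is filled with the
  median of the observed values before it, segments processed left to
  right so later medians include earlier imputations. The median of an
  even-length prefix is the mean of the central pair. The first sample
  must be observed. The baseline-variability channel is imputed
  independently by the same rule.
* **Decentralization** `D(t) = S0(t) − B(t)`. When no baseline channel is
  recorded, `estimate_baseline` supplies a 10-minute centred rolling
  median.
* **Trace summarisation** recovers the tabular CTG features: baseline =
  window median; variability = 10th–90th percentile spread of the
  baseline-removed signal outside excursions; accelerations = excursions
  ≥ +15 bpm lasting ≥ 15 s; decelerations classified on the full event
  (run boundaries extended to where the signal leaves the baseline):
  ≥ 120 s → prolonged, time-to-nadir ≤ 30 s → variable, gradual ≥ 60 s →
  late, else early. A bare FHR trace cannot express the "regular"
  (uterine-activity-relative) pattern, so the summariser never emits it.
* **Clinical conditioning**: missing cells take the training-partition
  column mean; columns are then zero-mean shifted by training means (no
  variance scaling — the conditioning step is specified as mean removal
  only). All data-dependent statistics are fit on the training partition
  and applied unchanged elsewhere, preventing leakage.
* **Fusion** concatenates the 3 numeric CTG features, a fixed-order
  6-level one-hot deceleration block, and the 5 clinical columns into a
  14-column design matrix. For numeric stability of the small networks,
  the modeling path (`prepare_model_matrices`) additionally centres and
  unit-variance-scales the continuous columns with training statistics;
  one-hot columns are left untouched.

## The generative model

Each augmented class gets its own BEGAN. The discriminator is an
autoencoder (input → 80 → 50 → 80 → input, rectifier hidden activations,
linear output); the generator maps a 50-dimensional standard-normal latent
through an 80-unit hidden layer. With λ(·) the mean absolute
reconstruction error, per batch:

* discriminator loss `λ(a) − k_t·λ(G(z))`,
* generator loss `λ(G(z))` (gradient through both the direct path and the
  frozen discriminator),
* control update `k_{t+1} = clip(k_t + 0.001·(α·λ(a) − λ(G(z))), 0, 1)`,
  `k_0 = 0`,

with α the diversity ratio (default 0.5; its experimental value is not
reported in the literature this follows, so it is configurable). After
each epoch the convergence measure `M = λ(a) + |α·λ(a) − λ(G(z))|` is
evaluated on a fixed held-out real batch and fixed latent draws — so the
stopping decision is independent of that epoch's shuffling — and training
stops the first epoch `M < 0.058`, or at the 280-epoch cap. Optimisation
is Adam at 1e-3, batch 64 (unreported upstream; fixed defaults here).

**A structural caveat.** `M` is only informative while the discriminator's
reconstruction distinguishes real from generated rows. When the code layer
(50) is wide relative to the data dimension (14 fused features, or 2 in a
toy), the autoencoder can approach a global identity map; then both λ
terms collapse, `M` crosses any threshold, and the generator receives
little shaping. The toy mean-matching test therefore uses a binding
bottleneck (code dimension 1 for 2-feature data), which exercises the
intended equilibrium mechanism; at the default sizes the stopping rule is
honoured exactly as specified but early stopping can occur before the
generator has matched the class distribution.

**Augmentation policy** (`make_plan`): binary mode gives a flat 6,000
synthetic rows to each class; multiclass mode gives 10,000 rows to each
class holding under 10 % of the population and none to the rest.
Generators train on the standardized fused feature space, so synthetic
rows need no further preprocessing; they carry a `synthetic` provenance
tag and never enter validation or test partitions.

## Representation and classification

Algorithmically: expand the training data with every planned synthetic
set (|ED| = |TD| + Σ mᵢ, checked exactly), train the autoencoder
(architecture as the discriminator, mean-squared-error objective —
the natural choice for a continuous design matrix) for exactly 300
epochs, then extract the encoding half. Extraction shares the layer
objects, so encoder and autoencoder parameters are bit-identical, and the
encoder stays frozen (byte-for-byte, asserted in tests) while classifier
heads train on top of it.

Heads (rectifier activations, softmax/cross-entropy output, Adam 1e-3):

* `dnn`: dense 32 → dense 16 → output;
* `cnn1d`: the feature row as a single-channel sequence, one 1-D
  convolution with 32 filters (kernel 3, valid padding) → dense 16 →
  output;
* `lstm`: two stacked 64-cell recurrent layers over the
  one-value-per-step sequence → dense 32 → output. Presenting a tabular
  row as a length-F sequence is an arbitrary but fixed convention; no
  temporal structure is claimed.

Families: *naive* = head on raw fused features, real data only;
*advanced* = frozen encoder (trained on real data) + head; *proposed* =
encoder trained on the GAN-expanded data + head trained on the expanded
data. The binary task merges suspicious and pathological into `abnormal`.
Default training is 100 epochs with early stopping on validation loss
(patience 10, best parameters restored); classifier epochs are unreported
upstream, so these are package defaults, and scaled studies reduce them
(the acceptance experiment uses 20 fixed epochs). `run_experiment` repeats
classifier training R times with independent seeds (generators and
encoders fitted once per configuration), evaluates every run on the
untouched real test partition, and reports the best run by test accuracy
alongside mean/sd/95 % CI — best-run-on-test mirrors the evaluated
protocol but is optimistic, and the per-run statistics are reported for
that reason.

## Evaluation and comparison

Accuracy = (TP+TN)/total; per-class precision, recall and F1 are
one-vs-rest reductions of the confusion matrix. Ratios with zero
denominators surface as NaN with a warning, never as silent zeros —
minority classes that a collapsed model never predicts would otherwise
fake a 0 % that looks computed. ROC sweeps every distinct threshold and
integrates by trapezoid (cross-checked against scikit-learn in tests).
Run statistics use the sample (n−1) standard deviation and the normal
approximation mean ± z·sd/√R. McNemar's test is the exact two-sided
binomial on the discordant counts (b, c) with success probability ½ —
exact rather than the χ² approximation because minority-class discordant
counts are small. Bootstrap CIs are percentile intervals over 10,000
paired row resamples; degenerate resamples (undefined metric) are redrawn
and counted.

## Reproducibility

A single global seed fans out to per-stage seeds via a CRC32 derivation of
`"{stage}:{seed}"` (mod 2³¹), so stages re-run in isolation reproduce the
pipeline run. Every artifact embeds the config hash; `compare` refuses
reports whose test partitions differ. Identical seed + config yields
byte-identical datasets, parameter vectors and reports (asserted in
tests).

## Problem sizes

Desk-scale defaults used by the tests and the acceptance script: the full
42,000-record cohort for scaffolding checks; a tenth-scale cohort
(train 2,793/97/50, test 1,222/27/11) with 600 synthetic rows per minority
class, 50-epoch generators, the full 300-epoch autoencoder, 20-epoch
classifier heads and 5 independent runs for the end-to-end imbalance
experiment; 2-feature/500-row toys for generator and autoencoder sanity.

## Limitations

* The synthetic cohort's classes are separable by construction (disjoint
  feature intervals, deterministic labels). On such data a naive
  classifier with an adequate budget can learn the minority classes from
  few examples, so augmentation has little headroom and lossy stages
  (encoding, imperfect synthetic rows) can dominate. The end-to-end
  experiment in the acceptance suite reports both models' minority recall
  honestly; a benefit from augmentation of the kind seen on noisy clinical
  cohorts should not be expected on this fixture, and passing pipeline
  tests demonstrate mechanism correctness, not clinical performance.
* BEGAN with an overcomplete discriminator code (see above) can satisfy
  the convergence criterion without distribution matching; the measure is
  a stopping rule, not a quality guarantee.
* The trace summariser is a rule-based stand-in for learned CTG feature
  extraction; it recovers events embedded by the trace fixture exactly on
  clean signals but is not validated on real recordings, and cannot
  distinguish "regular" from "late" decelerations without a uterine
  activity channel.
* Best-run selection on the test partition is optimistic; per-run
  statistics accompany it.
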