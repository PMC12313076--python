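# ctgaug

GAN-based minority-class augmentation and autoencoder feature extraction
for severely imbalanced cardiotocography (CTG) classification.

## The problem

Cardiotocography records fetal heart rate (FHR) alongside maternal vital
signs to assess fetal wellbeing. Clinically, each monitoring case reduces
to four CTG features — FHR baseline, baseline variability, accelerations
per 20 minutes, and the deceleration pattern — each judged *reassuring* or
*non-reassuring* (FHR 110–160 bpm, variability 5–25 bpm, ≥ 2 accelerations
per 20 min, deceleration ∈ {none, early, variable}). A case with no
non-reassuring feature is **normal**, with exactly one **suspicious**, with
two or more **pathological**. Real monitoring cohorts are severely
imbalanced (≈ 95 % normal), so classifiers trained naively collapse onto
the majority class and miss exactly the cases that matter.

`ctgaug` implements a generative rebalancing pipeline for this setting:

1. **Synthetic cohort generator** emulating an imbalanced hospital cohort
   of 42,000 cases (train 27,930 / 970 / 500, test 12,222 / 265 / 113),
   with labels derived deterministically from the features by the clinical
   rule above.
2. **Signal preprocessing** for raw FHR traces: edge outlier trimming,
   prefix-median imputation of missing segments, baseline removal
   (decentralization, `D(t) = S0(t) − B(t)`), trace summarisation into the
   four tabular CTG features, and fusion with mean-imputed, zero-mean
   maternal clinical features.
3. **Per-class boundary-equilibrium GANs (BEGAN)** whose discriminator is
   an autoencoder. Both players optimise L1 reconstruction losses with a
   proportional control variable `k_t` balancing them, and training stops
   via the scalar convergence measure

   ```
   M = λ(a) + |α·λ(a) − λ(G(z))|
   ```

   (λ = mean absolute reconstruction error, `a` a real batch, α the
   diversity ratio) once `M < 0.058` or at the 280-epoch cap. The
   augmentation policy gives 6,000 synthetic rows per class in binary mode
   and 10,000 per minority class (< 10 % population share) in multiclass
   mode.
4. **Autoencoder representation**: a 14 → 80 → 50 → 80 → 14 autoencoder
   trained 300 epochs on the expanded (real ∪ synthetic) dataset; its
   encoding half is extracted and frozen as a 50-dimensional feature
   extractor.
5. **Classifier heads** — DNN (32→16), 1-D CNN (32 filters → 16), LSTM
   (2×64 → 32) — trained on raw features (naive family), on encoder codes
   (advanced), or on encoder codes of the GAN-expanded data (proposed),
   in binary (normal vs abnormal) or three-class mode.
6. **Evaluation**: confusion matrices, per-class one-vs-rest
   precision/recall/F1, ROC, repeated-run mean/sd/95 % CI, exact-binomial
   McNemar tests and percentile-bootstrap CIs of metric differences.

All networks are implemented in NumPy with hand-written backpropagation
(gradient-checked against finite differences in the test suite), so the
package has no deep-learning-framework dependency and every run is
bit-reproducible from a single seed.

## Worked example

A tenth-scale cohort, multiclass augmentation, and the proposed
encoder+GAN CNN:

```python
import numpy as np
from ctgaug import (FixtureConfig, generate_dataset, make_plan, BeganConfig,
                    train_began, expand_dataset, AutoencoderConfig,
                    train_autoencoder, build_head, concat_model,
                    train_classifier, predict, confusion, metrics_table,
                    prepare_model_matrices)

fixture = FixtureConfig(
    train_counts={"normal": 2793, "suspicious": 97, "pathological": 50},
    test_counts={"normal": 1222, "suspicious": 27, "pathological": 11},
    seed=11)
split = generate_dataset(fixture)
x_train, y_train, x_val, y_val, x_test, y_test, cols = prepare_model_matrices(split)

counts = {c: int((y_train == c).sum()) for c in ("normal", "suspicious", "pathological")}
plan = make_plan(counts, "multiclass", multiclass_minor=600)

generators = {}
for i, cls in enumerate(sorted(c for c, m in plan.counts.items() if m)):
    generators[cls] = train_began(x_train[y_train == cls],
                                  BeganConfig(max_epochs=50, seed=7 + i), cls)

ed, ed_labels, provenance = expand_dataset(x_train, y_train, generators, plan, seed=1)
encoder = train_autoencoder(ed, AutoencoderConfig(epochs=300, seed=3))
model = concat_model(encoder, build_head("cnn1d", 50, "multiclass", seed=5),
                     family="proposed")
train_classifier(model, ed, ed_labels, val_rows=x_val, val_labels=y_val)
_, pred = predict(model, x_test)
table = metrics_table(confusion(y_test, pred, ("normal", "suspicious", "pathological")))
```

Output:

```
training rows: 2352, test rows: 1260, features: 14
augmentation plan: {'normal': 0, 'suspicious': 600, 'pathological': 600}
pathological: 50 epochs (epoch_cap), final M = 0.436
suspicious: 50 epochs (epoch_cap), final M = 0.228
expanded dataset: 3552 rows (1200 synthetic)
autoencoder: 300 epochs, reconstruction error 0.511 -> 0.0000
test accuracy: 0.979
  normal: recall 1.000, precision 0.984
  suspicious: recall 0.185, precision 0.500
  pathological: recall 0.545, precision 0.750
```

The plan targets only the two minority classes (both < 10 % of the
population); the generators run to the 50-epoch cap without crossing the
0.058 convergence threshold at this scale; the autoencoder reconstructs the
expanded data almost losslessly; and the composite classifier, trained on
the rebalanced data through the frozen encoder, recovers a substantial
fraction of the rare pathological cases while keeping overall accuracy
high. See `docs/methods.md` for what this fixture can and cannot show
about real monitoring data.

The same pipeline is scriptable from the shell:

```sh
ctgaug generate-data --output-dir out          # 42,000-record cohort CSV
ctgaug preprocess --output-dir out
ctgaug train-gan --mode multiclass --output-dir out
ctgaug augment --output-dir out
ctgaug train-ae --output-dir out
ctgaug train-clf --model g_cnn_ae --output-dir out
ctgaug evaluate --predictions out/predictions_g_cnn_ae_multiclass.csv --output-dir out
ctgaug run-all --seed 1 --output-dir out       # everything, reproducibly
```

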