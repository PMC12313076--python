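"""Classifier heads over the frozen encoder, and the experiment driver.

Three small heads are supported, mirroring common tabular/sequence
baselines:

* ``dnn``   - dense 32 -> dense 16 -> output;
* ``cnn1d`` - 1-D convolution with 32 filters (kernel 3) over the feature
  row viewed as a single-channel sequence, then dense 16 -> output;
* ``lstm``  - two recurrent layers of 64 cells -> dense 32 -> output.

Model families:

* naive     - head alone on the raw fused features, real data only;
* advanced  - frozen encoder (trained on real data, no augmentation) + head;
* proposed  - frozen encoder trained on the GAN-expanded dataset + head,
  with the head also trained on the expanded data.

The binary task merges suspicious and pathological into a single
``abnormal`` class; the test partition always stays real-only.
"""

from __future__ import annotations

import zlib
from dataclasses import asdict, dataclass, field

import numpy as np

from . import nn
from .began import BeganConfig, make_plan, train_began
from .evaluate import confusion, metrics_table, run_stats
from .representation import (
    AutoencoderConfig,
    EncoderModel,
    expand_dataset,
    train_autoencoder,
)

__all__ = [
    "BINARY_CLASSES",
    "MULTICLASS_CLASSES",
    "ClassifierModel",
    "TrainConfig",
    "ExperimentConfig",
    "build_head",
    "concat_model",
    "train_classifier",
    "predict",
    "merge_binary",
    "run_experiment",
    "MODEL_FAMILIES",
]

BINARY_CLASSES = ("normal", "abnormal")
MULTICLASS_CLASSES = ("normal", "suspicious", "pathological")
HEAD_KINDS = ("dnn", "cnn1d", "lstm")

# canonical model roster: name -> (family, head kind)
MODEL_FAMILIES: dict[str, tuple[str, str]] = {
    "dnn": ("naive", "dnn"),
    "cnn": ("naive", "cnn1d"),
    "lstm": ("naive", "lstm"),
    "dnn_ae": ("advanced", "dnn"),
    "cnn_ae": ("advanced", "cnn1d"),
    "g_dnn_ae": ("proposed", "dnn"),
    "g_cnn_ae": ("proposed", "cnn1d"),
    "g_lstm": ("proposed", "lstm"),
}


@dataclass
class ClassifierModel:
    head_kind: str
    task: str                           # "binary" | "multiclass"
    network: nn.Sequential
    input_dim: int
    classes: tuple[str, ...]
    family: str = "naive"
    encoder: EncoderModel | None = None
    frozen_encoder: bool = False
    seed: int = 0
    trained: bool = False

    def features(self, rows: np.ndarray) -> np.ndarray:
        rows = np.asarray(rows, dtype=float)
        return self.encoder.encode(rows) if self.encoder is not None else rows

    def logits(self, rows: np.ndarray) -> np.ndarray:
        return self.network(self.features(rows))


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 100
    batch_size: int = 64
    learning_rate: float = 1e-3
    early_stop_patience: int = 10       # on validation loss; 0 disables


def build_head(kind: str, input_dim: int, task: str, seed: int = 0,
               family: str = "naive") -> ClassifierModel:
    """Untrained head of the requested architecture and output width."""
    if kind not in HEAD_KINDS:
        raise ValueError(f"unknown head kind {kind!r}")
    if task not in ("binary", "multiclass"):
        raise ValueError(f"unknown task {task!r}")
    classes = BINARY_CLASSES if task == "binary" else MULTICLASS_CLASSES
    out = len(classes)
    rng = np.random.default_rng(seed)
    if kind == "dnn":
        net = nn.Sequential([
            nn.Dense(input_dim, 32, rng), nn.ReLU(),
            nn.Dense(32, 16, rng), nn.ReLU(),
            nn.Dense(16, out, rng),
        ])
    elif kind == "cnn1d":
        kernel = 3
        conv_out = (input_dim - kernel + 1) * 32
        net = nn.Sequential([
            nn.AsSequence(),
            nn.Conv1D(1, 32, kernel, rng), nn.ReLU(),
            nn.Flatten(),
            nn.Dense(conv_out, 16, rng), nn.ReLU(),
            nn.Dense(16, out, rng),
        ])
    else:  # lstm: the feature row is a length-input_dim, one-value-per-step sequence
        net = nn.Sequential([
            nn.AsSequence(),
            nn.LSTM(1, 64, rng, return_sequences=True),
            nn.LSTM(64, 64, rng, return_sequences=False),
            nn.Dense(64, 32, rng), nn.ReLU(),
            nn.Dense(32, out, rng),
        ])
    return ClassifierModel(head_kind=kind, task=task, network=net,
                           input_dim=input_dim, classes=classes,
                           family=family, seed=seed)


def concat_model(encoder: EncoderModel, head: ClassifierModel,
                 family: str = "advanced") -> ClassifierModel:
    """Compose the frozen encoder with a head consuming its codes."""
    if head.input_dim != encoder.config.code_dim:
        raise ValueError(
            f"head input dim {head.input_dim} != encoder code dim {encoder.config.code_dim}"
        )
    return ClassifierModel(head_kind=head.head_kind, task=head.task,
                           network=head.network, input_dim=head.input_dim,
                           classes=head.classes, family=family,
                           encoder=encoder, frozen_encoder=True,
                           seed=head.seed)


def merge_binary(labels: np.ndarray) -> np.ndarray:
    """Collapse suspicious/pathological into the single abnormal class."""
    labels = np.asarray(labels)
    return np.where(labels == "normal", "normal", "abnormal")


def _encode_labels(labels: np.ndarray, model: ClassifierModel) -> np.ndarray:
    labels = np.asarray(labels)
    if model.task == "binary":
        labels = merge_binary(labels)
    index = {cls: i for i, cls in enumerate(model.classes)}
    try:
        return np.array([index[l] for l in labels], dtype=int)
    except KeyError as err:
        raise ValueError(f"unknown label {err.args[0]!r} for task {model.task}") from err


def train_classifier(model: ClassifierModel, rows: np.ndarray, labels: np.ndarray,
                     config: TrainConfig = TrainConfig(),
                     val_rows: np.ndarray | None = None,
                     val_labels: np.ndarray | None = None) -> ClassifierModel:
    """Cross-entropy training of the head; an attached encoder never updates.

    With validation data, training stops early when the validation loss has
    not improved for ``early_stop_patience`` epochs and the best parameters
    are restored.  Deterministic for a fixed seed/config/data.
    """
    x = model.features(rows)
    y = _encode_labels(labels, model)
    if np.unique(y).size < 2:
        raise ValueError("training labels cover a single class")
    xv = yv = None
    if val_rows is not None and len(val_rows):
        xv = model.features(val_rows)
        yv = _encode_labels(val_labels, model)
    rng = np.random.default_rng(model.seed)
    net = model.network
    opt = nn.Adam(net.params, lr=config.learning_rate)
    n = x.shape[0]
    batch = min(config.batch_size, n)
    best_loss, best_params, patience = np.inf, None, 0
    for _epoch in range(config.epochs):
        order = rng.permutation(n)
        for start in range(0, n, batch):
            idx = order[start:start + batch]
            net.zero_grad()
            _, grad = nn.softmax_cross_entropy(net(x[idx]), y[idx])
            net.backward(grad)
            opt.step(net.grads)
        if xv is not None and config.early_stop_patience > 0:
            val_loss, _ = nn.softmax_cross_entropy(net(xv), yv)
            if val_loss < best_loss - 1e-6:
                best_loss, patience = val_loss, 0
                best_params = [p.copy() for p in net.params]
            else:
                patience += 1
                if patience >= config.early_stop_patience:
                    break
    if best_params is not None:
        net.set_params(best_params)
    model.trained = True
    return model


def predict(model: ClassifierModel, rows: np.ndarray):
    """Per-row class probabilities and argmax labels (lowest-index ties)."""
    if not model.trained:
        raise RuntimeError("classifier has not been trained")
    rows = np.asarray(rows, dtype=float)
    if rows.shape[0] == 0:
        return np.zeros((0, len(model.classes))), np.array([], dtype=object)
    if rows.shape[1] != (model.encoder.feature_dim if model.encoder else model.input_dim):
        raise ValueError("feature dimension mismatch")
    probs = nn.softmax(model.logits(rows))
    labels = np.array([model.classes[i] for i in probs.argmax(axis=1)], dtype=object)
    return probs, labels


# --- experiment driver ------------------------------------------------------

@dataclass
class ExperimentConfig:
    task: str = "multiclass"
    models: tuple[str, ...] = tuple(MODEL_FAMILIES)
    runs: int = 5                       # independent training runs per model
    seed: int = 0
    began: BeganConfig = field(default_factory=BeganConfig)
    autoencoder: AutoencoderConfig = field(default_factory=AutoencoderConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    binary_per_class: int = 6_000
    multiclass_minor: int = 10_000
    minor_threshold: float = 0.10


def _train_generators(rows: np.ndarray, labels: np.ndarray, plan,
                      config: ExperimentConfig):
    generators = {}
    for i, (cls, count) in enumerate(sorted(plan.counts.items())):
        if count == 0:
            continue
        class_rows = rows[labels == cls]
        gan_config = BeganConfig(**{**config.began.__dict__,
                                    "seed": config.began.seed + i})
        generators[cls] = train_began(class_rows, gan_config, class_label=cls)
    return generators


def run_experiment(x_train: np.ndarray, y_train: np.ndarray,
                   x_val: np.ndarray, y_val: np.ndarray,
                   x_test: np.ndarray, y_test: np.ndarray,
                   config: ExperimentConfig) -> dict[str, dict]:
    """Train every requested model family over R seeded runs and evaluate.

    Generators and encoders are fitted once per family configuration; each
    of the R runs re-initialises and re-trains the classifier head.  All
    evaluation uses the untouched real test partition; the report for each
    model carries the best run (by test accuracy), per-run metrics and
    mean/sd/95%-CI statistics.
    """
    classes = BINARY_CLASSES if config.task == "binary" else MULTICLASS_CLASSES
    y_train_eval = merge_binary(y_train) if config.task == "binary" else np.asarray(y_train)
    y_test_eval = merge_binary(y_test) if config.task == "binary" else np.asarray(y_test)

    class_counts = {cls: int((y_train_eval == cls).sum()) for cls in classes}
    plan = make_plan(class_counts,
                     mode="binary" if config.task == "binary" else "multiclass",
                     binary_per_class=config.binary_per_class,
                     multiclass_minor=config.multiclass_minor,
                     minor_threshold=config.minor_threshold)

    needs = {MODEL_FAMILIES[m][0] for m in config.models}
    generators = encoder_plain = encoder_gan = None
    x_expanded = y_expanded = None
    if "proposed" in needs:
        generators = _train_generators(x_train, y_train_eval, plan, config)
        x_expanded, y_expanded, _prov = expand_dataset(
            x_train, y_train_eval, generators, plan, seed=config.seed + 1)
        encoder_gan = train_autoencoder(x_expanded, config.autoencoder)
    if "advanced" in needs:
        encoder_plain = train_autoencoder(x_train, config.autoencoder)

    reports: dict[str, dict] = {}
    for name in config.models:
        family, kind = MODEL_FAMILIES[name]
        per_run = []
        best = None
        for run in range(config.runs):
            run_seed = config.seed + 1000 * run + zlib.crc32(name.encode()) % 997
            if family == "naive":
                model = build_head(kind, x_train.shape[1], config.task,
                                   seed=run_seed, family=family)
                xt, yt = x_train, y_train_eval
            elif family == "advanced":
                head = build_head(kind, encoder_plain.config.code_dim,
                                  config.task, seed=run_seed, family=family)
                model = concat_model(encoder_plain, head, family=family)
                xt, yt = x_train, y_train_eval
            else:
                head = build_head(kind, encoder_gan.config.code_dim,
                                  config.task, seed=run_seed, family=family)
                model = concat_model(encoder_gan, head, family=family)
                xt, yt = x_expanded, y_expanded
            train_classifier(model, xt, yt, config.train, x_val, y_val)
            _, pred = predict(model, x_test)
            cm = confusion(y_test_eval, pred, classes)
            table = metrics_table(cm)
            entry = {
                "run": run,
                "accuracy": table["accuracy"],
                "per_class": table["per_class"],
                "confusion": cm.table.tolist(),
                "predictions": pred,
            }
            per_run.append(entry)
            if best is None or entry["accuracy"] > best["accuracy"]:
                best = entry
        accs = [e["accuracy"] for e in per_run]
        reports[name] = {
            "family": family,
            "head": kind,
            "task": config.task,
            "runs": config.runs,
            "best_run": best,
            "per_run": per_run,
            "stats": {"accuracy": asdict(run_stats(accs)) if len(accs) >= 2 else
                      {"mean": float(np.mean(accs)), "sd": None, "ci": None}},
        }
    return reports
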