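"""Autoencoder representation learning on the GAN-expanded dataset.

The expanded dataset is the union of the real training rows with every
per-class synthetic set the augmentation plan requests.  An autoencoder
(input -> 80 -> 50 -> 80 -> input, rectifier activations, linear output)
is trained unsupervised on it for a fixed number of epochs (default 300,
mean-squared-error objective), and its encoding half is then extracted as
a standalone 50-dimensional feature extractor.  Extraction shares the
layer objects, so the encoder's parameters are bit-identical to the
corresponding autoencoder layers — and stay identical when a downstream
classifier trains with the encoder frozen.
"""

from __future__ import annotations

import json
import pathlib
from dataclasses import dataclass, asdict

import numpy as np

from . import nn
from .began import AugmentationPlan, BeganState, TrainingDivergence, generate_synthetic

__all__ = [
    "AutoencoderConfig",
    "EncoderModel",
    "expand_dataset",
    "train_autoencoder",
    "extract_encoder",
    "save_encoder",
    "load_encoder",
]

REAL, SYNTHETIC = "real", "synthetic"


@dataclass(frozen=True)
class AutoencoderConfig:
    code_dim: int = 50
    hidden_width: int = 80
    epochs: int = 300
    batch_size: int = 64
    learning_rate: float = 1e-3
    seed: int = 0


@dataclass
class EncoderModel:
    """Full autoencoder plus its extracted (parameter-sharing) encoder."""

    autoencoder: nn.Sequential | None
    encoder: nn.Sequential | None
    config: AutoencoderConfig
    feature_dim: int
    epochs_trained: int = 0
    initial_error: float = float("nan")
    final_error: float = float("nan")

    @property
    def trained(self) -> bool:
        return self.autoencoder is not None and self.epochs_trained > 0

    def encode(self, rows: np.ndarray) -> np.ndarray:
        if self.encoder is None:
            raise RuntimeError("encoder has not been extracted")
        return self.encoder(np.asarray(rows, dtype=float))


def expand_dataset(td_rows: np.ndarray, td_labels: np.ndarray,
                   generators: dict[str, BeganState], plan: AugmentationPlan,
                   seed: int = 0):
    """ED = real rows united with every planned synthetic set.

    Returns ``(rows, labels, provenance)`` where provenance tags each row
    ``real`` or ``synthetic``; ``|ED| = |TD| + sum_i m_i`` exactly.
    """
    plan.validate()
    td_rows = np.asarray(td_rows, dtype=float)
    td_labels = np.asarray(td_labels)
    if td_rows.shape[0] != td_labels.shape[0]:
        raise ValueError("rows and labels must align")
    rows = [td_rows]
    labels = [td_labels]
    provenance = [np.full(td_rows.shape[0], REAL)]
    for cls, count in plan.counts.items():
        if count == 0:
            continue
        if cls not in generators:
            raise ValueError(f"no trained generator for planned class {cls!r}")
        synth = generate_synthetic(generators[cls], count, seed=seed)
        rows.append(synth)
        labels.append(np.full(count, cls, dtype=td_labels.dtype))
        provenance.append(np.full(count, SYNTHETIC))
        seed += 1
    return (np.concatenate(rows, axis=0), np.concatenate(labels),
            np.concatenate(provenance))


def train_autoencoder(ed_rows: np.ndarray,
                      config: AutoencoderConfig = AutoencoderConfig()) -> EncoderModel:
    """Minimise reconstruction MSE on the expanded dataset for ``epochs`` epochs.

    Training is unsupervised (labels are not consulted) and fully seeded:
    the same seed, config and data give identical final parameters.
    """
    rows = np.asarray(ed_rows, dtype=float)
    if rows.ndim != 2 or rows.shape[0] == 0:
        raise ValueError("expanded dataset must be a non-empty 2-D array")
    n, feature_dim = rows.shape
    rng = np.random.default_rng(config.seed)
    w, c = config.hidden_width, config.code_dim
    enc_layers = [nn.Dense(feature_dim, w, rng), nn.ReLU(), nn.Dense(w, c, rng)]
    dec_layers = [nn.ReLU(), nn.Dense(c, w, rng), nn.ReLU(), nn.Dense(w, feature_dim, rng)]
    auto = nn.Sequential(enc_layers + dec_layers)
    encoder = nn.Sequential(enc_layers)  # shares the layer objects
    opt = nn.Adam(auto.params, lr=config.learning_rate)

    initial_error, _ = nn.mse_loss(auto(rows), rows)
    batch = min(config.batch_size, n)
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        for start in range(0, n, batch):
            x = rows[order[start:start + batch]]
            auto.zero_grad()
            loss, grad = nn.mse_loss(auto(x), x)
            if not np.isfinite(loss):
                raise TrainingDivergence(epoch)
            auto.backward(grad)
            opt.step(auto.grads)
    final_error, _ = nn.mse_loss(auto(rows), rows)

    return EncoderModel(autoencoder=auto, encoder=encoder, config=config,
                        feature_dim=feature_dim, epochs_trained=config.epochs,
                        initial_error=float(initial_error),
                        final_error=float(final_error))


def extract_encoder(model: EncoderModel) -> nn.Sequential:
    """The trained encoding half (input -> hidden -> code), shared parameters."""
    if not model.trained:
        raise RuntimeError("autoencoder has not been trained")
    return model.encoder


# --- persistence -----------------------------------------------------------

def save_encoder(model: EncoderModel, directory: str | pathlib.Path) -> None:
    directory = pathlib.Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    np.savez(directory / "autoencoder.npz", *model.autoencoder.params)
    record = {
        "config": asdict(model.config),
        "feature_dim": model.feature_dim,
        "epochs_trained": model.epochs_trained,
        "initial_error": model.initial_error,
        "final_error": model.final_error,
    }
    (directory / "training.json").write_text(json.dumps(record, indent=1))


def load_encoder(directory: str | pathlib.Path) -> EncoderModel:
    directory = pathlib.Path(directory)
    record = json.loads((directory / "training.json").read_text())
    config = AutoencoderConfig(**record["config"])
    rng = np.random.default_rng(0)
    w, c = config.hidden_width, config.code_dim
    feature_dim = record["feature_dim"]
    enc_layers = [nn.Dense(feature_dim, w, rng), nn.ReLU(), nn.Dense(w, c, rng)]
    dec_layers = [nn.ReLU(), nn.Dense(c, w, rng), nn.ReLU(), nn.Dense(w, feature_dim, rng)]
    auto = nn.Sequential(enc_layers + dec_layers)
    with np.load(directory / "autoencoder.npz") as data:
        auto.set_params([data[f"arr_{i}"] for i in range(len(data.files))])
    return EncoderModel(autoencoder=auto, encoder=nn.Sequential(enc_layers),
                        config=config, feature_dim=feature_dim,
                        epochs_trained=record["epochs_trained"],
                        initial_error=record["initial_error"],
                        final_error=record["final_error"])
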