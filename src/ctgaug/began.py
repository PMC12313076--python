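"""Per-class boundary-equilibrium GAN (BEGAN) for tabular augmentation.

One generator is trained per minority (or, in binary mode, per) class on
that class's preprocessed feature rows.  The discriminator is itself an
autoencoder, and both players optimise reconstruction (L1) losses:

    L_D = lam(a) - k_t * lam(G(z))          (discriminator)
    L_G = lam(G(z))                         (generator)
    k_{t+1} = clip(k_t + gain * (alpha * lam(a) - lam(G(z))), 0, 1)

where ``lam`` is the mean absolute reconstruction error, ``a`` a real
batch, ``alpha`` the diversity ratio balancing sample fidelity against
variety, and ``k_t`` the proportional equilibrium control variable.
Unlike most adversarial models, this scheme admits a scalar convergence
measure,

    M = lam(a) + |alpha * lam(a) - lam(G(z))|,

evaluated here once per epoch on a fixed held-out batch; training stops the
first epoch M falls below the configured threshold (default 0.058) or at
the epoch cap (default 280).
"""

from __future__ import annotations

import json
import pathlib
from dataclasses import dataclass, field, asdict

import numpy as np

from . import nn

__all__ = [
    "BeganConfig",
    "BeganState",
    "AugmentationPlan",
    "TrainingDivergence",
    "reconstruction_error",
    "convergence_measure",
    "train_began",
    "generate_synthetic",
    "make_plan",
    "save_state",
    "load_state",
]


class TrainingDivergence(RuntimeError):
    """Raised when a loss goes non-finite; carries the epoch index."""

    def __init__(self, epoch: int) -> None:
        super().__init__(f"non-finite loss at epoch {epoch}")
        self.epoch = epoch


@dataclass(frozen=True)
class BeganConfig:
    latent_dim: int = 50
    hidden_width: int = 80
    discriminator_depth: int = 3        # hidden layers: width, code, width
    alpha: float = 0.5                  # diversity ratio, in (0, 1]
    convergence_threshold: float = 0.058
    max_epochs: int = 280
    equilibrium_gain: float = 0.001     # proportional step for k_t
    batch_size: int = 64
    learning_rate: float = 1e-3
    seed: int = 0

    def validate(self) -> None:
        if self.convergence_threshold < 0:
            raise ValueError("convergence_threshold must be >= 0")
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError("alpha must lie in (0, 1]")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")
        if self.latent_dim < 1 or self.hidden_width < 1:
            raise ValueError("network widths must be positive")


@dataclass
class BeganState:
    """Trained per-class generator with its convergence history."""

    generator: nn.Sequential | None
    discriminator: nn.Sequential | None
    k: float
    m_history: list[float]
    epochs_run: int
    stop_reason: str                    # "threshold" | "epoch_cap"
    config: BeganConfig
    feature_dim: int
    class_label: str | None = None

    @property
    def trained(self) -> bool:
        return self.generator is not None and self.epochs_run > 0


@dataclass(frozen=True)
class AugmentationPlan:
    """How many synthetic rows each class receives."""

    mode: str                                   # "binary" | "multiclass"
    counts: dict[str, int] = field(default_factory=dict)
    minor_threshold: float = 0.10

    def validate(self) -> None:
        if self.mode not in ("binary", "multiclass"):
            raise ValueError(f"unknown augmentation mode {self.mode!r}")
        if any(n < 0 for n in self.counts.values()):
            raise ValueError("synthetic counts must be non-negative")

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def reconstruction_error(batch: np.ndarray, discriminator) -> float:
    """Mean absolute elementwise error between a batch and its reconstruction."""
    batch = np.asarray(batch, dtype=float)
    if batch.size == 0:
        raise ValueError("batch must be non-empty")
    if batch.ndim != 2:
        raise ValueError("batch must be 2-D (rows, features)")
    recon = discriminator(batch)
    if recon.shape != batch.shape:
        raise ValueError(f"reconstruction shape {recon.shape} != batch shape {batch.shape}")
    return float(np.mean(np.abs(batch - recon)))


def convergence_measure(lambda_real: float, lambda_fake: float, alpha: float) -> float:
    """M = lam_real + |alpha * lam_real - lam_fake| (non-negative inputs)."""
    if lambda_real < 0 or lambda_fake < 0:
        raise ValueError("reconstruction errors must be non-negative")
    if not 0.0 < alpha <= 1.0:
        raise ValueError("alpha must lie in (0, 1]")
    return float(lambda_real + abs(alpha * lambda_real - lambda_fake))


def _build_discriminator(feature_dim: int, width: int, code: int,
                         rng: np.random.Generator) -> nn.Sequential:
    # autoencoder-shaped: input -> width -> code -> width -> input
    return nn.Sequential([
        nn.Dense(feature_dim, width, rng), nn.ReLU(),
        nn.Dense(width, code, rng), nn.ReLU(),
        nn.Dense(code, width, rng), nn.ReLU(),
        nn.Dense(width, feature_dim, rng),
    ])


def _build_generator(latent: int, width: int, feature_dim: int,
                     rng: np.random.Generator) -> nn.Sequential:
    return nn.Sequential([
        nn.Dense(latent, width, rng), nn.ReLU(),
        nn.Dense(width, feature_dim, rng),
    ])


def train_began(class_rows: np.ndarray, config: BeganConfig = BeganConfig(),
                class_label: str | None = None) -> BeganState:
    """Train one generator on the feature rows of a single class.

    The convergence measure is evaluated after every epoch on a fixed batch
    of real rows and fixed latent draws, so the stopping decision does not
    depend on the minibatch shuffling of that epoch.  With the same seed,
    config and data the full M history is reproducible.
    """
    config.validate()
    rows = np.asarray(class_rows, dtype=float)
    if rows.ndim != 2 or rows.shape[0] == 0:
        raise ValueError("class_rows must be a non-empty 2-D array")
    if not np.isfinite(rows).all():
        raise ValueError("class_rows must be finite")
    n, feature_dim = rows.shape
    rng = np.random.default_rng(config.seed)
    disc = _build_discriminator(feature_dim, config.hidden_width,
                                config.latent_dim, rng)
    gen = _build_generator(config.latent_dim, config.hidden_width,
                           feature_dim, rng)
    opt_d = nn.Adam(disc.params, lr=config.learning_rate)
    opt_g = nn.Adam(gen.params, lr=config.learning_rate)

    eval_n = min(n, 4 * config.batch_size)
    eval_real = rows[rng.choice(n, size=eval_n, replace=False)]
    eval_z = rng.standard_normal((eval_n, config.latent_dim))

    k = 0.0
    history: list[float] = []
    stop_reason = "epoch_cap"
    epochs_run = 0
    batch = min(config.batch_size, n)
    for epoch in range(config.max_epochs):
        order = rng.permutation(n)
        for start in range(0, n, batch):
            real = rows[order[start:start + batch]]
            z = rng.standard_normal((real.shape[0], config.latent_dim))

            # discriminator step: minimise lam(real) - k * lam(fake)
            fake = gen(z)
            disc.zero_grad()
            recon_real = disc(real)
            loss_real, grad_real = nn.l1_loss(recon_real, real)
            disc.backward(grad_real)
            recon_fake = disc(fake)
            loss_fake, grad_fake = nn.l1_loss(recon_fake, fake)
            disc.backward(-k * grad_fake)
            if not np.isfinite(loss_real) or not np.isfinite(loss_fake):
                raise TrainingDivergence(epoch)
            opt_d.step(disc.grads)

            # generator step: minimise lam(G(z)); gradient flows through the
            # (frozen for this step) discriminator and the direct path
            gen.zero_grad()
            disc.zero_grad()
            fake = gen(z)
            recon = disc(fake)
            loss_g, grad_recon = nn.l1_loss(recon, fake)
            if not np.isfinite(loss_g):
                raise TrainingDivergence(epoch)
            grad_fake_total = -grad_recon + disc.backward(grad_recon)
            gen.backward(grad_fake_total)
            opt_g.step(gen.grads)

            # proportional control toward the equilibrium lam_fake = alpha*lam_real
            k = float(np.clip(
                k + config.equilibrium_gain * (config.alpha * loss_real - loss_g),
                0.0, 1.0,
            ))

        lam_real = reconstruction_error(eval_real, disc)
        lam_fake = reconstruction_error(gen(eval_z), disc)
        m = convergence_measure(lam_real, lam_fake, config.alpha)
        history.append(m)
        epochs_run = epoch + 1
        if m < config.convergence_threshold:
            stop_reason = "threshold"
            break

    return BeganState(generator=gen, discriminator=disc, k=k,
                      m_history=history, epochs_run=epochs_run,
                      stop_reason=stop_reason, config=config,
                      feature_dim=feature_dim, class_label=class_label)


def generate_synthetic(state: BeganState, n: int, seed: int = 0) -> np.ndarray:
    """Draw exactly ``n`` synthetic feature rows from a trained generator."""
    if n < 0:
        raise ValueError("n must be >= 0")
    if not state.trained:
        raise RuntimeError("generator has not been trained")
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n, state.config.latent_dim))
    rows = state.generator(z) if n else np.zeros((0, state.feature_dim))
    if not np.isfinite(rows).all():  # pragma: no cover - guarded by training
        raise RuntimeError("generator produced non-finite rows")
    return rows


def make_plan(class_counts: dict[str, int], mode: str,
              binary_per_class: int = 6_000, multiclass_minor: int = 10_000,
              minor_threshold: float = 0.10) -> AugmentationPlan:
    """Decide per-class synthetic row counts.

    Binary mode gives every class the flat per-class count (default 6,000).
    Multiclass mode targets only minority classes: a class whose population
    share is below ``minor_threshold`` (default 10%) receives
    ``multiclass_minor`` rows (default 10,000); all others receive none.
    """
    if any(n <= 0 for n in class_counts.values()):
        raise ValueError("class counts must be positive")
    if mode == "binary":
        counts = {cls: binary_per_class for cls in class_counts}
    elif mode == "multiclass":
        total = sum(class_counts.values())
        counts = {
            cls: (multiclass_minor if n / total < minor_threshold else 0)
            for cls, n in class_counts.items()
        }
    else:
        raise ValueError(f"unknown augmentation mode {mode!r}")
    plan = AugmentationPlan(mode=mode, counts=counts, minor_threshold=minor_threshold)
    plan.validate()
    return plan


# --- persistence -----------------------------------------------------------

def save_state(state: BeganState, directory: str | pathlib.Path) -> None:
    """One directory per class: parameter file + JSON training record."""
    directory = pathlib.Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    np.savez(directory / "generator.npz",
             *state.generator.params)
    np.savez(directory / "discriminator.npz",
             *state.discriminator.params)
    record = {
        "epochs_run": state.epochs_run,
        "stop_reason": state.stop_reason,
        "m_history": state.m_history,
        "k": state.k,
        "feature_dim": state.feature_dim,
        "class_label": state.class_label,
        "config": asdict(state.config),
    }
    (directory / "training.json").write_text(json.dumps(record, indent=1))


def load_state(directory: str | pathlib.Path) -> BeganState:
    directory = pathlib.Path(directory)
    record = json.loads((directory / "training.json").read_text())
    config = BeganConfig(**record["config"])
    rng = np.random.default_rng(0)
    gen = _build_generator(config.latent_dim, config.hidden_width,
                           record["feature_dim"], rng)
    disc = _build_discriminator(record["feature_dim"], config.hidden_width,
                                config.latent_dim, rng)
    with np.load(directory / "generator.npz") as data:
        gen.set_params([data[f"arr_{i}"] for i in range(len(data.files))])
    with np.load(directory / "discriminator.npz") as data:
        disc.set_params([data[f"arr_{i}"] for i in range(len(data.files))])
    return BeganState(generator=gen, discriminator=disc, k=record["k"],
                      m_history=list(record["m_history"]),
                      epochs_run=record["epochs_run"],
                      stop_reason=record["stop_reason"], config=config,
                      feature_dim=record["feature_dim"],
                      class_label=record["class_label"])
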