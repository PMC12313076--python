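"""Configuration, dataset I/O and reproducible pipeline orchestration.

A single global seed fans out to per-stage seeds through a fixed CRC32
derivation, so any stage can be re-run in isolation and still reproduce the
full-pipeline result.  Every artifact written by the pipeline embeds the
hash of the configuration that produced it, and report comparison refuses
to mix reports whose test partitions differ.
"""

from __future__ import annotations

import hashlib
import json
import logging
import pathlib
import zlib
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .began import BeganConfig
from .classifier import (
    ExperimentConfig,
    TrainConfig,
    merge_binary,
    run_experiment,
)
from .fixtures import (
    CLASS_ORDER,
    CLINICAL_FEATURES,
    CTG_FEATURES,
    DatasetSplit,
    FixtureConfig,
    frame_to_records,
    generate_dataset,
    records_to_frame,
)
from .preprocess import (
    DECELERATION_LEVELS,
    fuse_features,
    impute_clinical_mean,
    standardize_clinical,
)
from .representation import AutoencoderConfig

__all__ = [
    "RunConfig",
    "derive_seed",
    "config_hash",
    "read_dataset",
    "write_dataset",
    "prepare_model_matrices",
    "run_all",
    "setup_logging",
]

logger = logging.getLogger("ctgaug")

DATASET_COLUMNS = list(CLINICAL_FEATURES) + list(CTG_FEATURES) + ["label", "split"]
SPLIT_VALUES = ("train", "validation", "test")


def setup_logging(output_dir: pathlib.Path | None = None,
                  level: int = logging.INFO) -> None:
    handlers: list[logging.Handler] = [logging.StreamHandler()]
    if output_dir is not None:
        output_dir.mkdir(parents=True, exist_ok=True)
        handlers.append(logging.FileHandler(output_dir / "run.log"))
    logging.basicConfig(
        level=level,
        format="%(asctime)s %(levelname)s %(name)s: %(message)s",
        handlers=handlers,
        force=True,
    )


def derive_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage seed from the global seed and the stage name."""
    return zlib.crc32(f"{stage}:{global_seed}".encode()) % (2 ** 31)


@dataclass
class RunConfig:
    """Everything one reproducible end-to-end run needs."""

    seed: int = 0
    task: str = "multiclass"
    fixture: FixtureConfig = field(default_factory=FixtureConfig)
    began: BeganConfig = field(default_factory=BeganConfig)
    autoencoder: AutoencoderConfig = field(default_factory=AutoencoderConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    models: tuple[str, ...] = ("cnn", "lstm", "cnn_ae", "g_cnn_ae")
    runs: int = 5
    binary_per_class: int = 6_000
    multiclass_minor: int = 10_000
    minor_threshold: float = 0.10

    def to_dict(self) -> dict:
        d = asdict(self)
        d["models"] = list(d["models"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "fixture" in d:
            d["fixture"] = FixtureConfig(**_tupled(d["fixture"]))
        if "began" in d:
            d["began"] = BeganConfig(**d["began"])
        if "autoencoder" in d:
            d["autoencoder"] = AutoencoderConfig(**d["autoencoder"])
        if "train" in d:
            d["train"] = TrainConfig(**d["train"])
        if "models" in d:
            d["models"] = tuple(d["models"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        pathlib.Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(pathlib.Path(path).read_text()))


def _tupled(d: dict) -> dict:
    """YAML round-trips tuples as lists; restore the tuple-typed fields."""
    out = dict(d)
    for key in ("fhr_reassuring", "bv_reassuring"):
        if key in out:
            out[key] = tuple(out[key])
    for key in ("fhr_non_reassuring", "bv_non_reassuring"):
        if key in out:
            out[key] = tuple(tuple(pair) for pair in out[key])
    if "accel_non_reassuring" in out:
        out["accel_non_reassuring"] = tuple(out["accel_non_reassuring"])
    if "clinical_ranges" in out:
        out["clinical_ranges"] = {k: tuple(v) for k, v in out["clinical_ranges"].items()}
    return out


def config_hash(config: RunConfig) -> str:
    payload = json.dumps(config.to_dict(), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


# --- dataset I/O -----------------------------------------------------------

def write_dataset(split: DatasetSplit, path) -> None:
    frames = [
        records_to_frame(split.train, "train"),
        records_to_frame(split.validation, "validation"),
        records_to_frame(split.test, "test"),
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_dataset(path) -> DatasetSplit:
    """Read and validate the canonical dataset CSV; errors name the row."""
    frame = pd.read_csv(path)
    unknown = [c for c in frame.columns if c not in DATASET_COLUMNS]
    if unknown:
        raise ValueError(f"unknown columns in dataset file: {unknown}")
    missing = [c for c in DATASET_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"dataset file missing columns: {missing}")
    for i, row in enumerate(frame.itertuples(index=False), start=2):  # header = line 1
        if row.label not in CLASS_ORDER:
            raise ValueError(f"line {i}: unknown label {row.label!r}")
        if row.deceleration not in DECELERATION_LEVELS:
            raise ValueError(f"line {i}: unknown deceleration {row.deceleration!r}")
        if row.split not in SPLIT_VALUES:
            raise ValueError(f"line {i}: unknown split {row.split!r}")
    parts = {}
    for name in SPLIT_VALUES:
        parts[name] = frame_to_records(frame[frame["split"] == name])
    per_class = {
        cls: (
            sum(1 for r in parts["train"] + parts["validation"] if r.label == cls),
            sum(1 for r in parts["test"] if r.label == cls),
        )
        for cls in CLASS_ORDER
    }
    return DatasetSplit(train=parts["train"], validation=parts["validation"],
                        test=parts["test"], per_class_counts=per_class)


# --- feature preparation ---------------------------------------------------

def prepare_model_matrices(split: DatasetSplit):
    """Fused, conditioned design matrices for the three partitions.

    Clinical columns are mean-imputed and zero-mean shifted with
    training-partition statistics; for numeric stability of the small
    networks the CTG numeric columns are also centred and all continuous
    columns scaled by their training standard deviation (one-hot columns
    are left untouched).  Returns ``(X_train, y_train, X_val, y_val,
    X_test, y_test, column_names)``.
    """
    frames = {}
    for name, records in (("train", split.train), ("validation", split.validation),
                          ("test", split.test)):
        frame = records_to_frame(records)
        ctg = frame[list(CTG_FEATURES)]
        clinical = frame[list(CLINICAL_FEATURES)]
        frames[name] = (ctg, clinical, frame["label"].to_numpy())

    train_clin = frames["train"][1]
    imputed = impute_clinical_mean(train_clin)
    _, means = standardize_clinical(imputed)

    matrices = {}
    for name, (ctg, clinical, labels) in frames.items():
        clin_shifted = clinical.copy()
        for col, mu in means.items():
            clin_shifted[col] = clinical[col].fillna(mu) - mu
        fused = fuse_features(ctg, clin_shifted, means)
        matrices[name] = (fused.frame, labels)

    train_frame = matrices["train"][0]
    onehot = [c for c in train_frame.columns if c.startswith("deceleration_")]
    center = {}
    scale = {}
    for col in train_frame.columns:
        if col in onehot:
            center[col], scale[col] = 0.0, 1.0
        else:
            center[col] = float(train_frame[col].mean())
            sd = float(train_frame[col].std(ddof=0))
            scale[col] = sd if sd > 1e-9 else 1.0

    out = []
    for name in ("train", "validation", "test"):
        frame, labels = matrices[name]
        x = np.column_stack([
            (frame[col].to_numpy(dtype=float) - center[col]) / scale[col]
            for col in train_frame.columns
        ]) if len(frame) else np.zeros((0, len(train_frame.columns)))
        out.extend([x, labels])
    out.append(list(train_frame.columns))
    return tuple(out)


# --- pipeline --------------------------------------------------------------

def run_all(config: RunConfig, output_dir) -> dict:
    """Execute generate -> preprocess -> GAN -> AE -> classify -> evaluate.

    Writes the dataset CSV and a metrics JSON (tagged with the config hash
    and seed) under ``output_dir`` and returns the report dictionary.
    Identical config and seed give an identical report.
    """
    output_dir = pathlib.Path(output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)
    chash = config_hash(config)
    logger.info("run-all starting: config %s seed %d", chash, config.seed)

    fixture = FixtureConfig(**{**asdict(config.fixture),
                               "seed": derive_seed(config.seed, "fixtures")})
    fixture = FixtureConfig(**_tupled(asdict(fixture)))
    split = generate_dataset(fixture)
    write_dataset(split, output_dir / "dataset.csv")
    x_train, y_train, x_val, y_val, x_test, y_test, columns = \
        prepare_model_matrices(split)

    exp = ExperimentConfig(
        task=config.task,
        models=config.models,
        runs=config.runs,
        seed=derive_seed(config.seed, "classifier"),
        began=BeganConfig(**{**asdict(config.began),
                             "seed": derive_seed(config.seed, "began")}),
        autoencoder=AutoencoderConfig(**{**asdict(config.autoencoder),
                                         "seed": derive_seed(config.seed, "autoencoder")}),
        train=config.train,
        binary_per_class=config.binary_per_class,
        multiclass_minor=config.multiclass_minor,
        minor_threshold=config.minor_threshold,
    )
    reports = run_experiment(x_train, y_train, x_val, y_val, x_test, y_test, exp)

    test_hash = hashlib.sha256(
        pd.util.hash_pandas_object(records_to_frame(split.test)).values.tobytes()
    ).hexdigest()[:16]
    serializable = {}
    for name, report in reports.items():
        r = {k: v for k, v in report.items() if k != "per_run"}
        r["best_run"] = {k: v for k, v in report["best_run"].items()
                         if k != "predictions"}
        r["per_run_accuracy"] = [e["accuracy"] for e in report["per_run"]]
        serializable[name] = r
    payload = {
        "config_hash": chash,
        "seed": config.seed,
        "test_partition_hash": test_hash,
        "columns": columns,
        "models": serializable,
    }
    (output_dir / "metrics.json").write_text(json.dumps(payload, indent=1))
    logger.info("run-all finished: %d models evaluated", len(serializable))
    payload["_raw_reports"] = reports
    return payload


def compare_reports(path_a, path_b) -> None:
    """Guard: reports are only comparable on the identical test partition."""
    a = json.loads(pathlib.Path(path_a).read_text())
    b = json.loads(pathlib.Path(path_b).read_text())
    if a.get("test_partition_hash") != b.get("test_partition_hash"):
        raise ValueError("test partitions differ; reports are not comparable")
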