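"""Synthetic cardiotocography + maternal-clinical dataset generator.

The reference cohort this emulates is a severely imbalanced hospital
dataset of 42,000 monitoring cases with eight features: four maternal
clinical measurements (blood pressure, heart rate, oxygen saturation,
temperature) and four CTG features (FHR baseline, baseline variability,
accelerations per 20 minutes, deceleration category).  Class labels follow
a deterministic clinical rule over the CTG features only:

* normal        - all four CTG features reassuring;
* suspicious    - exactly one non-reassuring CTG feature;
* pathological  - two or more non-reassuring CTG features.

Reassuring ranges: FHR 110-160 bpm, variability 5-25 bpm, >= 2
accelerations per 20 min, deceleration in {none, early, variable}
(endpoints inclusive; the non-reassuring side is the strict complement,
bounded to physiologic extremes for sampling).

The default per-class counts reproduce the reference distribution exactly:
train 27,930 / 970 / 500 and test 12,222 / 265 / 113 (42,000 records
total), with a validation fifth carved per class out of the training side.
Generation is the inverse of the labeling rule: pick which features are
non-reassuring, then sample each feature from the matching interval, so
every emitted record's label re-derives from its own features.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .preprocess import DECELERATION_LEVELS, CtgTrace

__all__ = [
    "CLASS_ORDER",
    "CTG_FEATURES",
    "CLINICAL_FEATURES",
    "CaseRecord",
    "DatasetSplit",
    "FixtureConfig",
    "is_reassuring",
    "label_case",
    "sample_case",
    "generate_dataset",
    "generate_trace",
    "records_to_frame",
    "frame_to_records",
]

CLASS_ORDER = ("normal", "suspicious", "pathological")
CTG_FEATURES = ("fhr_baseline", "baseline_variability", "accelerations", "deceleration")
CLINICAL_FEATURES = ("bp_systolic", "bp_diastolic", "maternal_hr", "spo2", "temperature")

REASSURING_DECELERATIONS = frozenset({"none", "early", "variable"})
NON_REASSURING_DECELERATIONS = tuple(
    d for d in DECELERATION_LEVELS if d not in REASSURING_DECELERATIONS
)


@dataclass(frozen=True)
class CaseRecord:
    """One monitoring case: 5 maternal clinical + 4 CTG features + label."""

    bp_systolic: float            # mmHg
    bp_diastolic: float           # mmHg
    maternal_hr: float            # beats/min
    spo2: float                   # %
    temperature: float            # degrees F
    fhr_baseline: float           # beats/min
    baseline_variability: float   # beats/min
    accelerations: int            # count per 20 min
    deceleration: str             # category
    label: str                    # normal | suspicious | pathological

    def ctg_features(self) -> dict[str, float | int | str]:
        return {name: getattr(self, name) for name in CTG_FEATURES}


@dataclass
class DatasetSplit:
    train: list[CaseRecord]
    validation: list[CaseRecord]
    test: list[CaseRecord]
    per_class_counts: dict[str, tuple[int, int]]  # class -> (train_n, test_n)


@dataclass(frozen=True)
class FixtureConfig:
    """Generator configuration; defaults reproduce the reference cohort."""

    train_counts: dict[str, int] = field(default_factory=lambda: {
        "normal": 27_930, "suspicious": 970, "pathological": 500,
    })
    test_counts: dict[str, int] = field(default_factory=lambda: {
        "normal": 12_222, "suspicious": 265, "pathological": 113,
    })
    validation_fraction: float = 0.2  # carved per class from the train side
    seed: int = 0
    # reassuring intervals (inclusive) / sets
    fhr_reassuring: tuple[float, float] = (110.0, 160.0)
    bv_reassuring: tuple[float, float] = (5.0, 25.0)
    accel_reassuring_min: int = 2
    accel_reassuring_max: int = 6          # sampling cap only
    # non-reassuring sampling intervals: bounded extensions of the strict
    # complement, kept physiologic
    fhr_non_reassuring: tuple[tuple[float, float], ...] = ((60.0, 109.0), (161.0, 210.0))
    bv_non_reassuring: tuple[tuple[float, float], ...] = ((0.0, 4.5), (25.5, 40.0))
    accel_non_reassuring: tuple[int, ...] = (0, 1)
    # maternal clinical normal ranges (sampled identically for every class:
    # the labeling rule reads CTG features only)
    clinical_ranges: dict[str, tuple[float, float]] = field(default_factory=lambda: {
        "bp_systolic": (100.0, 139.0),
        "bp_diastolic": (60.0, 89.0),
        "maternal_hr": (60.0, 89.0),
        "spo2": (90.0, 100.0),
        "temperature": (97.0, 99.0),
    })

    def validate(self) -> None:
        for counts in (self.train_counts, self.test_counts):
            for cls, n in counts.items():
                if cls not in CLASS_ORDER:
                    raise ValueError(f"unknown class {cls!r}")
                if n < 0:
                    raise ValueError(f"negative count for {cls!r}")
        if not 0.0 <= self.validation_fraction < 1.0:
            raise ValueError("validation_fraction must be in [0, 1)")
        for lo, hi in self.fhr_non_reassuring:
            if self.fhr_reassuring[0] <= lo <= self.fhr_reassuring[1] or \
               self.fhr_reassuring[0] <= hi <= self.fhr_reassuring[1]:
                raise ValueError("FHR reassuring/non-reassuring intervals overlap")
        for lo, hi in self.bv_non_reassuring:
            if self.bv_reassuring[0] <= lo <= self.bv_reassuring[1] or \
               self.bv_reassuring[0] <= hi <= self.bv_reassuring[1]:
                raise ValueError("variability reassuring/non-reassuring intervals overlap")
        if any(a >= self.accel_reassuring_min for a in self.accel_non_reassuring):
            raise ValueError("acceleration reassuring/non-reassuring sets overlap")
        if not self.fhr_non_reassuring or not self.bv_non_reassuring \
                or not self.accel_non_reassuring:
            raise ValueError("empty non-reassuring interval set")


DEFAULT_CONFIG = FixtureConfig()


def is_reassuring(feature_name: str, value,
                  config: FixtureConfig = DEFAULT_CONFIG) -> bool:
    """Whether one CTG feature value falls on the reassuring side."""
    if feature_name == "fhr_baseline":
        lo, hi = config.fhr_reassuring
        return bool(lo <= value <= hi)
    if feature_name == "baseline_variability":
        lo, hi = config.bv_reassuring
        return bool(lo <= value <= hi)
    if feature_name == "accelerations":
        return bool(value >= config.accel_reassuring_min)
    if feature_name == "deceleration":
        if value not in DECELERATION_LEVELS:
            raise ValueError(f"unknown deceleration category {value!r}")
        return value in REASSURING_DECELERATIONS
    raise ValueError(f"unknown CTG feature {feature_name!r}")


def label_case(fhr_baseline: float, baseline_variability: float,
               accelerations: int, deceleration: str,
               config: FixtureConfig = DEFAULT_CONFIG) -> str:
    """Class label from the four CTG features: 0 / 1 / >=2 non-reassuring."""
    values = {
        "fhr_baseline": fhr_baseline,
        "baseline_variability": baseline_variability,
        "accelerations": accelerations,
        "deceleration": deceleration,
    }
    for name, value in values.items():
        if value is None:
            raise ValueError(f"missing CTG feature {name!r}")
    bad = sum(0 if is_reassuring(name, value, config) else 1
              for name, value in values.items())
    if bad >= 2:
        return "pathological"
    return "suspicious" if bad == 1 else "normal"


def _sample_interval(rng: np.random.Generator,
                     interval: tuple[float, float]) -> float:
    return float(rng.uniform(interval[0], interval[1]))


def _sample_ctg_feature(name: str, reassuring: bool, rng: np.random.Generator,
                        config: FixtureConfig):
    if name == "fhr_baseline":
        if reassuring:
            return round(_sample_interval(rng, config.fhr_reassuring), 1)
        branch = config.fhr_non_reassuring[rng.integers(len(config.fhr_non_reassuring))]
        return round(_sample_interval(rng, branch), 1)
    if name == "baseline_variability":
        if reassuring:
            return round(_sample_interval(rng, config.bv_reassuring), 1)
        branch = config.bv_non_reassuring[rng.integers(len(config.bv_non_reassuring))]
        return round(_sample_interval(rng, branch), 1)
    if name == "accelerations":
        if reassuring:
            return int(rng.integers(config.accel_reassuring_min,
                                    config.accel_reassuring_max + 1))
        return int(config.accel_non_reassuring[rng.integers(len(config.accel_non_reassuring))])
    if name == "deceleration":
        if reassuring:
            return str(rng.choice(sorted(REASSURING_DECELERATIONS)))
        return str(rng.choice(NON_REASSURING_DECELERATIONS))
    raise ValueError(f"unknown CTG feature {name!r}")  # pragma: no cover


# the 11 subsets of {0,1,2,3} with >= 2 elements, in a fixed order so that
# pathological cases draw uniformly over them
_PATHOLOGICAL_SUBSETS = tuple(
    tuple(i for i in range(4) if pattern >> i & 1)
    for pattern in range(16)
    if bin(pattern).count("1") >= 2
)


def sample_case(label: str, rng: np.random.Generator,
                config: FixtureConfig = DEFAULT_CONFIG) -> CaseRecord:
    """Draw one record whose CTG features re-derive the requested label."""
    if label not in CLASS_ORDER:
        raise ValueError(f"unknown class {label!r}")
    config.validate()
    if label == "normal":
        bad = frozenset()
    elif label == "suspicious":
        bad = frozenset({int(rng.integers(4))})
    else:
        bad = frozenset(_PATHOLOGICAL_SUBSETS[rng.integers(len(_PATHOLOGICAL_SUBSETS))])
    ctg = {
        name: _sample_ctg_feature(name, i not in bad, rng, config)
        for i, name in enumerate(CTG_FEATURES)
    }
    clinical = {name: round(_sample_interval(rng, config.clinical_ranges[name]), 1)
                for name in CLINICAL_FEATURES}
    return CaseRecord(**clinical, **ctg, label=label)


def _bulk_numeric(rng: np.random.Generator, bad: np.ndarray,
                  reassuring: tuple[float, float],
                  branches: tuple[tuple[float, float], ...]) -> np.ndarray:
    """Vectorized draw of a numeric CTG feature given its non-reassuring mask."""
    n = bad.size
    lo, hi = reassuring
    values = rng.uniform(lo, hi, size=n)
    n_bad = int(bad.sum())
    if n_bad:
        which = rng.integers(len(branches), size=n_bad)
        bounds = np.asarray(branches)
        blo, bhi = bounds[which, 0], bounds[which, 1]
        values[bad] = rng.uniform(blo, bhi)
    return np.round(values, 1)


def _sample_class_bulk(label: str, n: int, rng: np.random.Generator,
                       config: FixtureConfig) -> list[CaseRecord]:
    """Vectorized equivalent of ``n`` calls to sample_case for one class."""
    if n == 0:
        return []
    if label == "normal":
        bad = np.zeros((n, 4), dtype=bool)
    elif label == "suspicious":
        bad = np.zeros((n, 4), dtype=bool)
        bad[np.arange(n), rng.integers(4, size=n)] = True
    else:
        subsets = np.zeros((len(_PATHOLOGICAL_SUBSETS), 4), dtype=bool)
        for i, subset in enumerate(_PATHOLOGICAL_SUBSETS):
            subsets[i, list(subset)] = True
        bad = subsets[rng.integers(len(_PATHOLOGICAL_SUBSETS), size=n)]

    fhr = _bulk_numeric(rng, bad[:, 0], config.fhr_reassuring, config.fhr_non_reassuring)
    bv = _bulk_numeric(rng, bad[:, 1], config.bv_reassuring, config.bv_non_reassuring)
    accel = rng.integers(config.accel_reassuring_min,
                         config.accel_reassuring_max + 1, size=n)
    if bad[:, 2].any():
        pool = np.asarray(config.accel_non_reassuring)
        accel[bad[:, 2]] = pool[rng.integers(pool.size, size=int(bad[:, 2].sum()))]
    reas_dec = np.array(sorted(REASSURING_DECELERATIONS), dtype=object)
    decel = reas_dec[rng.integers(reas_dec.size, size=n)]
    if bad[:, 3].any():
        pool = np.array(NON_REASSURING_DECELERATIONS, dtype=object)
        decel[bad[:, 3]] = pool[rng.integers(pool.size, size=int(bad[:, 3].sum()))]
    clinical = {
        name: np.round(rng.uniform(*config.clinical_ranges[name], size=n), 1)
        for name in CLINICAL_FEATURES
    }
    return [
        CaseRecord(
            bp_systolic=float(clinical["bp_systolic"][i]),
            bp_diastolic=float(clinical["bp_diastolic"][i]),
            maternal_hr=float(clinical["maternal_hr"][i]),
            spo2=float(clinical["spo2"][i]),
            temperature=float(clinical["temperature"][i]),
            fhr_baseline=float(fhr[i]),
            baseline_variability=float(bv[i]),
            accelerations=int(accel[i]),
            deceleration=str(decel[i]),
            label=label,
        )
        for i in range(n)
    ]


def generate_dataset(config: FixtureConfig = DEFAULT_CONFIG) -> DatasetSplit:
    """Emit exactly the configured per-class train/validation/test records.

    The validation set is carved per class out of the training count at
    ``validation_fraction``, so per-class train+validation totals equal the
    configured training counts.  The same seed always yields the identical
    dataset.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    train: list[CaseRecord] = []
    validation: list[CaseRecord] = []
    test: list[CaseRecord] = []
    per_class: dict[str, tuple[int, int]] = {}
    for cls in CLASS_ORDER:
        n_train_total = config.train_counts.get(cls, 0)
        n_test = config.test_counts.get(cls, 0)
        n_val = int(round(config.validation_fraction * n_train_total))
        n_train = n_train_total - n_val
        train.extend(_sample_class_bulk(cls, n_train, rng, config))
        validation.extend(_sample_class_bulk(cls, n_val, rng, config))
        test.extend(_sample_class_bulk(cls, n_test, rng, config))
        per_class[cls] = (n_train_total, n_test)
    return DatasetSplit(train=train, validation=validation, test=test,
                        per_class_counts=per_class)


def records_to_frame(records: list[CaseRecord],
                     split: str | list[str] | None = None) -> pd.DataFrame:
    """Records as the canonical CSV-schema DataFrame."""
    cols = list(CLINICAL_FEATURES) + list(CTG_FEATURES) + ["label"]
    frame = pd.DataFrame(
        [[getattr(r, c) for c in cols] for r in records], columns=cols
    )
    if split is not None:
        frame["split"] = split
    return frame


def frame_to_records(frame: pd.DataFrame) -> list[CaseRecord]:
    cols = list(CLINICAL_FEATURES) + list(CTG_FEATURES) + ["label"]
    records = []
    for row in frame[cols].itertuples(index=False):
        values = dict(zip(cols, row))
        values["accelerations"] = int(values["accelerations"])
        records.append(CaseRecord(**values))
    return records


# --- raw-trace fixture -----------------------------------------------------

# event shapes recoverable by the trace summariser: (duration s, onset-to-
# nadir s).  Variable decelerations are abrupt (< 30 s to nadir), early and
# late gradual; "regular"/"late" share the gradual long-event shape because
# "regular" is a repetition pattern relative to uterine activity that a
# single bare trace cannot encode.
_DECEL_SHAPES = {
    "early": (50.0, 35.0),
    "variable": (40.0, 8.0),
    "late": (90.0, 45.0),
    "regular": (90.0, 45.0),
    "prolonged": (150.0, 40.0),
}


def _embed_event(signal: np.ndarray, start: int, n: int, amplitude: float,
                 onset_n: int, ramp_out_n: int) -> None:
    """Trapezoidal excursion: linear ramp to amplitude at ``onset_n``, flat
    plateau, linear recovery over the final ``ramp_out_n`` samples."""
    ramp_out = max(1, min(ramp_out_n, n - onset_n))
    for j in range(n):
        if j < onset_n:
            frac = (j + 1) / onset_n
        elif j >= n - ramp_out:
            frac = (n - j) / ramp_out
        else:
            frac = 1.0
        signal[start + j] += amplitude * min(1.0, frac)


def generate_trace(case: CaseRecord, duration: float = 1200.0,
                   sampling_rate: float = 4.0, missing_rate: float = 0.0,
                   rng: np.random.Generator | None = None,
                   noise: bool = True) -> CtgTrace:
    """Synthesize a raw FHR trace consistent with a tabular record.

    The trace is a piecewise-constant baseline near ``case.fhr_baseline``
    with additive variability of the record's amplitude, the record's
    accelerations and deceleration embedded as transient excursions, and
    missing segments inserted at ``missing_rate``.  Event amplitudes (+25 /
    -25 bpm) clear the summariser's 15 bpm excursion threshold even at full
    variability.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if not 0.0 <= missing_rate < 1.0:
        raise ValueError("missing_rate must be in [0, 1)")
    rng = rng or np.random.default_rng(0)
    n = int(round(duration * sampling_rate))
    # piecewise-constant baseline: 120 s plateaus stepping within +/-2 bpm
    seg = max(1, int(round(120.0 * sampling_rate)))
    n_seg = -(-n // seg)
    steps = rng.uniform(-2.0, 2.0, size=n_seg)
    baseline = np.repeat(case.fhr_baseline + steps, seg)[:n]
    s0 = baseline.copy()
    if noise and case.baseline_variability > 0:
        s0 = s0 + rng.uniform(-case.baseline_variability / 2,
                              case.baseline_variability / 2, size=n)

    # events in evenly spaced slots with margins, so excursions never merge
    events: list[tuple[float, float, float]] = []  # (duration s, onset s, amplitude)
    for _ in range(int(case.accelerations)):
        events.append((30.0, 5.0, 25.0))
    if case.deceleration != "none":
        dur, onset = _DECEL_SHAPES[case.deceleration]
        events.append((dur, onset, -25.0))
    if events:
        slot = n // len(events)
        ramp_out_n = int(round(6.0 * sampling_rate))
        for i, (dur, onset, amp) in enumerate(events):
            ev_n = int(round(dur * sampling_rate))
            if ev_n >= slot:
                raise ValueError("trace too short to embed the record's events")
            start = i * slot + (slot - ev_n) // 2
            _embed_event(s0, start, ev_n, amp,
                         int(round(onset * sampling_rate)), ramp_out_n)

    if missing_rate > 0:
        target = int(round(missing_rate * n))
        seg_len = max(1, int(round(2.0 * sampling_rate)))
        missing = np.zeros(n, dtype=bool)
        while missing.sum() < target:
            st = int(rng.integers(1, max(2, n - seg_len)))
            missing[st:st + seg_len] = True
        # never lose the anchor sample the imputation needs
        missing[0] = False
        extra = missing.sum() - target
        if extra > 0:
            idx = np.flatnonzero(missing)
            missing[idx[-extra:]] = False
        s0[missing] = np.nan

    return CtgTrace(s0=s0, baseline=baseline, sampling_rate=sampling_rate)
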