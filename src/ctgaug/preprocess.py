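"""Signal cleaning and feature conditioning for cardiotocography records.

The pipeline mirrors standard computerised-CTG practice: trim untrustworthy
samples from the edges of the fetal-heart-rate (FHR) trace, mark interior
out-of-range samples missing, fill missing segments with the median of the
observed prefix, remove the baseline (decentralization, ``D = S0 - B``),
summarise each trace into the four tabular CTG features, then fuse them with
mean-imputed, zero-mean-standardized maternal clinical features.

All data-dependent statistics (imputation means, standardization means) are
fit on the training partition only and applied unchanged to validation and
test data, so no information leaks across partitions.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CtgTrace",
    "TraceSummary",
    "FeatureMatrix",
    "trim_outliers",
    "impute_median",
    "decentralize",
    "impute_clinical_mean",
    "standardize_clinical",
    "summarize_trace",
    "fuse_features",
    "estimate_baseline",
    "DECELERATION_LEVELS",
]

# categorical vocabulary for the deceleration feature; "regular" and "late"
# exist in the tabular data but only duration/onset-distinguishable shapes
# can be recovered from a raw trace (see summarize_trace)
DECELERATION_LEVELS = ("none", "early", "variable", "regular", "late", "prolonged")

DEFAULT_VALID_RANGE = (50.0, 210.0)  # physiologic FHR bounds (bpm)


@dataclass
class CtgTrace:
    """A sampled FHR trace with baseline; ``nan`` marks missing samples."""

    s0: np.ndarray                      # FHR samples S0(t), bpm
    baseline: np.ndarray                # baseline B(t), bpm
    sampling_rate: float                # Hz
    decentralized: np.ndarray | None = None  # D(t) = S0(t) - B(t)

    def __post_init__(self) -> None:
        self.s0 = np.asarray(self.s0, dtype=float)
        self.baseline = np.asarray(self.baseline, dtype=float)
        if self.s0.shape != self.baseline.shape:
            raise ValueError(
                f"FHR and baseline lengths differ: {self.s0.shape} vs {self.baseline.shape}"
            )
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")

    @property
    def n(self) -> int:
        return int(self.s0.shape[0])

    @property
    def duration(self) -> float:
        return self.n / self.sampling_rate


@dataclass(frozen=True)
class TraceSummary:
    """The four tabular CTG features recovered from one trace."""

    fhr_baseline: float          # bpm
    baseline_variability: float  # bpm
    accelerations: int           # count over the analysed trace
    deceleration: str            # one of DECELERATION_LEVELS


@dataclass
class FeatureMatrix:
    """Fused CTG + clinical design matrix with standardization metadata."""

    frame: pd.DataFrame
    standardization_means: dict[str, float] = field(default_factory=dict)

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, means: dict[str, float] | None = None) -> "FeatureMatrix":
        return cls(pd.read_csv(path), means or {})


def trim_outliers(trace: CtgTrace,
                  valid_range: tuple[float, float] = DEFAULT_VALID_RANGE) -> CtgTrace:
    """Drop out-of-range runs at the trace edges; mark interior ones missing.

    Untrustworthy samples (outside ``valid_range``, e.g. sensor dropouts read
    as 0 or spikes above 210 bpm) are removed entirely when they form the
    leading/trailing run and replaced by ``nan`` in the interior, where the
    median imputation will handle them.
    """
    lo, hi = valid_range
    if not lo < hi:
        raise ValueError("valid_range must be a non-empty interval")
    ok = (trace.s0 >= lo) & (trace.s0 <= hi)
    idx = np.flatnonzero(ok)
    if idx.size == 0:
        raise ValueError("entire trace outside the valid range")
    start, stop = idx[0], idx[-1] + 1
    s0 = trace.s0[start:stop].copy()
    baseline = trace.baseline[start:stop].copy()
    interior_bad = ~ok[start:stop]
    s0[interior_bad] = np.nan
    return CtgTrace(s0=s0, baseline=baseline, sampling_rate=trace.sampling_rate)


def impute_median(signal: np.ndarray) -> np.ndarray:
    """Fill each missing segment with the median of the observed prefix.

    Segments are processed left to right, so the prefix feeding a later
    segment's median includes earlier imputed values.  The first sample must
    be observed (a signal cannot be anchored otherwise).
    """
    x = np.asarray(signal, dtype=float).copy()
    if x.size == 0:
        return x
    if np.isnan(x[0]):
        raise ValueError("signal starts with a missing value; no prefix to impute from")
    missing = np.isnan(x)
    i = 0
    n = x.size
    while i < n:
        if missing[i]:
            st = i
            while i < n and missing[i]:
                i += 1
            x[st:i] = np.median(x[:st])
        else:
            i += 1
    return x


def decentralize(s0: np.ndarray, baseline: np.ndarray) -> np.ndarray:
    """``D(t) = S0(t) - B(t)`` elementwise."""
    s0 = np.asarray(s0, dtype=float)
    baseline = np.asarray(baseline, dtype=float)
    if s0.shape != baseline.shape:
        raise ValueError(f"length mismatch: {s0.shape} vs {baseline.shape}")
    if np.isnan(s0).any() or np.isnan(baseline).any():
        raise ValueError("decentralize requires fully imputed inputs")
    return s0 - baseline


def estimate_baseline(s0: np.ndarray, sampling_rate: float,
                      window_s: float = 600.0) -> np.ndarray:
    """Rolling-median baseline estimate for traces recorded without one."""
    win = max(3, int(round(window_s * sampling_rate)) | 1)  # odd width
    return (
        pd.Series(s0).rolling(win, center=True, min_periods=1).median().to_numpy()
    )


def _train_subset(table: pd.DataFrame, split) -> pd.DataFrame:
    if split is None:
        return table
    mask = np.asarray(split) == "train"
    if not mask.any():
        raise ValueError("no training rows to fit statistics on")
    return table.loc[mask]


def impute_clinical_mean(table: pd.DataFrame, split=None) -> pd.DataFrame:
    """Replace missing clinical cells with the training-partition column mean.

    ``split`` is an optional per-row array with values in
    {train, validation, test}; when omitted, means are fit on all rows.
    """
    train = _train_subset(table, split)
    out = table.copy()
    for col in table.columns:
        if not pd.api.types.is_numeric_dtype(table[col]):
            continue
        observed = train[col].dropna()
        if observed.empty:
            raise ValueError(f"column {col!r} has no observed training values")
        out[col] = out[col].fillna(float(observed.mean()))
    return out


def standardize_clinical(table: pd.DataFrame,
                         split=None) -> tuple[pd.DataFrame, dict[str, float]]:
    """Zero-mean shift of each clinical column by its training-partition mean.

    Returns the shifted table and the means, which invert the transform and
    let new partitions be shifted consistently.  No variance scaling is
    applied; the conditioning step is a pure mean removal.
    """
    if table.isna().any().any():
        raise ValueError("standardize_clinical requires imputed input")
    train = _train_subset(table, split)
    means = {col: float(train[col].mean()) for col in table.columns
             if pd.api.types.is_numeric_dtype(table[col])}
    out = table.copy()
    for col, mu in means.items():
        out[col] = table[col] - mu
    return out, means


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal True runs of ``mask`` as (start, stop) index pairs."""
    out = []
    i, n = 0, mask.size
    while i < n:
        if mask[i]:
            st = i
            while i < n and mask[i]:
                i += 1
            out.append((st, i))
        else:
            i += 1
    return out


def _classify_deceleration(dev: np.ndarray, start: int, stop: int,
                           sampling_rate: float, *,
                           prolonged_s: float, abrupt_onset_s: float,
                           late_min_s: float, edge_bpm: float = 1.0) -> str:
    # the threshold run misses the excursion's shoulders; walk outward to
    # where the signal leaves the baseline so duration and onset slope are
    # measured on the whole event
    while start > 0 and dev[start - 1] <= -edge_bpm:
        start -= 1
    while stop < dev.size and dev[stop] <= -edge_bpm:
        stop += 1
    duration = (stop - start) / sampling_rate
    if duration >= prolonged_s:
        return "prolonged"
    nadir = start + int(np.argmin(dev[start:stop]))
    onset = (nadir - start) / sampling_rate
    if onset <= abrupt_onset_s:
        return "variable"
    return "late" if duration >= late_min_s else "early"


def summarize_trace(trace: CtgTrace, window_s: float = 1200.0, *,
                    excursion_bpm: float = 15.0, accel_min_s: float = 15.0,
                    decel_min_s: float = 15.0, prolonged_s: float = 120.0,
                    abrupt_onset_s: float = 30.0, late_min_s: float = 60.0,
                    min_duration_s: float = 60.0) -> TraceSummary:
    """Recover the four tabular CTG features from a cleaned, imputed trace.

    * baseline: median FHR over the analysis window;
    * variability: 10th-90th percentile spread of the baseline-removed
      signal outside excursion events;
    * accelerations: excursions >= +``excursion_bpm`` lasting >= 15 s;
    * deceleration: the longest excursion <= -``excursion_bpm`` classified by
      duration and onset slope (prolonged >= 120 s; abrupt nadir ->
      variable; gradual >= 60 s -> late; gradual shorter -> early).

    The "regular" tabular category describes a repetition pattern relative
    to uterine activity, which a bare FHR trace cannot express; it is never
    emitted here.
    """
    if trace.duration < min_duration_s:
        raise ValueError(
            f"trace of {trace.duration:.0f}s is shorter than the {min_duration_s:.0f}s minimum window"
        )
    s0 = trace.s0
    if np.isnan(s0).any():
        raise ValueError("summarize_trace requires an imputed trace")
    n_win = min(trace.n, int(round(window_s * trace.sampling_rate)))
    s0 = s0[:n_win]
    baseline = float(np.median(s0))
    dev = s0 - baseline

    accel_mask = dev >= excursion_bpm
    min_accel = int(math.ceil(accel_min_s * trace.sampling_rate))
    accels = sum(1 for st, sp in _runs(accel_mask) if sp - st >= min_accel)

    decel_mask = dev <= -excursion_bpm
    min_decel = int(math.ceil(decel_min_s * trace.sampling_rate))
    decel_runs = [(st, sp) for st, sp in _runs(decel_mask) if sp - st >= min_decel]
    if not decel_runs:
        decel = "none"
    else:
        st, sp = max(decel_runs, key=lambda r: r[1] - r[0])
        decel = _classify_deceleration(
            dev, st, sp, trace.sampling_rate,
            prolonged_s=prolonged_s, abrupt_onset_s=abrupt_onset_s,
            late_min_s=late_min_s,
        )

    quiet = ~(accel_mask | decel_mask)
    if quiet.any():
        lo, hi = np.percentile(dev[quiet], [10.0, 90.0])
        variability = float(hi - lo)
    else:  # pragma: no cover - pathological all-excursion trace
        warnings.warn("no quiet segment; variability computed over full trace")
        lo, hi = np.percentile(dev, [10.0, 90.0])
        variability = float(hi - lo)

    return TraceSummary(
        fhr_baseline=baseline,
        baseline_variability=variability,
        accelerations=int(accels),
        deceleration=decel,
    )


def fuse_features(ctg_summaries: pd.DataFrame,
                  clinical_table: pd.DataFrame,
                  standardization_means: dict[str, float] | None = None) -> FeatureMatrix:
    """Column-concatenate CTG summary features and clinical features.

    The categorical deceleration column is expanded into a fixed-order
    one-hot block (all six levels always present), giving a stable numeric
    design matrix: 3 numeric CTG + 6 one-hot + clinical columns.
    """
    if len(ctg_summaries) != len(clinical_table):
        raise ValueError(
            f"row-count mismatch: {len(ctg_summaries)} CTG vs {len(clinical_table)} clinical"
        )
    ctg = ctg_summaries.reset_index(drop=True)
    clin = clinical_table.reset_index(drop=True)
    parts = []
    for col in ctg.columns:
        if col == "deceleration":
            for level in DECELERATION_LEVELS:
                parts.append(pd.Series(
                    (ctg[col] == level).astype(float), name=f"deceleration_{level}"
                ))
        else:
            parts.append(ctg[col].astype(float))
    for col in clin.columns:
        parts.append(clin[col].astype(float))
    frame = pd.concat(parts, axis=1) if parts else pd.DataFrame()
    return FeatureMatrix(frame=frame, standardization_means=dict(standardization_means or {}))
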