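"""Evaluation metrics and statistical model comparison.

Per-class precision/recall/F1 follow the usual one-vs-rest reductions of a
confusion matrix; ratios with a zero denominator are reported as NaN with a
warning, never silently coerced to 0 — this matters for minority classes
that a biased model never predicts.  Repeated-run statistics use the sample
standard deviation and a normal-approximation 95% confidence interval.
Paired model comparison offers McNemar's exact test (two-sided binomial on
the discordant counts, appropriate because minority-class discordant counts
are small) and percentile bootstrap confidence intervals of metric
differences over paired row resampling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = [
    "ConfusionMatrix",
    "Metrics",
    "RunStats",
    "confusion",
    "metrics",
    "metrics_table",
    "roc",
    "run_stats",
    "mcnemar",
    "bootstrap_diff_ci",
    "accuracy_fn",
]


@dataclass
class ConfusionMatrix:
    classes: tuple[str, ...]
    table: np.ndarray                   # [true, predicted] counts

    @property
    def total(self) -> int:
        return int(self.table.sum())

    def one_vs_rest(self, positive_class: str) -> tuple[int, int, int, int]:
        """(TP, FP, TN, FN) counts for one class against the rest."""
        i = self.classes.index(positive_class)
        tp = int(self.table[i, i])
        fp = int(self.table[:, i].sum() - tp)
        fn = int(self.table[i, :].sum() - tp)
        tn = self.total - tp - fp - fn
        return tp, fp, tn, fn

    def to_csv(self, path) -> None:
        import pandas as pd
        pd.DataFrame(self.table, index=list(self.classes),
                     columns=list(self.classes)).to_csv(path)


@dataclass(frozen=True)
class Metrics:
    accuracy: float
    precision: float
    recall: float
    f1: float


@dataclass(frozen=True)
class RunStats:
    mean: float
    sd: float | None
    ci: tuple[float, float] | None


def confusion(true_labels, pred_labels, class_order: tuple[str, ...]) -> ConfusionMatrix:
    true_labels = np.asarray(true_labels)
    pred_labels = np.asarray(pred_labels)
    if true_labels.shape != pred_labels.shape:
        raise ValueError("label arrays must have equal length")
    index = {cls: i for i, cls in enumerate(class_order)}
    table = np.zeros((len(class_order), len(class_order)), dtype=int)
    for t, p in zip(true_labels, pred_labels):
        if t not in index or p not in index:
            raise ValueError(f"label outside class order: {t!r} / {p!r}")
        table[index[t], index[p]] += 1
    return ConfusionMatrix(classes=tuple(class_order), table=table)


def _ratio(num: int, den: int, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator); reported as NaN")
        return float("nan")
    return num / den


def metrics(cm: ConfusionMatrix, positive_class: str) -> Metrics:
    """Accuracy, precision, recall and F1 for one positive class.

    accuracy = (TP+TN)/total, precision = TP/(TP+FP), recall = TP/(TP+FN),
    F1 = 2PR/(P+R); undefined ratios surface as NaN.
    """
    tp, fp, tn, fn = cm.one_vs_rest(positive_class)
    acc = _ratio(tp + tn, tp + fp + tn + fn, "accuracy")
    prec = _ratio(tp, tp + fp, f"precision[{positive_class}]")
    rec = _ratio(tp, tp + fn, f"recall[{positive_class}]")
    if np.isnan(prec) or np.isnan(rec) or prec + rec == 0:
        if prec == 0 and rec == 0:
            warnings.warn(f"F1[{positive_class}] undefined (P = R = 0); reported as NaN")
        f1 = float("nan")
    else:
        f1 = 2 * prec * rec / (prec + rec)
    return Metrics(accuracy=acc, precision=prec, recall=rec, f1=f1)


def metrics_table(cm: ConfusionMatrix) -> dict:
    """Overall accuracy plus the per-class one-vs-rest metric block."""
    total = cm.total
    overall = float(np.trace(cm.table)) / total if total else float("nan")
    per_class = {}
    for cls in cm.classes:
        m = metrics(cm, cls)
        per_class[cls] = {"precision": m.precision, "recall": m.recall, "f1": m.f1}
    return {"accuracy": overall, "per_class": per_class}


def roc(scores, true_labels, positive_label="abnormal"):
    """ROC points from sweeping every distinct threshold, plus trapezoid AUC."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(true_labels) == positive_label
    if y.all() or not y.any():
        raise ValueError("ROC requires both classes present")
    order = np.argsort(-scores, kind="stable")
    y = y[order]
    s = scores[order]
    tps = np.cumsum(y)
    fps = np.cumsum(~y)
    # keep the last point of each tied-score block
    distinct = np.r_[s[1:] != s[:-1], True]
    tpr = np.r_[0.0, tps[distinct] / y.sum()]
    fpr = np.r_[0.0, fps[distinct] / (~y).sum()]
    area = float(np.trapezoid(tpr, fpr))
    return list(zip(fpr.tolist(), tpr.tolist())), area


def run_stats(values, confidence: float = 0.95) -> RunStats:
    """Mean, sample sd and normal-approximation CI over repeated runs."""
    values = np.asarray(values, dtype=float)
    mean = float(values.mean())
    if values.size < 2:
        warnings.warn("fewer than 2 runs; sd and CI omitted")
        return RunStats(mean=mean, sd=None, ci=None)
    sd = float(values.std(ddof=1))
    z = float(sps.norm.ppf(0.5 + confidence / 2))
    half = z * sd / np.sqrt(values.size)
    return RunStats(mean=mean, sd=sd, ci=(mean - half, mean + half))


def mcnemar(pred_a, pred_b, true_labels) -> tuple[int, int, float]:
    """Exact McNemar test on two classifiers' paired predictions.

    b counts rows where A is correct and B wrong, c the converse; the
    p-value is the exact two-sided binomial probability of the observed
    split under equal error-trading (success probability 1/2), capped at 1.
    """
    pred_a = np.asarray(pred_a)
    pred_b = np.asarray(pred_b)
    true_labels = np.asarray(true_labels)
    if not (pred_a.shape == pred_b.shape == true_labels.shape):
        raise ValueError("prediction and truth arrays must align")
    a_ok = pred_a == true_labels
    b_ok = pred_b == true_labels
    b = int((a_ok & ~b_ok).sum())
    c = int((~a_ok & b_ok).sum())
    if b + c == 0:
        warnings.warn("no discordant pairs; McNemar p-value is 1")
        return b, c, 1.0
    p = float(sps.binomtest(min(b, c), b + c, 0.5, alternative="two-sided").pvalue)
    return b, c, min(p, 1.0)


def accuracy_fn(pred, true_labels) -> float:
    pred = np.asarray(pred)
    true_labels = np.asarray(true_labels)
    if pred.size == 0:
        return float("nan")
    return float((pred == true_labels).mean())


def bootstrap_diff_ci(metric_fn, pred_a, pred_b, true_labels,
                      resamples: int = 10_000, confidence: float = 0.95,
                      seed: int = 0) -> tuple[float, float]:
    """Percentile CI of metric(A) - metric(B) over paired row resampling.

    Rows are resampled with replacement jointly for both models, preserving
    the pairing.  Resamples on which the metric is undefined (NaN) are
    redrawn, with the redraw count reported in a warning.
    """
    pred_a = np.asarray(pred_a)
    pred_b = np.asarray(pred_b)
    true_labels = np.asarray(true_labels)
    n = true_labels.shape[0]
    if not (pred_a.shape[0] == pred_b.shape[0] == n):
        raise ValueError("prediction and truth arrays must align")
    rng = np.random.default_rng(seed)
    diffs = np.empty(resamples)
    redraws = 0
    for i in range(resamples):
        while True:
            idx = rng.integers(n, size=n)
            d = metric_fn(pred_a[idx], true_labels[idx]) - \
                metric_fn(pred_b[idx], true_labels[idx])
            if np.isfinite(d):
                diffs[i] = d
                break
            redraws += 1
            if redraws > 100 * resamples:  # pragma: no cover
                raise RuntimeError("metric undefined on nearly all resamples")
    if redraws:
        warnings.warn(f"redrew {redraws} degenerate bootstrap resamples")
    lo = (1 - confidence) / 2
    lower, upper = np.quantile(diffs, [lo, 1 - lo])
    return float(lower), float(upper)
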