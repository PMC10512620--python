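"""Classifier evaluation: confusion counts, binary and multi-class metrics,
one-vs-rest ROC curves and AUC.

Definitions (per class, one-vs-rest counts TP/TN/FP/FN):

    accuracy  = (TP + TN) / (TP + TN + FP + FN)
    recall    = TP / (TP + FN)
    precision = TP / (TP + FP)
    F-score   = 2 TP / (2 TP + FP + FN)
    MCC       = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(FP+TN)(FN+TN))

Multi-class aggregation is macro (unweighted mean of per-class one-vs-rest
values) by default — per-class behaviour is reported separately, so the
macro mean is the natural summary; a ``weighted`` flag is available.  The
multi-class MCC is the covariance-form generalisation computed from the
full K x K confusion matrix (for K = 2 it reduces exactly to the binary
formula), not an average of binary MCCs.  AUC is the Mann-Whitney
statistic of each class's score column (ties get half credit), averaged
over classes present in the data.

Zero-denominator convention, applied uniformly: any metric whose
denominator is empty (e.g. precision with no predicted positives) is 0,
with a ``UserWarning``.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.stats import rankdata

__all__ = [
    "ConfusionCounts", "BinaryMetrics", "MetricsReport",
    "confusion_matrix", "one_vs_rest_counts", "binary_metrics",
    "multiclass_mcc", "roc_auc_ovr", "roc_curve_points", "multiclass_report",
    "write_report_json", "write_confusion_csv", "write_roc_csv",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """One-vs-rest tallies for a single class."""

    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class BinaryMetrics:
    accuracy: float
    recall: float
    precision: float
    f_score: float
    mcc: float


@dataclass
class MetricsReport:
    """Overall + per-class metrics for a K-class evaluation."""

    accuracy: float
    precision: float
    recall: float
    f_score: float
    mcc: float
    auc: float
    per_class: list[dict] = field(default_factory=list)
    confusion: np.ndarray | None = None

    def to_dict(self) -> dict:
        d = asdict(self)
        d["confusion"] = None if self.confusion is None else self.confusion.tolist()
        return d


def _safe_div(num: float, den: float, what: str) -> float:
    if den == 0:
        warnings.warn(f"{what}: empty denominator, returning 0", stacklevel=3)
        return 0.0
    return num / den


def _validate_labels(y, k: int, name: str) -> np.ndarray:
    y = np.asarray(y)
    if y.size and (y.min() < 0 or y.max() >= k):
        bad = y[(y < 0) | (y >= k)][0]
        raise ValueError(f"{name} contains label {bad} outside [0, {k})")
    return y.astype(np.intp)


def confusion_matrix(y_true, y_pred, k: int) -> np.ndarray:
    """K x K matrix with entry (i, j) = #(true i, predicted j)."""
    y_true = _validate_labels(y_true, k, "y_true")
    y_pred = _validate_labels(y_pred, k, "y_pred")
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    cm = np.zeros((k, k), dtype=np.int64)
    np.add.at(cm, (y_true, y_pred), 1)
    return cm


def one_vs_rest_counts(y_true, y_pred, k: int) -> list[ConfusionCounts]:
    """Per-class TP/TN/FP/FN derived from the K x K confusion matrix."""
    cm = confusion_matrix(y_true, y_pred, k)
    total = int(cm.sum())
    out = []
    for c in range(k):
        tp = int(cm[c, c])
        fn = int(cm[c].sum() - tp)
        fp = int(cm[:, c].sum() - tp)
        out.append(ConfusionCounts(tp=tp, tn=total - tp - fn - fp, fp=fp, fn=fn))
    return out


def binary_metrics(c: ConfusionCounts) -> BinaryMetrics:
    """Accuracy, recall, precision, F-score and MCC from one set of counts."""
    if c.total == 0:
        raise ValueError("all counts are zero; nothing was evaluated")
    tp, tn, fp, fn = c.tp, c.tn, c.fp, c.fn
    accuracy = (tp + tn) / c.total
    recall = _safe_div(tp, tp + fn, "recall")
    precision = _safe_div(tp, tp + fp, "precision")
    f_score = _safe_div(2 * tp, 2 * tp + fp + fn, "f_score")
    den = float(tp + fp) * (tp + fn) * (fp + tn) * (fn + tn)
    mcc = _safe_div(float(tp) * tn - float(fp) * fn, np.sqrt(den), "mcc")
    return BinaryMetrics(accuracy, recall, precision, f_score, mcc)


def multiclass_mcc(cm: np.ndarray) -> float:
    """Covariance-form MCC from a K x K confusion matrix."""
    cm = np.asarray(cm, dtype=np.float64)
    t = cm.sum(axis=1)   # true-class supports
    p = cm.sum(axis=0)   # predicted-class totals
    s = cm.sum()
    c = np.trace(cm)
    num = c * s - t @ p
    den = np.sqrt((s * s - p @ p) * (s * s - t @ t))
    return _safe_div(num, den, "mcc")


def roc_auc_ovr(y_true, scores, k: int | None = None):
    """Per-class one-vs-rest AUC and their macro mean.

    AUC for class c is the Mann-Whitney statistic of that class's score
    column: the probability a random positive outranks a random negative,
    ties counting 1/2.  Classes absent from ``y_true`` get NaN and are
    excluded from the macro mean with a warning.
    """
    scores = np.asarray(scores, dtype=np.float64)
    if scores.ndim != 2:
        raise ValueError("scores must be (n_samples, n_classes)")
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    k = scores.shape[1] if k is None else k
    y_true = _validate_labels(y_true, k, "y_true")
    if y_true.shape[0] != scores.shape[0]:
        raise ValueError("y_true and scores must have equal length")
    aucs = np.full(k, np.nan)
    for c in range(k):
        pos = y_true == c
        n_pos = int(pos.sum())
        n_neg = y_true.size - n_pos
        if n_pos == 0 or n_neg == 0:
            warnings.warn(f"class {c} absent from y_true; AUC undefined",
                          stacklevel=2)
            continue
        ranks = rankdata(scores[:, c])          # average ranks -> 1/2 tie credit
        aucs[c] = (ranks[pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    valid = ~np.isnan(aucs)
    macro = float(aucs[valid].mean()) if valid.any() else float("nan")
    return aucs, macro


def roc_curve_points(y_true, scores_c, positive_class, k: int):
    """ROC points (fpr, tpr, threshold) for one class, threshold-swept
    over the observed scores, no interpolation."""
    y_true = _validate_labels(y_true, k, "y_true")
    s = np.asarray(scores_c, dtype=np.float64)
    pos = (y_true == positive_class)
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    order = np.argsort(-s, kind="stable")
    s_sorted, pos_sorted = s[order], pos[order]
    tps = np.cumsum(pos_sorted)
    fps = np.cumsum(~pos_sorted)
    # keep the last point of each tied-score run
    distinct = np.r_[s_sorted[1:] != s_sorted[:-1], True]
    tpr = np.r_[0.0, tps[distinct] / max(n_pos, 1)]
    fpr = np.r_[0.0, fps[distinct] / max(n_neg, 1)]
    thresholds = np.r_[np.inf, s_sorted[distinct]]
    return fpr, tpr, thresholds


def multiclass_report(y_true, y_pred, scores, k: int, *,
                      average: str = "macro") -> MetricsReport:
    """Full evaluation: overall accuracy, aggregated precision/recall/F,
    covariance-form MCC, macro one-vs-rest AUC, per-class table, confusion
    matrix.  ``scores`` rows must sum to 1 (softmax output)."""
    if average not in ("macro", "weighted"):
        raise ValueError(f"unknown average {average!r}")
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    scores = np.asarray(scores, dtype=np.float64)
    if not (y_true.shape[0] == y_pred.shape[0] == scores.shape[0]):
        raise ValueError("y_true, y_pred and scores must have equal length")
    if scores.shape[1] != k:
        raise ValueError(f"scores must have {k} columns, got {scores.shape[1]}")
    if not np.allclose(scores.sum(axis=1), 1.0, atol=1e-5):
        raise ValueError("score rows must sum to 1 (use softmax probabilities)")

    cm = confusion_matrix(y_true, y_pred, k)
    counts = one_vs_rest_counts(y_true, y_pred, k)
    per_class_metrics = [binary_metrics(c) for c in counts]
    aucs, macro_auc = roc_auc_ovr(y_true, scores, k)

    supports = cm.sum(axis=1).astype(np.float64)
    if average == "macro":
        w = np.ones(k) / k
    else:
        w = supports / supports.sum()
    precision = float(sum(wi * m.precision for wi, m in zip(w, per_class_metrics)))
    recall = float(sum(wi * m.recall for wi, m in zip(w, per_class_metrics)))
    f_score = float(sum(wi * m.f_score for wi, m in zip(w, per_class_metrics)))

    per_class = [
        {"class": c, "support": int(supports[c]), "auc": float(aucs[c]),
         **asdict(m)}
        for c, m in enumerate(per_class_metrics)
    ]
    return MetricsReport(
        accuracy=float(np.trace(cm) / cm.sum()),
        precision=precision,
        recall=recall,
        f_score=f_score,
        mcc=float(multiclass_mcc(cm)),
        auc=macro_auc,
        per_class=per_class,
        confusion=cm,
    )


# ---------------------------------------------------------------------------
# serialization

def write_report_json(report: MetricsReport, path):
    with open(path, "w") as fh:
        json.dump(report.to_dict(), fh, indent=2)


def write_confusion_csv(cm: np.ndarray, path, labels=None):
    k = cm.shape[0]
    labels = labels if labels is not None else [str(i) for i in range(k)]
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["true\\pred"] + list(labels))
        for i in range(k):
            w.writerow([labels[i]] + cm[i].tolist())


def write_roc_csv(y_true, scores, k: int, path_prefix):
    """One CSV per class: columns fpr, tpr, threshold."""
    scores = np.asarray(scores)
    paths = []
    for c in range(k):
        fpr, tpr, thr = roc_curve_points(y_true, scores[:, c], c, k)
        path = f"{path_prefix}_class{c}.csv"
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["fpr", "tpr", "threshold"])
            for row in zip(fpr, tpr, thr):
                w.writerow(row)
        paths.append(path)
    return paths
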