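"""Classifier evaluation: confusion matrix, derived rates, ROC and AUC,
and the per-feature-set comparison table.

The positive class is *abnormal* (disease-detection convention), so
sensitivity is the fraction of abnormal cases flagged abnormal and
specificity the fraction of normal cases cleared.  Rates with a zero
denominator are defined as 0 and a warning is issued.  The ROC curve is
traced over every distinct score of the abnormal output unit (ties grouped)
and the AUC is the trapezoidal area, which equals the Mann-Whitney
pair-counting statistic U / (n+ * n-).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ConfusionMatrix",
    "MetricSet",
    "ROCCurve",
    "confusion",
    "metrics",
    "roc",
    "plot_roc",
    "compare_feature_sets",
]

POSITIVE = "abnormal"
NEGATIVE = "normal"


@dataclass(frozen=True)
class ConfusionMatrix:
    """Counts with abnormal as the positive class."""

    TP: int
    FN: int
    TN: int
    FP: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FN, self.TN, self.FP) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.total < 1:
            raise ValueError("confusion matrix must count at least one case")

    @property
    def total(self) -> int:
        return self.TP + self.FN + self.TN + self.FP


def confusion(labels_true, labels_pred) -> ConfusionMatrix:
    """Count a confusion matrix from normal/abnormal label sequences."""
    t = np.asarray(labels_true)
    p = np.asarray(labels_pred)
    if t.shape != p.shape or t.size == 0:
        raise ValueError("label sequences must be equal-length and non-empty")
    bad = set(np.unique(np.concatenate([t, p]))) - {POSITIVE, NEGATIVE}
    if bad:
        raise ValueError(f"labels must be normal/abnormal, got {sorted(bad)}")
    return ConfusionMatrix(
        TP=int(np.sum((t == POSITIVE) & (p == POSITIVE))),
        FN=int(np.sum((t == POSITIVE) & (p == NEGATIVE))),
        TN=int(np.sum((t == NEGATIVE) & (p == NEGATIVE))),
        FP=int(np.sum((t == NEGATIVE) & (p == POSITIVE))),
    )


@dataclass(frozen=True)
class MetricSet:
    """Derived rates in [0, 1]; ``as_percent`` renders the reporting
    style (one decimal unless two are needed, e.g. 91.67)."""

    accuracy: float
    sensitivity: float
    specificity: float
    fpr: float
    fnr: float
    misclassification_rate: float

    def as_percent(self, decimals: int = 1) -> dict[str, float]:
        return {k: round(100.0 * v, decimals) for k, v in self.__dict__.items()}


def _rate(num: int, den: int, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name}: zero denominator, rate defined as 0")
        return 0.0
    return num / den


def metrics(cm: ConfusionMatrix) -> MetricSet:
    pos = cm.TP + cm.FN
    neg = cm.TN + cm.FP
    return MetricSet(
        accuracy=(cm.TP + cm.TN) / cm.total,
        sensitivity=_rate(cm.TP, pos, "sensitivity"),
        specificity=_rate(cm.TN, neg, "specificity"),
        fpr=_rate(cm.FP, neg, "false positive rate"),
        fnr=_rate(cm.FN, pos, "false negative rate"),
        misclassification_rate=(cm.FP + cm.FN) / cm.total,
    )


@dataclass
class ROCCurve:
    """(FPR, TPR) points from (0,0) to (1,1) plus the trapezoidal AUC."""

    points: np.ndarray          # (n_points, 2) columns FPR, TPR
    thresholds: np.ndarray
    auc: float


def roc(scores_abnormal, labels_true) -> ROCCurve:
    """ROC over all distinct thresholds of the abnormal-class score."""
    s = np.asarray(scores_abnormal, dtype=float)
    t = np.asarray(labels_true)
    n_pos = int(np.sum(t == POSITIVE))
    n_neg = int(np.sum(t == NEGATIVE))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC needs at least one case of each class")
    order = np.argsort(-s, kind="stable")
    s_sorted = s[order]
    is_pos = (t[order] == POSITIVE).astype(float)
    tp = np.cumsum(is_pos)
    fp = np.cumsum(1.0 - is_pos)
    # one point per distinct score: keep the last index of each tie group
    distinct = np.flatnonzero(np.diff(s_sorted) != 0)
    keep = np.concatenate([distinct, [len(s_sorted) - 1]])
    tpr = np.concatenate([[0.0], tp[keep] / n_pos])
    fpr = np.concatenate([[0.0], fp[keep] / n_neg])
    thresholds = np.concatenate([[np.inf], s_sorted[keep]])
    auc = float(np.trapezoid(tpr, fpr))
    return ROCCurve(points=np.column_stack([fpr, tpr]),
                    thresholds=thresholds, auc=auc)


def plot_roc(curve: ROCCurve, path, title: str = "ROC") -> None:
    """Write a ROC plot (TPR vs FPR with the chance diagonal) to ``path``."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot(curve.points[:, 0], curve.points[:, 1], "-o", ms=3,
            label=f"AUC = {curve.auc:.3f}")
    ax.plot([0, 1], [0, 1], "--", color="gray", lw=1)
    ax.set_xlabel("false positive rate (1 - specificity)")
    ax.set_ylabel("true positive rate (sensitivity)")
    ax.set_title(title)
    ax.legend(loc="lower right")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def compare_feature_sets(
    results: dict[str, tuple[MetricSet, MetricSet]]
) -> pd.DataFrame:
    """Comparison table across feature sets.

    ``results`` maps feature-set name -> (training MetricSet, testing
    MetricSet).  Columns carry accuracy/TPR/TNR/FNR percents for both
    stages; ``best`` flags the highest testing accuracy (all rows on a
    tie).
    """
    if not results:
        raise ValueError("need at least one feature set to compare")
    rows = []
    for name, (train_m, test_m) in results.items():
        rows.append({
            "feature_set": name,
            "train_accuracy": 100 * train_m.accuracy,
            "train_tpr": 100 * train_m.sensitivity,
            "train_tnr": 100 * train_m.specificity,
            "train_fnr": 100 * train_m.fnr,
            "test_accuracy": 100 * test_m.accuracy,
            "test_tpr": 100 * test_m.sensitivity,
            "test_tnr": 100 * test_m.specificity,
            "test_fnr": 100 * test_m.fnr,
        })
    df = pd.DataFrame(rows)
    best = df["test_accuracy"].max()
    df["best"] = df["test_accuracy"] == best
    return df
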