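"""Multiclass one-vs-rest evaluation metrics.

A K x K confusion matrix (rows = true class, columns = predicted class) is
binarized per class k — TP the diagonal cell, FN the rest of row k, FP the
rest of column k, TN everything else — and seven measures are computed per
class, all reported in percent:

    accuracy    (TP + TN) / total
    precision   TP / (TP + FP)
    recall      TP / (TP + FN)           (sensitivity)
    specificity TN / (TN + FP)
    F-score     2 precision recall / (precision + recall)
    MCC         (TP TN - FP FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))
    G-mean      sqrt(recall * specificity)

The macro row is the unweighted arithmetic mean over classes, computed on
unrounded per-class values.  Report rounding is half-up to 2 decimals, at
report time only.  A zero denominator yields 0.0 and sets a degenerate
flag instead of raising, so tiny synthetic runs with empty predicted
classes still produce a report.

The 8-class breast-histology label order used throughout the package is
(A, F, PT, TA, DC, LC, MC, PC): four benign subtypes (adenosis,
fibroadenoma, phyllodes tumor, tubular adenoma) then four malignant
(ductal, lobular, mucinous, papillary carcinoma).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

__all__ = [
    "CLASS_LABELS",
    "METRIC_NAMES",
    "MetricsReport",
    "build_confusion",
    "per_class_metrics",
    "macro_average",
    "overall_accuracy",
]

CLASS_LABELS = ("A", "F", "PT", "TA", "DC", "LC", "MC", "PC")
METRIC_NAMES = ("accuracy", "precision", "recall", "specificity",
                "f_score", "mcc", "g_mean")


def round_half_up(value: float, decimals: int = 2) -> float:
    """Round half away from zero at the given decimal place (report rule)."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


def build_confusion(y_true, y_pred, n_classes: int) -> np.ndarray:
    """Count matrix with counts[i, j] = #{true = i, predicted = j}."""
    t = np.asarray(y_true, dtype=int)
    p = np.asarray(y_pred, dtype=int)
    if t.shape != p.shape or t.ndim != 1:
        raise ValueError("y_true and y_pred must be equal-length 1-D label vectors")
    if t.size and (t.min() < 0 or t.max() >= n_classes
                   or p.min() < 0 or p.max() >= n_classes):
        raise ValueError(f"labels must lie in [0, {n_classes})")
    cm = np.zeros((n_classes, n_classes), dtype=int)
    np.add.at(cm, (t, p), 1)
    return cm


@dataclass
class MetricsReport:
    """Per-class metric table in percent, plus the macro (unweighted mean) row.

    ``table`` has one row per class and one column per metric, unrounded;
    ``degenerate`` flags classes where some denominator was zero.
    """

    table: pd.DataFrame
    macro: pd.Series
    confusion: np.ndarray
    degenerate: list[str] = field(default_factory=list)

    def rounded(self, decimals: int = 2) -> pd.DataFrame:
        """Report-ready table (class rows + Average) rounded half-up."""
        out = self.table.copy()
        out.loc["Average"] = self.macro
        return out.map(lambda v: round_half_up(v, decimals))

    def to_csv(self, path) -> None:
        self.rounded().to_csv(path, index_label="class")

    def to_dict(self) -> dict:
        return {
            "per_class": {idx: {m: round_half_up(v) for m, v in row.items()}
                          for idx, row in self.table.iterrows()},
            "average": {m: round_half_up(v) for m, v in self.macro.items()},
            "degenerate_classes": list(self.degenerate),
        }


def _safe_div(num: float, den: float, flags: list, label: str) -> float:
    if den == 0:
        flags.append(label)
        return 0.0
    return num / den


def per_class_metrics(cm: np.ndarray, labels=None) -> MetricsReport:
    """One-vs-rest metric table from a confusion matrix, in percent."""
    cm = np.asarray(cm)
    if cm.ndim != 2 or cm.shape[0] != cm.shape[1] or cm.size == 0:
        raise ValueError("confusion matrix must be a nonempty square matrix")
    K = cm.shape[0]
    if labels is None:
        labels = CLASS_LABELS if K == len(CLASS_LABELS) else tuple(str(k) for k in range(K))
    total = cm.sum()
    rows = {}
    degenerate: list[str] = []
    for k in range(K):
        tp = float(cm[k, k])
        fn = float(cm[k, :].sum() - tp)
        fp = float(cm[:, k].sum() - tp)
        tn = float(total - tp - fn - fp)
        flags: list[str] = []
        acc = _safe_div(tp + tn, total, flags, "accuracy")
        prec = _safe_div(tp, tp + fp, flags, "precision")
        rec = _safe_div(tp, tp + fn, flags, "recall")
        spec = _safe_div(tn, tn + fp, flags, "specificity")
        f1 = _safe_div(2.0 * prec * rec, prec + rec, flags, "f_score")
        mcc_den = np.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
        mcc = _safe_div(tp * tn - fp * fn, mcc_den, flags, "mcc")
        gmean = np.sqrt(rec * spec)
        rows[labels[k]] = [100.0 * acc, 100.0 * prec, 100.0 * rec, 100.0 * spec,
                           100.0 * f1, 100.0 * mcc, 100.0 * gmean]
        if flags:
            degenerate.append(labels[k])
    table = pd.DataFrame.from_dict(rows, orient="index", columns=METRIC_NAMES)
    macro = table.mean(axis=0)
    return MetricsReport(table=table, macro=macro, confusion=cm,
                         degenerate=degenerate)


def macro_average(report: MetricsReport) -> pd.Series:
    """Unweighted mean of each metric over classes (the report's Average row)."""
    return report.table.mean(axis=0)


def overall_accuracy(cm: np.ndarray) -> float:
    """Overall (micro) accuracy in percent: trace / total.  Complements the
    error-rate fitness exactly: overall_accuracy = 100 - error rate."""
    cm = np.asarray(cm)
    total = cm.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    return 100.0 * float(np.trace(cm)) / float(total)
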