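"""Binary confusion-matrix metrics and ROC analysis.

Implements the full evaluation column set used for the nodule tasks:
accuracy, recall (sensitivity), precision, specificity, F1 and the Matthews
correlation coefficient (MCC), plus a threshold-sweep ROC curve with
trapezoidal AUC.  Ratios with zero denominators are reported as NaN with an
``undefined`` flag rather than silently coerced to 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["BinaryMetrics", "confusion_and_metrics", "f1_from_precision_recall", "roc_auc"]


@dataclass
class BinaryMetrics:
    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float
    recall: float
    precision: float
    specificity: float
    f1: float
    mcc: float
    undefined: list[str] = field(default_factory=list)

    def to_row(self) -> dict:
        """Row matching the standard results-table column set (percentages)."""
        return {
            "Accuracy (%)": 100.0 * self.accuracy,
            "Recall(Sensitivity) (%)": 100.0 * self.recall,
            "Precision (%)": 100.0 * self.precision,
            "F1 Score": self.f1,
            "MMC": self.mcc,
        }


def _safe_div(num: float, den: float, name: str, undefined: list[str]) -> float:
    if den == 0:
        undefined.append(name)
        return float("nan")
    return num / den


def f1_from_precision_recall(precision: float, recall: float) -> float:
    """F1 = 2PR/(P+R), the harmonic mean of precision and recall.

    Accepts either fractions or percentages (the ratio is scale-free).
    """
    if precision + recall == 0:
        return float("nan")
    return 2.0 * precision * recall / (precision + recall)


def confusion_and_metrics(y_pred, y_true, positive: int = 1) -> BinaryMetrics:
    """Confusion counts and derived metrics for binary predictions."""
    y_pred = np.asarray(y_pred)
    y_true = np.asarray(y_true)
    if y_pred.shape != y_true.shape:
        raise ValueError("prediction/label length mismatch")
    if y_pred.size == 0:
        raise ValueError("empty input")
    p = y_pred == positive
    t = y_true == positive
    tp = int(np.sum(p & t))
    fp = int(np.sum(p & ~t))
    tn = int(np.sum(~p & ~t))
    fn = int(np.sum(~p & t))

    undefined: list[str] = []
    accuracy = (tp + tn) / (tp + tn + fp + fn)
    recall = _safe_div(tp, tp + fn, "recall", undefined)
    precision = _safe_div(tp, tp + fp, "precision", undefined)
    specificity = _safe_div(tn, tn + fp, "specificity", undefined)
    if np.isnan(precision) or np.isnan(recall) or precision + recall == 0:
        undefined.append("f1")
        f1 = float("nan")
    else:
        f1 = f1_from_precision_recall(precision, recall)
    mcc_den = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if mcc_den == 0:
        undefined.append("mcc")
        mcc = float("nan")
    else:
        mcc = (tp * tn - fp * fn) / np.sqrt(mcc_den)
    return BinaryMetrics(
        tp=tp, fp=fp, tn=tn, fn=fn,
        accuracy=accuracy, recall=recall, precision=precision,
        specificity=specificity, f1=f1, mcc=float(mcc), undefined=undefined,
    )


def roc_auc(scores, y_true, positive: int = 1):
    """ROC curve by threshold sweep over the unique scores, trapezoidal AUC.

    Returns (fpr, tpr, auc).  Tied scores move together through the sweep, so
    ties contribute half (the trapezoid cuts diagonally across a tied block);
    all-equal scores give AUC 0.5.
    """
    scores = np.asarray(scores, dtype=np.float64)
    y_true = np.asarray(y_true)
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    t = (y_true == positive).astype(np.float64)
    n_pos = t.sum()
    n_neg = len(t) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("need both classes present for a ROC curve")
    order = np.argsort(-scores, kind="stable")
    s_sorted = scores[order]
    t_sorted = t[order]
    # cumulative counts at each distinct-threshold boundary
    distinct = np.r_[np.nonzero(np.diff(s_sorted))[0], len(s_sorted) - 1]
    tps = np.cumsum(t_sorted)[distinct]
    fps = np.cumsum(1.0 - t_sorted)[distinct]
    tpr = np.r_[0.0, tps / n_pos]
    fpr = np.r_[0.0, fps / n_neg]
    auc = float(np.trapezoid(tpr, fpr))
    return fpr, tpr, auc
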