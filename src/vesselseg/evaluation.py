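"""Pixel-level segmentation metrics: confusion counts, Se, Ac, F1, AUC.

Vessel pixels are the positive class.  With TP/FP/TN/FN counted over the
evaluated pixels (inside the field-of-view mask when one is supplied):

    Se = TP / (TP + FN)                  sensitivity (recall)
    Ac = (TP + TN) / (TP + FP + TN + FN) accuracy
    F1 = 2 * Prec * Se / (Prec + Se),    Prec = TP / (TP + FP)

AUC is the area under the ROC curve of the soft scores, equivalently the
Mann-Whitney probability that a random vessel pixel outscores a random
background pixel.  Metrics with a zero denominator are reported as None
rather than silently coerced to 0.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from sklearn.metrics import roc_auc_score, roc_curve

__all__ = ["ConfusionCounts", "MetricsReport", "confusion", "metrics",
           "roc_auc", "evaluate_pair"]


class DimensionError(ValueError):
    pass


@dataclasses.dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclasses.dataclass
class MetricsReport:
    se: float | None
    ac: float | None
    f1: float | None
    auc: float | None = None


def _masked(arr: np.ndarray, fov: np.ndarray | None) -> np.ndarray:
    if fov is None:
        return arr.ravel()
    return arr[fov.astype(bool)]


def confusion(pred: np.ndarray, truth: np.ndarray,
              fov: np.ndarray | None = None) -> ConfusionCounts:
    """Count TP/FP/TN/FN of a binary prediction against a binary truth."""
    pred, truth = np.asarray(pred), np.asarray(truth)
    if pred.shape != truth.shape or (fov is not None and fov.shape != pred.shape):
        raise DimensionError(
            f"shape mismatch: pred {pred.shape}, truth {truth.shape}")
    p = _masked(pred, fov).astype(bool)
    t = _masked(truth, fov).astype(bool)
    tp = int(np.count_nonzero(p & t))
    fp = int(np.count_nonzero(p & ~t))
    fn = int(np.count_nonzero(~p & t))
    tn = int(np.count_nonzero(~p & ~t))
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def _ratio(num: int, den: int) -> float | None:
    return num / den if den > 0 else None


def metrics(c: ConfusionCounts) -> MetricsReport:
    """Sensitivity, accuracy and F1 from confusion counts."""
    se = _ratio(c.tp, c.tp + c.fn)
    ac = _ratio(c.tp + c.tn, c.total)
    prec = _ratio(c.tp, c.tp + c.fp)
    if se is None or prec is None or se + prec == 0:
        f1 = None
    else:
        f1 = 2.0 * prec * se / (prec + se)
    return MetricsReport(se=se, ac=ac, f1=f1)


def roc_auc(scores: np.ndarray, truth: np.ndarray,
            fov: np.ndarray | None = None) -> float | None:
    """Trapezoidal area under the ROC curve; None for single-class truth."""
    scores, truth = np.asarray(scores), np.asarray(truth)
    if scores.shape != truth.shape:
        raise DimensionError(
            f"shape mismatch: scores {scores.shape}, truth {truth.shape}")
    s = _masked(scores, fov).astype(np.float64)
    t = _masked(truth, fov).astype(int)
    if t.min() == t.max():
        return None
    return float(roc_auc_score(t, s))


def roc_points(scores: np.ndarray, truth: np.ndarray,
               fov: np.ndarray | None = None):
    """(FPR, TPR, thresholds) of the ROC curve, for plotting or export."""
    s = _masked(np.asarray(scores), fov)
    t = _masked(np.asarray(truth), fov).astype(int)
    fpr, tpr, thr = roc_curve(t, s)
    return fpr, tpr, thr


def evaluate_pair(scores: np.ndarray, truth: np.ndarray,
                  fov: np.ndarray | None = None,
                  threshold: float = 0.5) -> MetricsReport:
    """Full report for one image: threshold at 0.5, then Se/Ac/F1 + AUC."""
    pred = np.asarray(scores) >= threshold
    report = metrics(confusion(pred, truth, fov))
    report.auc = roc_auc(scores, truth, fov)
    return report
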