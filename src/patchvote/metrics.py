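"""Classification and segmentation metrics.

Sensitivity, specificity and F1 follow the usual confusion-matrix
definitions; a metric whose denominator is zero is reported as missing
(``None``) rather than silently set to 0.  AUC is the probability that a
random positive is ranked above a random negative (ties count 1/2),
computed via scikit-learn's rank-based estimator.  IoU is the Jaccard
coefficient |A ∩ B| / |A ∪ B| with the convention that two empty masks
agree perfectly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import roc_auc_score

__all__ = ["ConfusionCounts", "MetricsReport", "confusion_metrics", "auc",
           "iou", "grid_to_mask"]


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        for name in ("tp", "fp", "tn", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @classmethod
    def from_predictions(cls, pred: np.ndarray, truth: np.ndarray) -> "ConfusionCounts":
        pred = np.asarray(pred).astype(bool)
        truth = np.asarray(truth).astype(bool)
        return cls(tp=int((pred & truth).sum()), fp=int((pred & ~truth).sum()),
                   tn=int((~pred & ~truth).sum()), fn=int((~pred & truth).sum()))


@dataclass
class MetricsReport:
    auc: float | None
    f1: float | None
    sensitivity: float | None
    specificity: float | None
    iou: float | None
    n_eval: int

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("auc", "f1", "sensitivity", "specificity", "iou", "n_eval")}


def confusion_metrics(c: ConfusionCounts) -> dict[str, float | None]:
    """sensitivity = TP/(TP+FN), specificity = TN/(TN+FP),
    F1 = 2TP/(2TP+FP+FN); zero denominators yield None."""
    sens = c.tp / (c.tp + c.fn) if (c.tp + c.fn) else None
    spec = c.tn / (c.tn + c.fp) if (c.tn + c.fp) else None
    f1 = 2 * c.tp / (2 * c.tp + c.fp + c.fn) if (2 * c.tp + c.fp + c.fn) else None
    return {"sensitivity": sens, "specificity": spec, "f1": f1}


def auc(scores, labels) -> float:
    """Rank-based AUC with ties counted one half."""
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ValueError("AUC requires both classes present")
    return float(roc_auc_score(labels, np.asarray(scores)))


def iou(pred_mask, true_mask) -> float:
    """Jaccard coefficient; both-empty masks score 1."""
    a = np.asarray(pred_mask).astype(bool)
    b = np.asarray(true_mask).astype(bool)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    union = (a | b).sum()
    if union == 0:
        return 1.0
    return float((a & b).sum() / union)


def grid_to_mask(grid, threshold: float = 0.5, stride: int = 16) -> np.ndarray:
    """Patch-probability grid -> pixel mask.

    Nearest-neighbour upsampling by ``stride`` followed by ``>= threshold``
    binarization (so a probability exactly at the threshold is positive).
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    probs = np.asarray(grid.probs if hasattr(grid, "probs") else grid,
                       dtype=np.float64)
    up = np.repeat(np.repeat(probs, stride, axis=0), stride, axis=1)
    return up >= threshold
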