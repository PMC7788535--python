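"""Ranking metrics shared by classifier cross-validation and the GSEA benchmark.

Thin validated wrappers over ``sklearn.metrics``: AUROC uses the
Mann-Whitney formulation (ties credited 1/2), average precision uses the
step-interpolated precision-recall definition with tied scores grouped.
"""

from __future__ import annotations

import numpy as np
from sklearn import metrics as _skm

from .io import ValidationError

__all__ = ["auroc", "average_precision", "roc_curve", "pr_curve"]


def _validate(scores, labels, need_both: bool = True) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.ndim != 1 or scores.shape != labels.shape or scores.size == 0:
        raise ValidationError("scores and labels must be equal-length non-empty 1-D")
    if not np.isfinite(scores).all():
        raise ValidationError("scores contain non-finite values")
    if set(np.unique(labels)) - {0, 1}:
        raise ValidationError("labels must be 0/1")
    if need_both and len(np.unique(labels)) < 2:
        raise ValidationError("metric undefined: only one class present")
    return scores, labels


def auroc(scores, labels) -> float:
    """Probability that a random positive outscores a random negative."""
    scores, labels = _validate(scores, labels)
    return float(_skm.roc_auc_score(labels, scores))


def average_precision(scores, labels) -> float:
    """Average precision of the precision-recall curve (AP score)."""
    scores, labels = _validate(scores, labels, need_both=False)
    if labels.sum() == 0:
        raise ValidationError("average precision undefined: no positives")
    return float(_skm.average_precision_score(labels, scores))


def roc_curve(scores, labels) -> list[tuple[float, float]]:
    """(fpr, tpr) points from (0, 0) to (1, 1), tied scores grouped."""
    scores, labels = _validate(scores, labels)
    fpr, tpr, _ = _skm.roc_curve(labels, scores, drop_intermediate=False)
    return list(zip(fpr.tolist(), tpr.tolist()))


def pr_curve(scores, labels) -> list[tuple[float, float]]:
    """(recall, precision) points of the precision-recall curve."""
    scores, labels = _validate(scores, labels)
    precision, recall, _ = _skm.precision_recall_curve(labels, scores)
    return list(zip(recall.tolist(), precision.tolist()))
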