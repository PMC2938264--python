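"""Single-marker receiver-operating-characteristic analysis.

The AUC of a marker equals the probability that a randomly chosen positive
sample scores higher than a randomly chosen negative one (ties count one
half, the Mann-Whitney convention).  Orientation is explicit and never
auto-flipped: an AUC below 0.5 is reported as-is, since direction is
informative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn import metrics as _skm

from .errors import UndefinedValueError

__all__ = ["RocCurve", "roc_curve", "auc_rank_oracle"]


@dataclass
class RocCurve:
    """ROC curve points (thresholds descending in score order) plus AUC."""

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    positive_label: str
    orientation: str


def _validate(scores, labels, positive_label):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise UndefinedValueError("scores and labels must be matching 1-d vectors")
    if not np.isfinite(scores).all():
        raise UndefinedValueError("scores must be finite")
    y = labels == positive_label
    if y.all() or not y.any():
        raise UndefinedValueError("ROC undefined: both classes must be present")
    return scores, y


def roc_curve(
    scores,
    labels,
    positive_label: str = "case",
    orientation: str = "greater",
) -> RocCurve:
    """ROC curve over all distinct score thresholds, AUC by trapezoid.

    ``orientation="greater"`` means high scores indicate the positive
    class; ``"less"`` the reverse.  Tied scores are grouped at a single
    threshold; the curve runs from (0, 0) to (1, 1).
    """
    if orientation not in ("greater", "less"):
        raise UndefinedValueError(f"unknown orientation {orientation!r}")
    scores, y = _validate(scores, labels, positive_label)
    oriented = scores if orientation == "greater" else -scores
    fpr, tpr, thr = _skm.roc_curve(y, oriented, drop_intermediate=False)
    thresholds = thr if orientation == "greater" else -thr
    return RocCurve(
        thresholds=thresholds,
        fpr=fpr,
        tpr=tpr,
        auc=float(_skm.auc(fpr, tpr)),
        positive_label=str(positive_label),
        orientation=orientation,
    )


def auc_rank_oracle(scores, labels, positive_label: str = "case") -> float:
    """Exact pairwise AUC: (#{pos > neg} + 0.5 #{pos = neg}) / (n+ * n-).

    Independent of the curve construction; used as the rank-statistic
    cross-check for :func:`roc_curve`.
    """
    scores, y = _validate(scores, labels, positive_label)
    pos = scores[y][:, None]
    neg = scores[~y][None, :]
    wins = np.count_nonzero(pos > neg)
    ties = np.count_nonzero(pos == neg)
    return float((wins + 0.5 * ties) / (pos.shape[0] * neg.shape[1]))
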