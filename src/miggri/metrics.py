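"""Link-prediction evaluation: confusion counts, accuracy, F1, ROC and AUC.

    accuracy = (TP + TN) / (TP + FP + TN + FN)
    F1       = 2 TP / (2 TP + FP + FN)

The ROC curve sweeps every distinct score as a cutpoint; AUC is the
trapezoid area, which equals the rank statistic P(score_pos > score_neg)
with ties counted 1/2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["MetricsReport", "compute_metrics", "roc_curve"]


@dataclass
class MetricsReport:
    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float
    f1: float
    roc_points: list = field(repr=False, default_factory=list)  # (fpr, tpr)
    auc: float | None = None

    def as_dict(self) -> dict:
        return {
            "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
            "accuracy": self.accuracy, "f1": self.f1, "auc": self.auc,
        }


def _split_scores(scored) -> tuple[np.ndarray, np.ndarray]:
    pairs = list(scored)
    labels = np.array([int(l) for l, _ in pairs])
    scores = np.array([float(s) for _, s in pairs])
    return labels, scores


def roc_curve(labels: np.ndarray, scores: np.ndarray):
    """ROC points from sweeping all distinct score cutpoints (desc), plus endpoints."""
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    order = np.argsort(-scores, kind="stable")
    s_sorted = scores[order]
    l_sorted = labels[order]
    tps = np.cumsum(l_sorted)
    fps = np.cumsum(1 - l_sorted)
    # keep only the last index of each tied-score run
    distinct = np.flatnonzero(np.diff(s_sorted, append=-np.inf))
    points = [(0.0, 0.0)] + [
        (fps[i] / n_neg, tps[i] / n_pos) for i in distinct
    ]
    return points


def compute_metrics(scored, threshold: float = 0.5, with_auc: bool = True) -> MetricsReport:
    """Evaluate (label, score) pairs at a hard threshold and over the ROC sweep.

    A score >= threshold is called positive.  AUC requires both classes:
    single-class input raises unless ``with_auc=False``, in which case the
    threshold metrics are returned with ``auc=None``.
    """
    labels, scores = _split_scores(scored)
    if len(labels) == 0:
        raise ValueError("no scored pairs given")
    calls = (scores >= threshold).astype(int)
    tp = int(np.sum((calls == 1) & (labels == 1)))
    fp = int(np.sum((calls == 1) & (labels == 0)))
    tn = int(np.sum((calls == 0) & (labels == 0)))
    fn = int(np.sum((calls == 0) & (labels == 1)))
    accuracy = (tp + tn) / len(labels)
    f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) > 0 else 0.0

    n_pos, n_neg = int(labels.sum()), int((1 - labels).sum())
    if n_pos == 0 or n_neg == 0:
        if not with_auc:
            return MetricsReport(tp=tp, fp=fp, tn=tn, fn=fn,
                                 accuracy=accuracy, f1=f1, auc=None)
        raise ValueError("AUC undefined: scores contain a single class")
    points = roc_curve(labels, scores)
    fpr = np.array([p[0] for p in points])
    tpr = np.array([p[1] for p in points])
    auc = float(np.trapezoid(tpr, fpr))
    return MetricsReport(
        tp=tp, fp=fp, tn=tn, fn=fn, accuracy=accuracy, f1=f1,
        roc_points=points, auc=auc,
    )
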