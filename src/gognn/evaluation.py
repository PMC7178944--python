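"""Imbalance-aware link-prediction metrics.

ROC-AUC equals the Mann–Whitney statistic P(score_pos > score_neg) + half
the tie probability and is insensitive to class prevalence; PR-AUC
(average-precision convention, step-wise, no linear interpolation) is the
metric of choice on sparse networks where negatives dominate.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score


@dataclass
class MetricsReport:
    roc_auc: float
    pr_auc: float
    n_pos: int
    n_neg: int
    positive_fraction: float

    def to_dict(self) -> dict:
        return asdict(self)


def _check(scores, labels):
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-d arrays")
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be binary")
    return scores, labels.astype(np.intp)


def roc_auc(scores, labels) -> float:
    """Midrank ROC-AUC; requires both classes present."""
    scores, labels = _check(scores, labels)
    if labels.min() == labels.max():
        raise ValueError("ROC-AUC undefined with a single class")
    return float(roc_auc_score(labels, scores))


def pr_auc(scores, labels) -> float:
    """Average precision (step-wise PR-AUC); requires positives present."""
    scores, labels = _check(scores, labels)
    if labels.sum() == 0:
        raise ValueError("PR-AUC undefined without positives")
    return float(average_precision_score(labels, scores))


def evaluate_scores(scores, labels) -> MetricsReport:
    scores, labels = _check(scores, labels)
    n_pos = int(labels.sum())
    n_neg = int(len(labels) - n_pos)
    return MetricsReport(
        roc_auc=roc_auc(scores, labels),
        pr_auc=pr_auc(scores, labels),
        n_pos=n_pos,
        n_neg=n_neg,
        positive_fraction=n_pos / len(labels),
    )
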