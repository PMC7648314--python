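"""Evaluation statistics for EPI prediction.

Six statistics are reported: accuracy, precision, recall, F1 (computed from
the confusion table at a fixed threshold, default 0.5, with score >= threshold
counted as a positive call), plus the threshold-free AUC (area under the ROC
curve, computed by the rank / Mann-Whitney formulation with midranks for tied
scores) and AUPR (area under the precision-recall curve by step-wise,
non-interpolated integration).  Ratios with a zero denominator are reported
as 0 and flagged rather than NaN.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
import numpy as np
from scipy.stats import rankdata


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class MetricsReport:
    accuracy: float
    precision: float
    recall: float
    f1: float
    auc: float
    aupr: float
    threshold: float
    n_samples: int
    degenerate: tuple[str, ...] = ()  # metrics whose denominator was zero

    def to_json(self) -> str:
        d = asdict(self)
        d["degenerate"] = list(self.degenerate)
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "MetricsReport":
        d = json.loads(text)
        d["degenerate"] = tuple(d.get("degenerate", ()))
        return cls(**d)


def _validate(labels, scores):
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if labels.shape != scores.shape or labels.ndim != 1:
        raise ValueError(f"labels {labels.shape} and scores {scores.shape} must be equal-length 1-D")
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be 0/1")
    return labels.astype(int), scores


def confusion_counts(labels, scores, threshold: float = 0.5) -> ConfusionCounts:
    """Tally the confusion table; ``score >= threshold`` predicts positive."""
    labels, scores = _validate(labels, scores)
    pred = scores >= threshold
    pos = labels == 1
    return ConfusionCounts(
        tp=int(np.sum(pred & pos)),
        tn=int(np.sum(~pred & ~pos)),
        fp=int(np.sum(pred & ~pos)),
        fn=int(np.sum(~pred & pos)),
    )


def point_metrics(counts: ConfusionCounts) -> tuple[float, float, float, float, tuple[str, ...]]:
    """Accuracy, precision, recall, F1 from the confusion table.

    accuracy  = (TP+TN) / (TP+TN+FN+FP)
    precision = TP / (TP+FP)
    recall    = TP / (TP+FN)
    F1        = 2 * precision * recall / (precision + recall)

    Returns the four statistics plus the names of any that had a zero
    denominator (reported as 0).
    """
    if counts.total == 0:
        raise ValueError("cannot compute metrics on zero samples")
    degenerate = []

    def ratio(num, den, name):
        if den == 0:
            degenerate.append(name)
            return 0.0
        return num / den

    accuracy = (counts.tp + counts.tn) / counts.total
    precision = ratio(counts.tp, counts.tp + counts.fp, "precision")
    recall = ratio(counts.tp, counts.tp + counts.fn, "recall")
    f1 = ratio(2 * precision * recall, precision + recall, "f1")
    return accuracy, precision, recall, f1, tuple(degenerate)


def roc_auc(labels, scores) -> float:
    """AUC by the rank (Mann-Whitney U) formulation; ties get midranks."""
    labels, scores = _validate(labels, scores)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: both classes must be present")
    ranks = rankdata(scores)  # average (mid) ranks for ties
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def pr_auc(labels, scores) -> float:
    """Area under the precision-recall curve, step-wise integration.

    Thresholds sweep the distinct scores in decreasing order (tied scores
    enter together); the area is sum over steps of (R_i - R_{i-1}) * P_i.
    """
    labels, scores = _validate(labels, scores)
    n_pos = int(labels.sum())
    if n_pos == 0 or n_pos == labels.size:
        raise ValueError("AUPR undefined: both classes must be present")
    order = np.argsort(-scores, kind="stable")
    sorted_scores = scores[order]
    sorted_labels = labels[order]
    tp_cum = np.cumsum(sorted_labels)
    n_called = np.arange(1, labels.size + 1)
    # keep only the last index of each tied-score block (all flip together)
    block_end = np.r_[sorted_scores[1:] != sorted_scores[:-1], True]
    tp = tp_cum[block_end]
    called = n_called[block_end]
    precision = tp / called
    recall = tp / n_pos
    prev_recall = np.r_[0.0, recall[:-1]]
    return float(np.sum((recall - prev_recall) * precision))


def compute_metrics(labels, scores, threshold: float = 0.5) -> MetricsReport:
    counts = confusion_counts(labels, scores, threshold)
    accuracy, precision, recall, f1, degenerate = point_metrics(counts)
    return MetricsReport(
        accuracy=accuracy,
        precision=precision,
        recall=recall,
        f1=f1,
        auc=roc_auc(labels, scores),
        aupr=pr_auc(labels, scores),
        threshold=threshold,
        n_samples=counts.total,
        degenerate=degenerate,
    )


def evaluate(model, target_test, threshold: float = 0.5) -> MetricsReport:
    """Score the target-domain test split (labels revealed only here).

    ``model`` is anything with ``predict_epi_proba(enh, prom)`` — the trained
    network or the sklearn-style estimator; dropout is disabled at inference.
    """
    if target_test.epi_label is None:
        raise ValueError("target_test must carry EPI labels for evaluation")
    scores = model.predict_epi_proba(target_test.enh, target_test.prom)
    return compute_metrics(target_test.epi_label, scores, threshold)


def feature_domain_probe(model, source, target, seed: int = 0) -> float:
    """How well learned features still separate the domains.

    Fits a logistic regression on the model's feature vectors (each domain
    contributes its first half for training, second half for held-out
    evaluation) and returns test accuracy.  Perfect domain-invariant features
    score ~0.5; domain-specific features score near 1.  ``model`` needs
    ``transform(enh, prom)``.
    """
    from .synthetic import _half_split_probe

    net = getattr(model, "network_", model)  # estimator or raw network
    fs = net.transform(source.enh, source.prom)
    ft = net.transform(target.enh, target.prom)
    return _half_split_probe(fs, ft)
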