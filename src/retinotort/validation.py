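"""Prognostic validation: ROC analysis of tortuosity scores vs consensus.

Continuous whole-retina tortuosity scores are evaluated against a binary
clinical reference (positive = symptomatic) by building the full ROC curve
over every distinct score threshold; a categorical expert prediction yields
a single point in ROC space instead.

The trapezoid AUC of :func:`roc_curve` is computed from integer confusion
counts with equal scores grouped at one threshold, which makes it *exactly*
equal to the Mann-Whitney pairwise probability of :func:`auc_oracle`
(ties counted 1/2) -- the two routes cross-check each other bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ROCCurve",
    "ExpertROCPoint",
    "DegenerateReferenceError",
    "roc_curve",
    "auc_oracle",
    "expert_roc_point",
]


class DegenerateReferenceError(ValueError):
    """The reference labels contain only one class; no ROC is defined."""


@dataclass(frozen=True)
class ROCCurve:
    """Ordered ROC operating points.

    Starts at (0, 0), ends at (1, 1); both coordinates are non-decreasing.
    ``thresholds[i]`` is the smallest score still classified positive at
    point ``i`` (the leading point uses +inf).
    """

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float


@dataclass(frozen=True)
class ExpertROCPoint:
    """Sensitivity/specificity of one categorical prediction vs reference."""

    sensitivity: float
    specificity: float
    rater: str = ""
    round: str = ""


def _check_binary(labels: np.ndarray) -> tuple:
    labels = np.asarray(labels).astype(int)
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be binary 0/1 (positive = symptomatic)")
    pos = int(labels.sum())
    neg = int(labels.size - pos)
    if pos == 0 or neg == 0:
        raise DegenerateReferenceError("reference must contain both classes")
    return labels, pos, neg


def roc_curve(scores, labels) -> ROCCurve:
    """ROC curve with the decision rule ``score >= t -> positive``.

    One operating point per distinct score value (ties grouped), plus the
    trivial endpoints.  AUC by the trapezoid rule on integer cumulative
    counts.
    """
    scores = np.asarray(scores, dtype=float)
    labels, P, N = _check_binary(labels)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must align")
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    y = labels[order]
    # last index of each tie group of equal scores
    distinct = np.r_[np.flatnonzero(np.diff(s)), s.size - 1]
    tp = np.cumsum(y)[distinct].astype(float)
    fp = (distinct + 1) - tp
    tp = np.r_[0.0, tp]
    fp = np.r_[0.0, fp]
    thresholds = np.r_[np.inf, s[distinct]]
    auc_num = float(np.sum((tp[1:] + tp[:-1]) * np.diff(fp)) / 2.0)
    return ROCCurve(
        fpr=fp / N,
        tpr=tp / P,
        thresholds=thresholds,
        auc=auc_num / (P * N),
    )


def auc_oracle(scores, labels) -> float:
    """Mann-Whitney pairwise AUC: the fraction of (positive, negative) pairs
    where the positive scores higher, ties counted 1/2."""
    scores = np.asarray(scores, dtype=float)
    labels, P, N = _check_binary(labels)
    pos = scores[labels == 1][:, None]
    neg = scores[labels == 0][None, :]
    wins = float(np.sum(pos > neg)) + 0.5 * float(np.sum(pos == neg))
    return wins / (P * N)


def expert_roc_point(pred, ref, rater: str = "", round: str = "") -> ExpertROCPoint:
    """Single ROC-space point of a binary expert prediction.

    ``sensitivity = TP / (TP + FN)``, ``specificity = TN / (TN + FP)`` with
    the symptomatic class positive.
    """
    pred = np.asarray(pred).astype(int)
    ref, P, N = _check_binary(ref)
    if pred.shape != ref.shape:
        raise ValueError("prediction and reference must align")
    if not np.isin(pred, (0, 1)).all():
        raise ValueError("prediction must be binary 0/1")
    tp = int(np.sum((pred == 1) & (ref == 1)))
    tn = int(np.sum((pred == 0) & (ref == 0)))
    return ExpertROCPoint(
        sensitivity=tp / P,
        specificity=tn / N,
        rater=rater,
        round=round,
    )
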