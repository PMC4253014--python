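"""Scoring DAT output against simulation ground truth.

Metrics follow standard benchmarking practice for differential-abundance
calling: ROC/AUC and precision-recall over the p-value ranking,
sensitivity at an FDR threshold, the realized (actual) FDR among calls,
and a between/within-group separability F-score for normalized expression
panels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn import metrics as skm

__all__ = [
    "EvalResult",
    "roc_auc",
    "sensitivity_at_fdr",
    "actual_fdr",
    "separability_fscore",
    "evaluate_result",
]


@dataclass
class EvalResult:
    """ROC/PR summary of one ranked prediction list against binary truth."""

    auc: float
    roc: np.ndarray  # (n, 2) of (FPR, TPR)
    pr: np.ndarray  # (n, 2) of (recall, precision)
    sensitivity_at: dict = field(default_factory=dict)
    actual_fdr_at: dict = field(default_factory=dict)
    flags: dict = field(default_factory=dict)


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> EvalResult:
    """ROC curve and AUC; higher score means more likely differentially abundant.

    The AUC equals the Mann-Whitney probability that a random true-positive
    outranks a random true-negative, with half credit for ties.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if labels.min() == labels.max():
        raise ValueError("both classes must be present to compute an ROC curve")
    fpr, tpr, _ = skm.roc_curve(labels, scores)
    prec, rec, _ = skm.precision_recall_curve(labels, scores)
    return EvalResult(
        auc=float(skm.roc_auc_score(labels, scores)),
        roc=np.column_stack([fpr, tpr]),
        pr=np.column_stack([rec[::-1], prec[::-1]]),
    )


def sensitivity_at_fdr(qvalues: np.ndarray, labels: np.ndarray, q: float = 0.05) -> float:
    """Fraction of truly DA entities called at q-value <= q (NaN if truth has none)."""
    qvalues = np.asarray(qvalues, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if labels.sum() == 0:
        return float("nan")
    return float((qvalues[labels] <= q).mean())


def actual_fdr(qvalues: np.ndarray, labels: np.ndarray, q: float = 0.05) -> float:
    """Realized FDR: fraction of truly null entities among calls at q-value <= q.

    Returns 0 when nothing is called (the estimated FDR is then trivially
    honored); callers can detect the empty-call case from the call count.
    """
    qvalues = np.asarray(qvalues, dtype=float)
    labels = np.asarray(labels).astype(bool)
    called = qvalues <= q
    if called.sum() == 0:
        return 0.0
    return float((~labels[called]).mean())


def separability_fscore(values: np.ndarray, group_labels: np.ndarray) -> float:
    """Between- over within-group variance ratio for a two-group panel.

    F = F_between / F_within with
    F_between = n1*(m1 - m)^2 + n2*(m2 - m)^2 and
    F_within  = (n1*Var(X1) + n2*Var(X2)) / (n1 + n2 - 2),
    using sample variances.  Infinite (flagged by the +inf return) when the
    within-group variance vanishes while the group means differ.
    """
    values = np.asarray(values, dtype=float)
    group_labels = np.asarray(group_labels)
    groups = np.unique(group_labels)
    if groups.size != 2:
        raise ValueError("exactly two groups are required")
    x1 = values[group_labels == groups[0]]
    x2 = values[group_labels == groups[1]]
    if x1.size < 2 or x2.size < 2:
        raise ValueError("both groups need >= 2 members")
    n1, n2 = x1.size, x2.size
    m = values.mean()
    f_between = n1 * (x1.mean() - m) ** 2 + n2 * (x2.mean() - m) ** 2
    f_within = (n1 * x1.var(ddof=1) + n2 * x2.var(ddof=1)) / (n1 + n2 - 2)
    if f_within == 0:
        return 0.0 if f_between == 0 else float("inf")
    return float(f_between / f_within)


def evaluate_result(result, truth, q: float = 0.05) -> EvalResult:
    """Score a DATResult against a PerturbedPair's labels.

    Entities are matched by identifier (the test may have filtered some
    out); the score is -p so smaller p-values rank higher.
    """
    idx = {e: i for i, e in enumerate(truth.entity_ids)}
    rows = [idx[e] for e in result.entity_ids]
    labels = (truth.da_label[rows] != "null").astype(int)
    ev = roc_auc(-result.pvalue, labels)
    ev.sensitivity_at[q] = sensitivity_at_fdr(result.qvalue, labels, q)
    ev.actual_fdr_at[q] = actual_fdr(result.qvalue, labels, q)
    ev.flags["n_called"] = int((result.qvalue <= q).sum())
    return ev
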