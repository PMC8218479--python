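"""ROC construction, AUC, and Youden-index cutoff selection.

The decision rule throughout is ``score >= threshold -> positive`` (ABE):
higher normalized T1 intensity means more suspicion of disease.  The
threshold grid consists of midpoints between adjacent distinct scores plus
one sentinel above the maximum (sensitivity 0) and one below the minimum
(sensitivity 1), so every achievable confusion matrix appears exactly once
and reported cutoffs follow the midpoint convention.

Two independent AUC routes are provided: the trapezoidal area over the
curve, and a brute-force rank oracle (the Mann-Whitney probability that a
random positive outscores a random negative, ties counting one half).  They
agree exactly on every instance; the oracle exists so that tests never have
to trust the curve construction it checks.

:func:`binormal_auc` is the closed form Phi(delta / sqrt(sd_pos^2 + sd_neg^2))
for normally distributed scores - the infinite-sample value the empirical
AUC converges to under the generator's score model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .errors import DegenerateInputError

POSITIVE = "ABE"
NEGATIVE = "non-ABE"


@dataclass
class RocCurve:
    thresholds: np.ndarray  # descending
    sensitivity: np.ndarray
    specificity: np.ndarray
    positive_label: str = POSITIVE

    def __post_init__(self) -> None:
        self.thresholds = np.asarray(self.thresholds, dtype=float)
        self.sensitivity = np.asarray(self.sensitivity, dtype=float)
        self.specificity = np.asarray(self.specificity, dtype=float)


@dataclass
class CutoffResult:
    cutoff: float
    j: float  # Youden index, sensitivity + specificity - 1
    sensitivity_at_cutoff: float
    specificity_at_cutoff: float


def _split_scores(scores, labels, positive_label: str) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be 1D sequences of equal length")
    if not np.isfinite(scores).all():
        raise ValueError("scores must be finite")
    pos = scores[labels == positive_label]
    neg = scores[labels != positive_label]
    if len(pos) == 0 or len(neg) == 0:
        raise DegenerateInputError("both classes must be present to build a ROC curve")
    return pos, neg


def roc_curve(scores, labels, positive_label: str = POSITIVE) -> RocCurve:
    """Empirical ROC curve over the midpoint threshold grid."""
    pos, neg = _split_scores(scores, labels, positive_label)
    distinct = np.unique(np.concatenate([pos, neg]))
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    thresholds = np.concatenate([[distinct[-1] + 1.0], mids[::-1], [distinct[0] - 1.0]])
    # score >= threshold -> positive call
    sens = (pos[None, :] >= thresholds[:, None]).mean(axis=1)
    spec = (neg[None, :] < thresholds[:, None]).mean(axis=1)
    return RocCurve(thresholds, sens, spec, positive_label)


def auc(curve: RocCurve) -> float:
    """Trapezoidal area under (1 - specificity, sensitivity)."""
    fpr = 1.0 - curve.specificity
    order = np.argsort(fpr, kind="stable")
    return float(np.trapezoid(curve.sensitivity[order], fpr[order]))


def auc_rank_oracle(scores, labels, positive_label: str = POSITIVE) -> float:
    """Brute-force AUC: mean over all positive x negative pairs of
    1[pos > neg] + 0.5 * 1[pos == neg].  Test oracle; O(n_pos * n_neg)."""
    pos, neg = _split_scores(scores, labels, positive_label)
    wins = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return float((wins + 0.5 * ties) / (len(pos) * len(neg)))


def youden_cutoff(curve: RocCurve) -> CutoffResult:
    """Threshold maximizing J = sensitivity + specificity - 1.

    Ties break to the smallest threshold, favoring sensitivity.
    """
    j = curve.sensitivity + curve.specificity - 1.0
    best_j = j.max()
    # thresholds are descending, so the last maximal index is the smallest one
    idx = np.flatnonzero(np.isclose(j, best_j, rtol=0, atol=1e-12))[-1]
    return CutoffResult(
        cutoff=float(curve.thresholds[idx]),
        j=float(j[idx]),
        sensitivity_at_cutoff=float(curve.sensitivity[idx]),
        specificity_at_cutoff=float(curve.specificity[idx]),
    )


def binormal_auc(mu_pos: float, sd_pos: float, mu_neg: float, sd_neg: float) -> float:
    """Closed-form AUC for normal score distributions in the two groups."""
    if sd_pos <= 0 or sd_neg <= 0:
        raise ValueError(f"standard deviations must be positive, got {sd_pos}, {sd_neg}")
    return float(norm.cdf((mu_pos - mu_neg) / np.hypot(sd_pos, sd_neg)))


def classify(scores, cutoff: float, positive_label: str = POSITIVE,
             negative_label: str = NEGATIVE) -> np.ndarray:
    """Apply the operating cutoff: score >= cutoff -> positive label."""
    if not np.isfinite(cutoff):
        raise ValueError(f"cutoff must be finite, got {cutoff}")
    scores = np.asarray(scores, dtype=float)
    return np.where(scores >= cutoff, positive_label, negative_label)
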