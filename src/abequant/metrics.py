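"""Diagnostic performance metrics, rater agreement, and method comparison.

Positive class is ABE throughout.  Metrics are kept at full precision in
:class:`MetricSet`; :meth:`MetricSet.display` applies the reporting
convention used for the study tables: sensitivity and specificity are shown
at 0.1% resolution (the resolution of ROC coordinate listings) zero-padded
to two decimals, while precision, F1, accuracy and AUC are shown at 0.01%.
Undefined metrics (zero denominators) are explicit ``None`` + flag, never a
silent 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

from .errors import DegenerateInputError, UndefinedMetricError

POSITIVE = "ABE"
NEGATIVE = "non-ABE"

METRIC_NAMES = ("sensitivity", "specificity", "precision", "f1", "accuracy", "auc")

#: display resolution in decimal places of a percentage, per metric
_DISPLAY_DECIMALS = {
    "sensitivity": 1,
    "specificity": 1,
    "precision": 2,
    "f1": 2,
    "accuracy": 2,
    "auc": 2,
}


@dataclass
class ConfusionMatrix:
    """2x2 counts with ABE as the positive class."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            v = getattr(self, name)
            if not float(v).is_integer() or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v}")
            setattr(self, name, int(v))

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def n_positive(self) -> int:
        return self.tp + self.fn

    @property
    def n_negative(self) -> int:
        return self.tn + self.fp


@dataclass
class MetricSet:
    """Percent-scale performance metrics; ``auc`` is a fraction in [0, 1].

    A metric whose denominator is zero is ``None`` and listed in
    ``undefined``.
    """

    sensitivity: float | None = None
    specificity: float | None = None
    precision: float | None = None
    f1: float | None = None
    accuracy: float | None = None
    auc: float | None = None
    undefined: tuple[str, ...] = field(default_factory=tuple)

    def display(self) -> dict[str, str]:
        """Rounded string form per the reporting convention (AUC as percent)."""
        out: dict[str, str] = {}
        for name in METRIC_NAMES:
            value = getattr(self, name)
            if value is None:
                out[name] = "undefined"
                continue
            pct = value * 100.0 if name == "auc" else value
            out[name] = f"{round(pct, _DISPLAY_DECIMALS[name]):.2f}%"
        return out

    def as_dict(self) -> dict:
        return {name: getattr(self, name) for name in METRIC_NAMES} | {
            "undefined": list(self.undefined)
        }


def confusion(predicted, truth, positive_label: str = POSITIVE,
              negative_label: str = NEGATIVE) -> ConfusionMatrix:
    predicted = np.asarray(predicted)
    truth = np.asarray(truth)
    if predicted.shape != truth.shape or predicted.ndim != 1:
        raise ValueError("predicted and truth must be 1D sequences of equal length")
    valid = {positive_label, negative_label}
    bad = (set(np.unique(predicted)) | set(np.unique(truth))) - valid
    if bad:
        raise ValueError(f"unknown label values {sorted(bad)}; expected {sorted(valid)}")
    pred_pos = predicted == positive_label
    true_pos = truth == positive_label
    return ConfusionMatrix(
        tp=int((pred_pos & true_pos).sum()),
        fp=int((pred_pos & ~true_pos).sum()),
        fn=int((~pred_pos & true_pos).sum()),
        tn=int((~pred_pos & ~true_pos).sum()),
    )


def metrics(cm: ConfusionMatrix, auc: float | None = None) -> MetricSet:
    """Sensitivity, specificity, precision, F1 and accuracy (percent) from counts."""
    if cm.total == 0:
        raise DegenerateInputError("empty confusion matrix")
    values: dict[str, float | None] = {}
    undefined: list[str] = []

    def ratio(name: str, num: int, den: int) -> float | None:
        if den == 0:
            undefined.append(name)
            return None
        return 100.0 * num / den

    values["sensitivity"] = ratio("sensitivity", cm.tp, cm.tp + cm.fn)
    values["specificity"] = ratio("specificity", cm.tn, cm.tn + cm.fp)
    values["precision"] = ratio("precision", cm.tp, cm.tp + cm.fp)
    sens, prec = values["sensitivity"], values["precision"]
    if sens is None or prec is None or (sens + prec) == 0:
        undefined.append("f1")
        values["f1"] = None
    else:
        values["f1"] = 2.0 * prec * sens / (prec + sens)
    values["accuracy"] = 100.0 * (cm.tp + cm.tn) / cm.total
    return MetricSet(auc=auc, undefined=tuple(undefined), **values)


def aggregate(metric_sets: list[MetricSet],
              skip_partial: bool = False) -> dict[str, tuple[float, float]]:
    """Mean and sample SD (n-1) per metric across raters or folds.

    All sets must define the same metrics; mixed availability is an error
    unless ``skip_partial`` drops partially-defined metrics instead.
    """
    if len(metric_sets) < 2:
        raise ValueError("need at least two metric sets to aggregate")
    out: dict[str, tuple[float, float]] = {}
    for name in METRIC_NAMES:
        values = [getattr(ms, name) for ms in metric_sets]
        defined = [v is not None for v in values]
        if not any(defined):
            continue
        if not all(defined):
            if skip_partial:
                continue
            raise ValueError(f"metric {name!r} defined in some sets but not others")
        arr = np.asarray(values, dtype=float)
        out[name] = (float(arr.mean()), float(arr.std(ddof=1)))
    return out


def fleiss_kappa(ratings) -> float:
    """Fleiss' kappa for agreement among >= 2 raters on categorical ratings.

    ``ratings`` is a subjects x raters grid of category labels (any hashable
    values; a DataFrame of ABE / non-ABE calls in practice).  Per-subject
    agreement is P_i = (sum_j n_ij^2 - r) / (r (r - 1)); chance agreement
    P_e comes from the pooled category proportions; kappa = (P_bar - P_e) /
    (1 - P_e).  All ratings in a single category makes kappa undefined.
    """
    if isinstance(ratings, pd.DataFrame):
        grid = ratings.to_numpy()
    else:
        grid = np.asarray(ratings)
    if grid.ndim != 2 or grid.shape[1] < 2:
        raise ValueError("ratings must be a 2D subjects x raters grid with >= 2 raters")
    if pd.isnull(grid).any():
        raise ValueError("ratings grid contains missing cells")
    n_subjects, n_raters = grid.shape
    categories = np.unique(grid)
    counts = np.zeros((n_subjects, len(categories)), dtype=float)
    for j, cat in enumerate(categories):
        counts[:, j] = (grid == cat).sum(axis=1)
    p_i = ((counts**2).sum(axis=1) - n_raters) / (n_raters * (n_raters - 1))
    p_bar = p_i.mean()
    p_j = counts.sum(axis=0) / (n_subjects * n_raters)
    p_e = float((p_j**2).sum())
    if p_e >= 1.0:
        raise UndefinedMetricError("all ratings fall in one category; kappa undefined")
    return float((p_bar - p_e) / (1.0 - p_e))


def compare_accuracy_chi2(correct_a: int, n_a: int, correct_b: int, n_b: int) -> tuple[float, float]:
    """Pearson chi-squared (1 df, no continuity correction) comparing two
    correct/incorrect proportions; returns (statistic, two-sided p)."""
    for correct, n in ((correct_a, n_a), (correct_b, n_b)):
        if not 0 <= correct <= n:
            raise ValueError(f"correct count {correct} outside [0, {n}]")
    table = np.array(
        [[correct_a, n_a - correct_a], [correct_b, n_b - correct_b]], dtype=float
    )
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise UndefinedMetricError("zero margin in the 2x2 table; test undefined")
    stat, p, _, _ = chi2_contingency(table, correction=False)
    return float(stat), float(p)
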