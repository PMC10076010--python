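"""ROC curves, AUC, and DeLong confidence intervals for marker evaluation.

A marker's per-sample score (TMM-normalized expression or a subpopulation
proportion) is swept over thresholds to build the ROC curve; the trapezoidal
area equals the Mann-Whitney statistic U/(n1 n0) with ties counted 1/2 —
the probability that a random positive outscores a random negative.  The
95% interval uses DeLong's placement-value variance with a normal
approximation, clipped to [0, 1] (the study reports intervals truncated at 1,
e.g. "0.7842 to 1").
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.stats as st


class RocError(ValueError):
    """Raised when ROC inputs are degenerate (e.g. a single class)."""


@dataclass
class RocResult:
    """ROC curve with AUC and confidence bounds for one marker."""

    marker: str
    source: str  # "expression" or "proportion"
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float
    ci_low: float
    ci_high: float
    positive_label: object
    n_pos: int
    n_neg: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.auc <= 1.0):
            raise ValueError("AUC must lie in [0, 1]")
        if not (self.ci_low <= self.auc <= self.ci_high):
            raise ValueError("CI must contain the point AUC")


def _validate(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-D arrays")
    pos = labels.astype(bool) if labels.dtype != bool else labels
    if pos.all() or not pos.any():
        raise RocError("both classes must be present")
    return scores, pos


def roc_points(
    scores: Sequence[float],
    labels: Sequence[int],
    flip: bool = False,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """ROC curve points (fpr, tpr, thresholds).

    Thresholds sweep the unique scores in descending order with ties grouped
    at one threshold; the curve starts at (0, 0) and ends at (1, 1).  Higher
    scores are treated as more positive unless ``flip`` is set; orientation is
    fixed by the declared positive class — AUC >= 0.5 is *not* forced.
    """
    scores, pos = _validate(scores, labels)
    if flip:
        scores = -scores
    order = np.argsort(-scores, kind="stable")
    s_sorted = scores[order]
    p_sorted = pos[order].astype(float)
    # indices of the last element of each tie group
    last_of_group = np.flatnonzero(np.diff(s_sorted) != 0)
    last_of_group = np.concatenate([last_of_group, [len(s_sorted) - 1]])
    tp = np.cumsum(p_sorted)[last_of_group]
    fp = (last_of_group + 1) - tp
    n_pos, n_neg = pos.sum(), (~pos).sum()
    tpr = np.concatenate([[0.0], tp / n_pos])
    fpr = np.concatenate([[0.0], fp / n_neg])
    thresholds = np.concatenate([[np.inf], s_sorted[last_of_group]])
    if flip:
        thresholds = -thresholds
    return fpr, tpr, thresholds


def auc(scores: Sequence[float], labels: Sequence[int], flip: bool = False) -> float:
    """Trapezoidal area under the ROC curve (= Mann-Whitney with half-ties)."""
    fpr, tpr, _ = roc_points(scores, labels, flip=flip)
    return float(np.trapezoid(tpr, fpr))


def _placements(scores: np.ndarray, pos: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """DeLong placement values V10 (per positive) and V01 (per negative)."""
    x = scores[pos][:, None]
    y = scores[~pos][None, :]
    psi = (x > y).astype(float) + 0.5 * (x == y)
    return psi.mean(axis=1), psi.mean(axis=0)


def auc_ci(
    scores: Sequence[float],
    labels: Sequence[int],
    level: float = 0.95,
    flip: bool = False,
) -> tuple[float, float]:
    """DeLong normal-approximation confidence interval, clipped to [0, 1].

    With zero placement variance (perfect separation) the interval degenerates
    to the point AUC, with a warning.
    """
    scores, pos = _validate(scores, labels)
    if flip:
        scores = -scores
    v10, v01 = _placements(scores, pos)
    theta = float(v10.mean())
    m, n = v10.size, v01.size
    var = 0.0
    if m > 1:
        var += np.var(v10, ddof=1) / m
    if n > 1:
        var += np.var(v01, ddof=1) / n
    if var <= 0:
        warnings.warn("zero DeLong variance (perfect separation); "
                      "degenerate interval")
        return theta, min(1.0, theta)
    z = st.norm.ppf(0.5 + level / 2.0)
    half = z * np.sqrt(var)
    return float(max(0.0, theta - half)), float(min(1.0, theta + half))


def evaluate_marker(
    marker: str,
    scores: Sequence[float],
    labels: Sequence[int],
    source: str = "expression",
    positive_label: object = 1,
    level: float = 0.95,
    flip: bool = False,
) -> RocResult:
    """Full ROC evaluation of one marker."""
    fpr, tpr, thresholds = roc_points(scores, labels, flip=flip)
    point = float(np.trapezoid(tpr, fpr))
    low, high = auc_ci(scores, labels, level=level, flip=flip)
    pos = np.asarray(labels).astype(bool)
    return RocResult(
        marker=marker, source=source, fpr=fpr, tpr=tpr, thresholds=thresholds,
        auc=point, ci_low=low, ci_high=high, positive_label=positive_label,
        n_pos=int(pos.sum()), n_neg=int((~pos).sum()),
    )
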