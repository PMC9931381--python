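"""Diagnostic-performance statistics.

Confusion matrices, sensitivity / specificity / accuracy with an exact
(Clopper-Pearson) binomial confidence interval on accuracy, ROC curves with
trapezoidal AUC, and the DeLong placement-value variance estimator for a
normal-approximation AUC confidence interval.  The positive class is
"submaximal / insincere" throughout: sensitivity always means the
probability of detecting a submaximal effort.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve as _sk_roc_curve

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "ROCCurve",
    "DeLongCI",
    "confusion",
    "report_from",
    "roc_from_scores",
    "delong_ci",
    "clopper_pearson",
    "comparison_table",
    "format_comparison_text",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """2x2 table of predicted vs true labels (positive = submaximal)."""

    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.tn, self.fp) < 0:
            raise ValueError("confusion counts must be >= 0")
        if self.total == 0:
            raise ValueError("confusion matrix is empty")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.tn + self.fp

    @property
    def n_pos(self) -> int:
        return self.tp + self.fn

    @property
    def n_neg(self) -> int:
        return self.tn + self.fp

    @property
    def sensitivity(self) -> float:
        if self.n_pos == 0:
            raise ValueError("sensitivity undefined: no positive samples")
        return self.tp / self.n_pos

    @property
    def specificity(self) -> float:
        if self.n_neg == 0:
            raise ValueError("specificity undefined: no negative samples")
        return self.tn / self.n_neg

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.total


@dataclass(frozen=True)
class ROCCurve:
    """ROC points (one per distinct score threshold) and trapezoidal AUC."""

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


class DeLongCI(NamedTuple):
    lo: float
    hi: float
    variance: float
    degenerate: bool


@dataclass(frozen=True)
class MetricsReport:
    """Machine-readable row of the diagnostic comparison table."""

    method_label: str
    sensitivity: float
    specificity: float
    accuracy: float
    accuracy_ci: tuple[float, float]
    auc: float
    auc_ci: tuple[float, float]
    n_pos: int
    n_neg: int

    def __post_init__(self) -> None:
        lo, hi = self.accuracy_ci
        if not (lo - 1e-12 <= self.accuracy <= hi + 1e-12):
            raise ValueError("accuracy outside its confidence interval")
        lo, hi = self.auc_ci
        if not (lo - 1e-12 <= self.auc <= hi + 1e-12):
            raise ValueError("AUC outside its confidence interval")


def _as_binary(labels: Sequence, positive_label) -> np.ndarray:
    arr = np.asarray(labels)
    uniq = set(np.unique(arr).tolist())
    if len(uniq) > 2:
        raise ValueError(f"labels must be binary, got {sorted(map(str, uniq))}")
    if positive_label not in uniq and len(uniq) == 2:
        raise ValueError(f"positive label {positive_label!r} absent from labels {sorted(map(str, uniq))}")
    return (arr == positive_label).astype(int)


def confusion(truth: Sequence, predicted: Sequence, positive_label=1) -> ConfusionMatrix:
    """Tally the confusion matrix of predicted vs true binary labels."""
    t = np.asarray(truth)
    p = np.asarray(predicted)
    if t.shape != p.shape or t.ndim != 1:
        raise ValueError("truth and predicted must be 1-D and of equal length")
    if t.size == 0:
        raise ValueError("empty label vectors")
    tb = _as_binary(t, positive_label)
    pb = _as_binary(p, positive_label)
    tp = int(np.sum((tb == 1) & (pb == 1)))
    fn = int(np.sum((tb == 1) & (pb == 0)))
    tn = int(np.sum((tb == 0) & (pb == 0)))
    fp = int(np.sum((tb == 0) & (pb == 1)))
    return ConfusionMatrix(tp=tp, fn=fn, tn=tn, fp=fp)


def clopper_pearson(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Exact binomial (Clopper-Pearson) confidence interval for k successes out of n."""
    if not (0 <= k <= n) or n <= 0:
        raise ValueError(f"need 0 <= k <= n with n > 0, got k={k}, n={n}")
    alpha = 1.0 - level
    lo = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2.0, k, n - k + 1))
    hi = 1.0 if k == n else float(stats.beta.ppf(1.0 - alpha / 2.0, k + 1, n - k))
    return lo, hi


def roc_from_scores(scores: Sequence[float], truth: Sequence, positive_label=1) -> ROCCurve:
    """ROC curve over distinct score thresholds, with trapezoidal AUC.

    Tied scores are grouped into a single threshold step; endpoints (0,0)
    and (1,1) are always included.  The AUC equals the Mann-Whitney
    probability that a random positive outscores a random negative, ties
    counted one half.
    """
    s = np.asarray(scores, dtype=float)
    y = _as_binary(truth, positive_label)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and truth must be 1-D and of equal length")
    if not np.all(np.isfinite(s)):
        raise ValueError("scores must be finite")
    if y.sum() == 0 or y.sum() == y.size:
        raise ValueError("ROC requires both classes present")
    fpr, tpr, thr = _sk_roc_curve(y, s, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return ROCCurve(thresholds=thr, fpr=fpr, tpr=tpr, auc=auc)


def _placements(pos: np.ndarray, neg: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """DeLong placement values via midranks.

    ``v_pos[i]`` is the fraction of negatives scored below positive ``i``
    (ties one half); ``v_neg[j]`` the fraction of positives scored above
    negative ``j``, complemented.
    """
    m, n = len(pos), len(neg)
    combined = np.concatenate([pos, neg])
    rank_all = stats.rankdata(combined)  # midranks
    rank_pos = stats.rankdata(pos)
    rank_neg = stats.rankdata(neg)
    v_pos = (rank_all[:m] - rank_pos) / n
    v_neg = 1.0 - (rank_all[m:] - rank_neg) / m
    return v_pos, v_neg


def delong_ci(
    scores: Sequence[float],
    truth: Sequence,
    level: float = 0.95,
    positive_label=1,
) -> DeLongCI:
    """DeLong confidence interval for the AUC.

    The AUC variance is estimated from the empirical variances of the
    placement values, ``var = S_pos/m + S_neg/n``; the CI is the normal
    approximation clipped to [0, 1].  Perfectly separated scores give zero
    variance: the CI collapses onto the point AUC and ``degenerate`` is set.
    """
    s = np.asarray(scores, dtype=float)
    y = _as_binary(truth, positive_label)
    pos = s[y == 1]
    neg = s[y == 0]
    if len(pos) < 2 or len(neg) < 2:
        raise ValueError("DeLong CI needs at least 2 samples per class")
    v_pos, v_neg = _placements(pos, neg)
    auc = float(v_pos.mean())
    var = float(np.var(v_pos, ddof=1) / len(pos) + np.var(v_neg, ddof=1) / len(neg))
    if var <= 0.0:
        return DeLongCI(lo=auc, hi=auc, variance=0.0, degenerate=True)
    z = float(stats.norm.ppf(0.5 + level / 2.0))
    half = z * var ** 0.5
    return DeLongCI(lo=max(0.0, auc - half), hi=min(1.0, auc + half), variance=var, degenerate=False)


def report_from(
    cm: ConfusionMatrix,
    scores: Sequence[float],
    truth: Sequence,
    method_label: str = "",
    level: float = 0.95,
    positive_label=1,
) -> MetricsReport:
    """Assemble the full diagnostic report for one method.

    Rates come from the confusion matrix; the accuracy CI is exact
    Clopper-Pearson; the AUC is the trapezoidal ROC area of ``scores`` with
    a DeLong CI.
    """
    roc = roc_from_scores(scores, truth, positive_label=positive_label)
    dl = delong_ci(scores, truth, level=level, positive_label=positive_label)
    return MetricsReport(
        method_label=method_label,
        sensitivity=cm.sensitivity,
        specificity=cm.specificity,
        accuracy=cm.accuracy,
        accuracy_ci=clopper_pearson(cm.tp + cm.tn, cm.total, level=level),
        auc=roc.auc,
        auc_ci=(dl.lo, dl.hi),
        n_pos=cm.n_pos,
        n_neg=cm.n_neg,
    )


_ROW_ORDER = ("Sensitivity", "Specificity", "Accuracy", "(95% CI)", "AUC", "(95% CI deLong)")


def comparison_table(reports: Sequence[MetricsReport]) -> pd.DataFrame:
    """Comparison table: methods as columns, metric rows, 4-decimal formatting."""
    cols = {}
    for r in reports:
        cols[r.method_label] = [
            f"{r.sensitivity:.4f}",
            f"{r.specificity:.4f}",
            f"{r.accuracy:.4f}",
            f"({r.accuracy_ci[0]:.4f}, {r.accuracy_ci[1]:.4f})",
            f"{r.auc:.4f}",
            f"({r.auc_ci[0]:.4f}, {r.auc_ci[1]:.4f})",
        ]
    return pd.DataFrame(cols, index=list(_ROW_ORDER))


def format_comparison_text(table: pd.DataFrame) -> str:
    """Aligned plain-text rendering of the comparison table."""
    width = max(len(str(i)) for i in table.index)
    col_widths = {c: max(len(c), *(len(v) for v in table[c])) for c in table.columns}
    lines = ["Method".ljust(width) + "  " + "  ".join(c.rjust(col_widths[c]) for c in table.columns)]
    for idx, row in table.iterrows():
        lines.append(str(idx).ljust(width) + "  " + "  ".join(str(row[c]).rjust(col_widths[c]) for c in table.columns))
    return "\n".join(lines) + "\n"
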