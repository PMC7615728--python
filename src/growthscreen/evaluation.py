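"""Cell-level performance evaluation: confusion metrics, ROC/AUC, Youden index.

All evaluation is at the cell level: the truth mask marks which height
cells were contaminated, and a detector contributes a binary flag (and
for score-based methods a continuous score) per height cell.

Point metrics are sensitivity, specificity, positive predictive value
and the positive likelihood ratio LR+ = Se / (1 - Sp), with exact
Clopper-Pearson 95% intervals for proportions and the log-method
interval for LR+.  ROC curves sweep every distinct score threshold;
the AUC equals the Mann-Whitney pair-counting statistic (ties count
half) and gets a DeLong 95% interval.  The Youden index
J = Se + Sp - 1 picks the cutoff maximizing vertical distance from the
chance diagonal; on ties the higher-specificity cutoff is reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.metrics import roc_curve
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "ConfusionCounts",
    "MetricEstimate",
    "RocSummary",
    "confusion",
    "binary_metrics",
    "roc_summary",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class MetricEstimate:
    name: str
    estimate: float
    ci_low: float
    ci_high: float


@dataclass(frozen=True)
class RocSummary:
    points: np.ndarray  # (k, 2) array of (1 - specificity, sensitivity)
    thresholds: np.ndarray = field(repr=False)
    auc: float = 0.0
    auc_ci: tuple[float, float] = (0.0, 1.0)
    youden_j: float = 0.0
    youden_cutoff: float = float("nan")
    youden_se: float = 0.0
    youden_sp: float = 0.0


def confusion(flags, truth) -> ConfusionCounts:
    """Cross-tabulate binary flags against the ground-truth error mask."""
    flags = np.asarray(flags, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if flags.shape != truth.shape:
        raise ValueError("flags and truth must have equal length")
    tp = int(np.count_nonzero(flags & truth))
    fp = int(np.count_nonzero(flags & ~truth))
    fn = int(np.count_nonzero(~flags & truth))
    tn = int(np.count_nonzero(~flags & ~truth))
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


def _proportion_ci(count: int, nobs: int) -> tuple[float, float]:
    lo, hi = proportion_confint(count, nobs, alpha=0.05, method="beta")
    return float(lo), float(hi)


def binary_metrics(counts: ConfusionCounts) -> list[MetricEstimate]:
    """Se, Sp, PPV and LR+ with 95% intervals.

    PPV is reported as NaN when nothing was flagged; LR+ is +inf with a
    one-sided interval when there are no false positives.
    """
    tp, fp, fn, tn = counts.tp, counts.fp, counts.fn, counts.tn
    pos, neg = tp + fn, fp + tn
    if pos == 0 or neg == 0:
        raise ValueError("both true-error and clean cells must be present")
    out = []
    se = tp / pos
    out.append(MetricEstimate("sensitivity", se, *_proportion_ci(tp, pos)))
    sp = tn / neg
    out.append(MetricEstimate("specificity", sp, *_proportion_ci(tn, neg)))
    if tp + fp == 0:
        out.append(MetricEstimate("ppv", float("nan"), float("nan"), float("nan")))
    else:
        out.append(MetricEstimate("ppv", tp / (tp + fp), *_proportion_ci(tp, tp + fp)))
    if fp == 0:
        # no false positives: LR+ unbounded; lower bound from the log method
        # with fp replaced by its one-sided upper bound is not defined either,
        # so report +inf with a one-sided interval.
        out.append(MetricEstimate("lr_plus", float("inf"), 0.0, float("inf")))
    elif tp == 0:
        out.append(MetricEstimate("lr_plus", 0.0, 0.0, float("inf")))
    else:
        lr = se / (1 - sp)
        se_log = np.sqrt(1 / tp - 1 / pos + 1 / fp - 1 / neg)
        lo = float(lr * np.exp(-1.959963984540054 * se_log))
        hi = float(lr * np.exp(+1.959963984540054 * se_log))
        out.append(MetricEstimate("lr_plus", lr, lo, hi))
    return out


def _delong_variance(scores_pos: np.ndarray, scores_neg: np.ndarray) -> float:
    """DeLong variance of the empirical AUC via midrank placements."""
    m, n = len(scores_pos), len(scores_neg)
    all_scores = np.concatenate([scores_pos, scores_neg])
    rank_all = stats.rankdata(all_scores)
    rank_pos = stats.rankdata(scores_pos)
    rank_neg = stats.rankdata(scores_neg)
    # placement of each positive among negatives, and vice versa
    v10 = (rank_all[:m] - rank_pos) / n
    v01 = 1.0 - (rank_all[m:] - rank_neg) / m
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return s10 / m + s01 / n


def roc_summary(scores, truth) -> RocSummary:
    """Empirical ROC of a continuous score against a truth mask.

    Higher scores must indicate errors.  Returns the curve points, the
    trapezoid AUC (= Mann-Whitney statistic) with a DeLong 95% CI, and
    the Youden-index operating point.
    """
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth, dtype=bool)
    if scores.shape != truth.shape:
        raise ValueError("scores and truth must have equal length")
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    if truth.all() or not truth.any():
        raise ValueError("both classes must be present")

    fpr, tpr, thr = roc_curve(truth, scores, drop_intermediate=False)
    # Mann-Whitney form of the trapezoid AUC: exact under perfect separation
    m, n_neg = int(truth.sum()), int((~truth).sum())
    ranks = stats.rankdata(scores)
    auc = float((ranks[truth].sum() - m * (m + 1) / 2) / (m * n_neg))
    var = _delong_variance(scores[truth], scores[~truth])
    half = 1.959963984540054 * np.sqrt(var)
    ci = (max(0.0, auc - half), min(1.0, auc + half))

    j = tpr - fpr
    jmax = j.max()
    # ties broken toward higher specificity (smaller fpr)
    cand = np.flatnonzero(np.isclose(j, jmax))
    best = cand[np.argmin(fpr[cand])]
    return RocSummary(
        points=np.column_stack([fpr, tpr]),
        thresholds=thr,
        auc=auc,
        auc_ci=ci,
        youden_j=float(j[best]),
        youden_cutoff=float(thr[best]),
        youden_se=float(tpr[best]),
        youden_sp=float(1.0 - fpr[best]),
    )
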