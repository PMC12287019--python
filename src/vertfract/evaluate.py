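"""Evaluation: confusion counts, segmentation and classification metrics,
leave-eleven-out cross-validation, and the paired statistical comparison of
two classifiers (paired t plus exact Wilcoxon signed-rank).

Segmentation metrics (percent): accuracy (TP+TN)/total, sensitivity
TP/(TP+FN), Dice 2TP/(2TP+FP+FN) and Jaccard TP/(TP+FP+FN); Dice and Jaccard
satisfy DSC = 2J/(1+J) with J as a fraction.  Classification metrics are the
usual accuracy / precision / recall / F1.  Metrics with a zero denominator
return 0 and set a warning flag rather than raising, so batch evaluation
survives empty predictions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "ConfusionCounts", "SegMetrics", "ClsMetrics", "ComparisonResult",
    "confusion", "seg_metrics", "cls_metrics", "dice",
    "fold_sizes", "leave_eleven_out_cv",
    "paired_t_test", "wilcoxon_signed_rank_exact", "compare_classifiers",
]


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass
class SegMetrics:
    accuracy: float      # percent
    sensitivity: float
    dsc: float
    jaccard: float
    degenerate: bool = False


@dataclass
class ClsMetrics:
    accuracy: float      # percent
    precision: float
    recall: float
    f1: float
    degenerate: bool = False


@dataclass
class ComparisonResult:
    """Paired comparison of two classifiers' per-split accuracies."""

    label: str
    t_statistic: float
    t_pvalue: float
    w_statistic: float
    w_pvalue: float
    n_pairs: int


def confusion(pred, truth) -> ConfusionCounts:
    """Elementwise confusion counts; positive class = 1/foreground."""
    p = np.asarray(pred).astype(bool).ravel()
    t = np.asarray(truth).astype(bool).ravel()
    if p.shape != t.shape:
        raise ValueError("prediction and truth shapes differ")
    return ConfusionCounts(
        TP=int(np.sum(p & t)), TN=int(np.sum(~p & ~t)),
        FP=int(np.sum(p & ~t)), FN=int(np.sum(~p & t)),
    )


def _ratio(num: float, den: float) -> tuple[float, bool]:
    if den == 0:
        return 0.0, True
    return 100.0 * num / den, False


def seg_metrics(c: ConfusionCounts) -> SegMetrics:
    acc, d1 = _ratio(c.TP + c.TN, c.total)
    sens, d2 = _ratio(c.TP, c.TP + c.FN)
    dsc_, d3 = _ratio(2 * c.TP, 2 * c.TP + c.FP + c.FN)
    jc, d4 = _ratio(c.TP, c.TP + c.FP + c.FN)
    return SegMetrics(acc, sens, dsc_, jc, degenerate=d1 or d2 or d3 or d4)


def cls_metrics(c: ConfusionCounts) -> ClsMetrics:
    acc, d1 = _ratio(c.TP + c.TN, c.total)
    prec, d2 = _ratio(c.TP, c.TP + c.FP)
    rec, d3 = _ratio(c.TP, c.TP + c.FN)
    if prec + rec == 0:
        f1, d4 = 0.0, True
    else:
        f1, d4 = 2 * prec * rec / (prec + rec), False
    return ClsMetrics(acc, prec, rec, f1, degenerate=d1 or d2 or d3 or d4)


def dice(pred_mask, truth_mask) -> float:
    """Dice similarity coefficient between two binary masks, in percent."""
    return seg_metrics(confusion(pred_mask, truth_mask)).dsc


def fold_sizes(n_cases: int, fold_size: int = 11) -> list[int]:
    """Sequential disjoint test folds of ``fold_size``, last fold smaller.

    63 cases -> (11, 11, 11, 11, 11, 8).
    """
    if n_cases < fold_size + 1:
        raise ValueError(f"need more than {fold_size} cases for leave-{fold_size}-out")
    sizes = [fold_size] * (n_cases // fold_size)
    rem = n_cases % fold_size
    if rem:
        sizes.append(rem)
    return sizes


def leave_eleven_out_cv(cases, segment_and_score, fold_size: int = 11) -> dict:
    """Leave-``fold_size``-out cross-validation over phantom/clinical cases.

    ``segment_and_score(case)`` must return a list of
    ``(level_name, ConfusionCounts)`` pairs for the case's vertebrae; the
    test-fold counts are aggregated per fold, per lumbar level and overall.
    """
    n = len(cases)
    sizes = fold_sizes(n, fold_size)
    per_fold: list[SegMetrics] = []
    level_counts: dict[str, list[ConfusionCounts]] = {}
    start = 0
    for size in sizes:
        fold_cases = cases[start:start + size]
        start += size
        cc = []
        for case in fold_cases:
            for level, counts in segment_and_score(case):
                cc.append(counts)
                level_counts.setdefault(level, []).append(counts)
        agg = ConfusionCounts(
            TP=sum(c.TP for c in cc), TN=sum(c.TN for c in cc),
            FP=sum(c.FP for c in cc), FN=sum(c.FN for c in cc))
        per_fold.append(seg_metrics(agg))
    per_level = {}
    for level, cs in sorted(level_counts.items()):
        agg = ConfusionCounts(
            TP=sum(c.TP for c in cs), TN=sum(c.TN for c in cs),
            FP=sum(c.FP for c in cs), FN=sum(c.FN for c in cs))
        per_level[level] = seg_metrics(agg)
    overall = SegMetrics(
        accuracy=float(np.mean([m.accuracy for m in per_fold])),
        sensitivity=float(np.mean([m.sensitivity for m in per_fold])),
        dsc=float(np.mean([m.dsc for m in per_fold])),
        jaccard=float(np.mean([m.jaccard for m in per_fold])),
    )
    return {"fold_sizes": sizes, "per_fold": per_fold,
            "per_level": per_level, "overall": overall}


def paired_t_test(a, b) -> tuple[float, float]:
    """Two-sided paired t-test on equal-length samples.

    t = mean(d) / (sd(d)/sqrt(n)) with the n-1 denominator in sd; p from the
    t distribution with n-1 degrees of freedom.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("need two equal-length 1-D samples of size >= 2")
    d = a - b
    if np.ptp(d) == 0:
        raise ValueError("degenerate paired test: zero-variance differences")
    res = sps.ttest_rel(a, b)
    return float(res.statistic), float(res.pvalue)


def wilcoxon_signed_rank_exact(a, b) -> tuple[float, float]:
    """Exact two-sided Wilcoxon signed-rank test by full sign enumeration.

    Zero differences are dropped (reducing n); tied absolute differences get
    average ranks.  W is the smaller of the positive- and negative-rank sums;
    the p-value enumerates all 2^n sign assignments:
    p = P(W+ <= min(w+, w-)) + P(W+ >= max(w+, w-)).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("need two equal-length 1-D samples")
    d = a - b
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise ValueError("all differences are zero")
    if n > 25:
        raise ValueError("exact enumeration supported for n <= 25 only")
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    total = n * (n + 1) / 2
    w_minus = total - w_plus
    w_stat = min(w_plus, w_minus)

    # enumerate W+ over all 2^n sign assignments (incremental doubling)
    w_all = np.zeros(1)
    for r in ranks:
        w_all = np.concatenate([w_all, w_all + r])
    eps = 1e-9
    lo, hi = min(w_plus, w_minus), max(w_plus, w_minus)
    p = (np.sum(w_all <= lo + eps) + np.sum(w_all >= hi - eps)) / len(w_all)
    return w_stat, float(min(p, 1.0))


def compare_classifiers(results_a: dict[str, list[float]],
                        results_b: list[float],
                        b_name: str = "SVM") -> list[ComparisonResult]:
    """Pair each arm in ``results_a`` (e.g. KNN per k) against ``results_b``
    per-split accuracies, emitting both the paired t and exact Wilcoxon tests."""
    out = []
    for name, acc in results_a.items():
        t, tp = paired_t_test(acc, results_b)
        w, wp = wilcoxon_signed_rank_exact(acc, results_b)
        out.append(ComparisonResult(
            label=f"{name} vs {b_name}", t_statistic=t, t_pvalue=tp,
            w_statistic=w, w_pvalue=wp, n_pairs=len(acc)))
    return out
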