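"""Benchmark statistics for a pathogenicity scorer against a reference set.

Conventions used throughout:

* a variant is called deleterious when its score is **at or above** the
  threshold (so the 0.6 spotting level is itself a deleterious call);
* precision-recall curves place one point per unique score value with ties
  grouped, and AUPRC is the conservative step sum
  ``sum_i (recall_i - recall_{i-1}) * precision_i`` — no linear
  interpolation between PR points;
* AUROC is the normalised rank-sum (Mann-Whitney) statistic, i.e. the
  probability that a random positive outranks a random negative, ties
  counting one half;
* variants with a missing score are excluded pairwise and counted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DegenerateSetError, InputError


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int
    n_excluded: int = 0

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp)

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp)


@dataclass
class PRCurve:
    """One point per unique score value, thresholds descending."""

    thresholds: np.ndarray
    recall: np.ndarray
    precision: np.ndarray
    prior: float


@dataclass
class BenchmarkSummary:
    scorer: str
    auprc: float
    auroc: float
    mcc: float
    rec90: float
    auprc_norm: float
    prior: float
    threshold_used_for_mcc: float
    n_used: int
    n_excluded: int


def _clean(scores, labels):
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=float)
    if s.shape != y.shape or s.ndim != 1:
        raise InputError("scores and labels must be equal-length 1-D arrays")
    keep = ~np.isnan(s)
    n_excluded = int((~keep).sum())
    s, y = s[keep], y[keep].astype(int)
    if s.size == 0 or y.min() == y.max():
        raise DegenerateSetError("need both classes present after exclusions")
    return s, y, n_excluded


def confusion_at_threshold(scores, labels, t: float) -> ConfusionCounts:
    """Confusion counts calling deleterious at score >= t."""
    s, y, n_excluded = _clean(scores, labels)
    pred = s >= t
    return ConfusionCounts(
        tp=int(np.sum(pred & (y == 1))),
        fp=int(np.sum(pred & (y == 0))),
        tn=int(np.sum(~pred & (y == 0))),
        fn=int(np.sum(~pred & (y == 1))),
        n_excluded=n_excluded,
    )


def pr_curve(scores, labels) -> PRCurve:
    """Precision-recall curve with tie-grouped thresholds (descending)."""
    s, y, _ = _clean(scores, labels)
    order = np.argsort(-s, kind="stable")
    s_sorted, y_sorted = s[order], y[order]
    cum_tp = np.cumsum(y_sorted == 1)
    cum_pred = np.arange(1, s.size + 1)
    # last index of each tie block = the grouped operating point
    block_end = np.nonzero(np.r_[s_sorted[1:] != s_sorted[:-1], True])[0]
    n_pos = int(np.sum(y == 1))
    recall = cum_tp[block_end] / n_pos
    precision = cum_tp[block_end] / cum_pred[block_end]
    return PRCurve(
        thresholds=s_sorted[block_end],
        recall=recall,
        precision=precision,
        prior=n_pos / s.size,
    )


def auprc(curve_or_scores, labels=None) -> float:
    """Step-integrated area under the PR curve.

    Precision is held at the value achieved at each newly reached recall
    level: ``sum_i (r_i - r_{i-1}) * p_i``.
    """
    curve = curve_or_scores if labels is None else pr_curve(curve_or_scores, labels)
    r = np.r_[0.0, curve.recall]
    return float(np.sum(np.diff(r) * curve.precision))


def auroc(scores, labels) -> float:
    """Normalised rank-sum AUROC (ties count 1/2)."""
    s, y, _ = _clean(scores, labels)
    n_pos = int(np.sum(y == 1))
    n_neg = s.size - n_pos
    ranks = stats.rankdata(s)
    u = np.sum(ranks[y == 1]) - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def mcc(counts: ConfusionCounts) -> float:
    """Matthews correlation coefficient; 0 (flagged) on a degenerate margin."""
    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return float((tp * tn - fp * fn) / np.sqrt(denom))


def rec90(curve: PRCurve, min_precision: float = 0.90) -> float:
    """Maximum recall over thresholds achieving precision >= 90%."""
    ok = curve.precision >= min_precision
    if not ok.any():
        return 0.0
    return float(curve.recall[ok].max())


def matched_recall_threshold(scores, labels, target_recall: float) -> float:
    """Largest score threshold whose recall is at least ``target_recall``.

    Recall is non-decreasing as the threshold drops, so the first curve
    point (highest threshold) reaching the target is returned; among equal
    thresholds, ties have already been grouped, which favours the higher-
    precision operating point.
    """
    curve = pr_curve(scores, labels)
    ok = np.nonzero(curve.recall >= target_recall)[0]
    if ok.size == 0:
        raise InputError(f"target recall {target_recall} is not achievable")
    return float(curve.thresholds[ok[0]])


def auprc_norm(scores, labels) -> float:
    """AUPRC divided by the positive-class prior; 1 for an uninformative scorer."""
    curve = pr_curve(scores, labels)
    return auprc(curve) / curve.prior


def summarize(
    scores,
    labels,
    scorer: str = "",
    threshold: float | None = None,
    matched_recall: float | None = None,
) -> BenchmarkSummary:
    """All single-point measures for one scorer on one reference set.

    MCC is computed at ``threshold`` when given, else at the threshold
    matching ``matched_recall``, else at the scorer's median unique score.
    """
    s, y, n_excluded = _clean(scores, labels)
    curve = pr_curve(s, y)
    if threshold is None:
        if matched_recall is not None:
            threshold = matched_recall_threshold(s, y, matched_recall)
        else:
            threshold = float(np.median(np.unique(s)))
    counts = confusion_at_threshold(s, y, threshold)
    return BenchmarkSummary(
        scorer=scorer,
        auprc=auprc(curve),
        auroc=auroc(s, y),
        mcc=mcc(counts),
        rec90=rec90(curve),
        auprc_norm=auprc(curve) / curve.prior,
        prior=curve.prior,
        threshold_used_for_mcc=float(threshold),
        n_used=int(s.size),
        n_excluded=n_excluded,
    )


def fisher_exact(table, sided: str = "two") -> tuple[float, float]:
    """Hypergeometric-exact p and the sample odds ratio (ad)/(bc).

    ``sided='one'`` tests enrichment of the [0,0] cell (alternative
    'greater'); ``'two'`` sums all tables at most as probable as observed.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any():
        raise InputError("fisher_exact needs a 2x2 table of non-negative counts")
    alternative = {"one": "greater", "two": "two-sided"}.get(sided)
    if alternative is None:
        raise InputError(f"sided must be 'one' or 'two', got {sided!r}")
    res = stats.fisher_exact(t, alternative=alternative)
    a, b, c, d = t.ravel()
    odds = np.inf if b * c == 0 else (a * d) / (b * c)
    return float(res.pvalue), float(odds)


def wilcoxon_ranksum(x, y) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value."""
    res = stats.mannwhitneyu(x, y, alternative="two-sided")
    return float(res.pvalue)


def pearson(x, y) -> float:
    """Pearson correlation coefficient."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    return float(stats.pearsonr(x[keep], y[keep]).statistic)
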