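"""Benchmark statistics against brute-force oracles and hand-worked examples.

The oracles deliberately avoid the implementation's code paths: AUROC is the
mean over all positive-negative pairs of the rank-order indicator, AUPRC is
an explicit loop over unique thresholds, and REC90/matched-recall scan every
threshold directly.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from compscore.benchmark import (
    ConfusionCounts,
    auprc,
    auprc_norm,
    auroc,
    confusion_at_threshold,
    fisher_exact,
    matched_recall_threshold,
    mcc,
    pearson,
    pr_curve,
    rec90,
    summarize,
    wilcoxon_ranksum,
)
from compscore.errors import DegenerateSetError, InputError


# ---------------------------------------------------------------- oracles --
def brute_auroc(scores, labels):
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = (pos[:, None] > neg[None, :]).sum() + 0.5 * (pos[:, None] == neg[None, :]).sum()
    return wins / (pos.size * neg.size)


def brute_pr_points(scores, labels):
    points = []
    for t in sorted(set(scores), reverse=True):
        pred = scores >= t
        tp = np.sum(pred & (labels == 1))
        points.append((t, tp / np.sum(labels == 1), tp / pred.sum()))
    return points


def brute_auprc(scores, labels):
    area, prev_recall = 0.0, 0.0
    for _, recall, precision in brute_pr_points(scores, labels):
        area += (recall - prev_recall) * precision
        prev_recall = recall
    return area


def random_instance(rng, n_max=200):
    n = int(rng.integers(10, n_max + 1))
    # mix continuous and heavily tied score sets
    if rng.random() < 0.5:
        scores = rng.normal(size=n)
    else:
        scores = rng.choice([0.0, 0.2, 0.6, 0.8, 1.0], size=n)
    labels = rng.integers(0, 2, size=n)
    if labels.min() == labels.max():
        labels[0] = 1 - labels[0]
    return scores, labels


# ------------------------------------------------------------------ tests --
class TestConfusion:
    def test_hand_enumerated_counts(self):
        scores = np.array([1, 0.8, 0.6, 0, 0, 0.6])
        labels = np.array([1, 1, 1, 0, 0, 0])
        c = confusion_at_threshold(scores, labels, 0.6)
        assert (c.tp, c.fp, c.tn, c.fn) == (3, 1, 2, 0)

    def test_perfect_separator_has_no_errors(self):
        c = confusion_at_threshold([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0], 0.5)
        assert c.fp == 0 and c.fn == 0

    def test_all_below_threshold(self):
        c = confusion_at_threshold([0.1, 0.2, 0.3], [1, 0, 1], 0.9)
        assert c.tp == 0 and c.fp == 0

    def test_missing_scores_excluded_and_counted(self):
        c = confusion_at_threshold([0.9, np.nan, 0.1], [1, 1, 0], 0.5)
        assert c.n_excluded == 1 and c.tp == 1 and c.tn == 1

    def test_single_class_is_degenerate(self):
        with pytest.raises(DegenerateSetError):
            confusion_at_threshold([0.1, 0.9], [1, 1], 0.5)


class TestPRCurve:
    def test_perfect_separator_auprc_one(self):
        assert auprc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == pytest.approx(1.0)

    def test_constant_scorer_collapses_to_prior(self):
        curve = pr_curve([0.5] * 8, [1, 1, 0, 0, 0, 0, 0, 0])
        assert curve.recall.tolist() == [1.0]
        assert curve.precision.tolist() == [0.25]
        assert auprc(curve) == pytest.approx(0.25)

    def test_random_scores_near_prior(self, rng):
        n = 2000
        scores = rng.normal(size=n)
        labels = rng.integers(0, 2, size=n)
        assert auprc(scores, labels) == pytest.approx(np.mean(labels), abs=0.03)

    def test_matches_brute_force_on_random_instances(self, rng):
        for _ in range(200):
            s, y = random_instance(rng)
            assert auprc(s, y) == pytest.approx(brute_auprc(s, y), abs=1e-12)

    def test_monotone_transform_invariance(self, rng):
        s, y = random_instance(rng)
        assert auprc(np.exp(3 * s), y) == pytest.approx(auprc(s, y), abs=1e-12)
        assert auroc(np.exp(3 * s), y) == pytest.approx(auroc(s, y), abs=1e-12)


class TestAuroc:
    def test_perfect_separator(self):
        assert auroc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_three_point_pair_enumeration(self):
        assert auroc([0.9, 0.4, 0.6], [1, 0, 1]) == 1.0

    def test_null_scores_near_half(self, rng):
        n = 5000
        assert auroc(rng.normal(size=n), rng.integers(0, 2, size=n)) == pytest.approx(
            0.5, abs=0.02
        )

    def test_matches_pairwise_brute_force(self, rng):
        for _ in range(200):
            s, y = random_instance(rng)
            assert auroc(s, y) == pytest.approx(brute_auroc(s, y), abs=1e-12)


class TestMcc:
    def test_perfect_and_independent(self):
        assert mcc(ConfusionCounts(5, 0, 5, 0)) == pytest.approx(1.0)
        assert mcc(ConfusionCounts(5, 5, 5, 5)) == 0.0

    def test_hand_arithmetic(self):
        assert mcc(ConfusionCounts(tp=3, fp=1, tn=2, fn=0)) == pytest.approx(
            6 / np.sqrt(72), abs=1e-12
        )

    def test_degenerate_margin_flagged_zero(self):
        assert mcc(ConfusionCounts(tp=0, fp=0, tn=5, fn=5)) == 0.0

    def test_matches_sklearn_on_random_confusions(self, rng):
        from sklearn.metrics import matthews_corrcoef

        for _ in range(50):
            y = rng.integers(0, 2, size=60)
            p = rng.integers(0, 2, size=60)
            c = ConfusionCounts(
                tp=int(np.sum((y == 1) & (p == 1))),
                fp=int(np.sum((y == 0) & (p == 1))),
                tn=int(np.sum((y == 0) & (p == 0))),
                fn=int(np.sum((y == 1) & (p == 0))),
            )
            assert mcc(c) == pytest.approx(matthews_corrcoef(y, p), abs=1e-12)


class TestRec90:
    def test_perfect_scorer_full_recall(self):
        assert rec90(pr_curve([0.9, 0.8, 0.2], [1, 1, 0])) == 1.0

    def test_useless_scorer_zero(self):
        curve = pr_curve([0.5] * 10, [1] * 5 + [0] * 5)
        assert rec90(curve) == 0.0

    def test_scans_all_points(self):
        # synthetic curve points {(0.4, 0.95), (0.7, 0.91), (1.0, 0.6)}
        from compscore.benchmark import PRCurve

        curve = PRCurve(
            thresholds=np.array([0.9, 0.5, 0.1]),
            recall=np.array([0.4, 0.7, 1.0]),
            precision=np.array([0.95, 0.91, 0.6]),
            prior=0.5,
        )
        assert rec90(curve) == pytest.approx(0.7)

    def test_never_exceeds_recall_at_lowest_threshold(self, rng):
        for _ in range(50):
            s, y = random_instance(rng, n_max=80)
            curve = pr_curve(s, y)
            assert rec90(curve) <= curve.recall[-1]


class TestMatchedRecall:
    def test_hand_enumerated_threshold(self):
        t = matched_recall_threshold([0.9, 0.8, 0.7, 0.3], [1, 1, 0, 1], 2 / 3)
        assert t == pytest.approx(0.8)

    def test_full_recall_needs_minimum_positive_score(self):
        scores = np.array([0.9, 0.5, 0.3, 0.7])
        labels = np.array([1, 1, 0, 0])
        assert matched_recall_threshold(scores, labels, 1.0) == pytest.approx(0.5)

    def test_unachievable_recall_rejected(self):
        with pytest.raises(InputError):
            matched_recall_threshold([0.9, 0.1], [1, 0], 1.5)


class TestAuprcNorm:
    def test_constant_scorer_is_one(self):
        assert auprc_norm([0.5] * 8, [1, 1, 0, 0, 0, 0, 0, 0]) == pytest.approx(1.0)

    def test_perfect_scorer_is_inverse_prior(self):
        assert auprc_norm([1, 1, 0, 0, 0, 0, 0, 0], [1, 1, 0, 0, 0, 0, 0, 0]) == pytest.approx(
            4.0
        )

    def test_binormal_cohort_matches_large_n_estimate(self, rng):
        # binormal d = 1.81 (AUROC 0.90), prior 0.5: compare the package value
        # on 5000/class against an independent Monte-Carlo estimate
        d = 1.8124
        reps = []
        for _ in range(5):
            pos = rng.normal(d, 1, size=5000)
            neg = rng.normal(0, 1, size=5000)
            scores = np.r_[pos, neg]
            labels = np.r_[np.ones(5000), np.zeros(5000)]
            reps.append(auprc_norm(scores, labels))
        pos = rng.normal(d, 1, size=5000)
        neg = rng.normal(0, 1, size=5000)
        value = auprc_norm(np.r_[pos, neg], np.r_[np.ones(5000), np.zeros(5000)])
        se = np.std(reps, ddof=1)
        assert abs(value - np.mean(reps)) < 3 * max(se, 1e-3)


class TestAssociationTests:
    def test_fisher_one_sided_enumeration(self):
        # [[5,0],[0,5]]: only 1 of C(10,5)=252 tables is as extreme
        p, odds = fisher_exact([[5, 0], [0, 5]], sided="one")
        assert p == pytest.approx(1 / 252, abs=1e-12)
        assert odds == np.inf

    def test_identical_rows_give_p_one(self):
        p, odds = fisher_exact([[10, 5], [10, 5]], sided="two")
        assert p == pytest.approx(1.0)
        assert odds == pytest.approx(1.0)

    def test_specificity_contrast_matches_reported_significance(self):
        # 23/64 vs 8/64 deleterious calls among nondisease variants
        p, odds = fisher_exact([[23, 41], [8, 56]], sided="two")
        assert odds == pytest.approx((23 * 56) / (41 * 8), abs=1e-9)
        assert p < 0.005

    def test_negative_counts_rejected(self):
        with pytest.raises(InputError):
            fisher_exact([[1, -2], [3, 4]])

    def test_ranksum_detects_shift(self, rng):
        x = rng.normal(1.5, 1, size=100)
        y = rng.normal(0.0, 1, size=100)
        assert wilcoxon_ranksum(x, y) < 1e-6
        assert wilcoxon_ranksum(x, x) > 0.5

    def test_pearson_ignores_missing_pairs(self):
        x = [1.0, 2.0, np.nan, 4.0]
        y = [2.0, 4.0, 1.0, 8.0]
        assert pearson(x, y) == pytest.approx(1.0)


class TestSummarize:
    def test_cross_checked_against_sklearn(self, medium_cohort):
        from sklearn.metrics import average_precision_score, roc_auc_score

        labels = medium_cohort["label"].to_numpy()
        scores = medium_cohort["predictor"].to_numpy()
        s = summarize(scores, labels, "predictor", threshold=0.5)
        assert s.auroc == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)
        assert s.auprc == pytest.approx(average_precision_score(labels, scores), abs=1e-12)
        assert s.auprc_norm == pytest.approx(s.auprc / s.prior, abs=1e-12)

    def test_fcs_summary_on_informative_cohort(self, medium_cohort):
        s = summarize(medium_cohort["fcs"], medium_cohort["label"], "fcs", threshold=0.6)
        assert 0.5 < s.auroc <= 1
        assert s.mcc > 0.5
        assert s.threshold_used_for_mcc == 0.6


@settings(max_examples=60, deadline=None, derandomize=True)
@given(st.integers(0, 2**32 - 1))
def test_metric_oracle_equivalence_property(seed):
    """auprc/auroc agree with brute force to 1e-12 on arbitrary instances."""
    rng = np.random.default_rng(seed)
    s, y = random_instance(rng, n_max=120)
    assert auprc(s, y) == pytest.approx(brute_auprc(s, y), abs=1e-12)
    assert auroc(s, y) == pytest.approx(brute_auroc(s, y), abs=1e-12)
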