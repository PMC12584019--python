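"""ROC metric core against brute-force oracles and published cell arithmetic."""

import numpy as np
import pytest

from clinstage import (
    ConfusionMatrix,
    UndefinedMetricError,
    auc,
    confusion_at_cutoff,
    metrics_from_confusion,
    optimal_cutoff_youden,
)
from clinstage._round import round_half_up


def pair_count_auc(scores, labels):
    """O(n^2) Mann-Whitney oracle: P(pos > neg) + 0.5 P(tie)."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    pos, neg = s[y], s[~y]
    wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
    return wins / (len(pos) * len(neg))


def brute_force_best_cutoff(scores, labels):
    """Exhaustive Youden search over all 301 integer cutoffs, smallest wins.

    Compares Youden as exact rationals so that mathematically tied cutoffs
    are really ties (float arithmetic would order them arbitrarily).
    """
    from fractions import Fraction

    best_c, best_j = None, Fraction(-2)
    for c in range(301):
        cm = confusion_at_cutoff(scores, labels, c)
        pos, neg = cm.tp + cm.fn, cm.tn + cm.fp
        j = Fraction(cm.tp, pos) + Fraction(cm.tn, neg) - 1
        if j > best_j:
            best_c, best_j = c, j
    return best_c, float(best_j)


class TestConfusionAtCutoff:
    def test_perfect_split(self):
        cm = confusion_at_cutoff([100, 200], [False, True], 150)
        assert (cm.tp, cm.fp, cm.tn, cm.fn) == (1, 0, 1, 0)

    def test_positive_prediction_is_score_geq_cutoff(self):
        cm = confusion_at_cutoff([150], [True], 150)
        assert cm.tp == 1  # boundary score counts as predicted positive

    def test_all_below_cutoff(self):
        cm = confusion_at_cutoff([10, 20, 30], [True, False, False], 200)
        assert cm.tp == 0 and cm.fp == 0 and cm.tn + cm.fn == 3

    def test_length_mismatch_and_empty(self):
        with pytest.raises(ValueError, match="mismatch"):
            confusion_at_cutoff([1, 2], [True], 1)
        with pytest.raises(ValueError, match="empty"):
            confusion_at_cutoff([], [], 1)


class TestMetricArithmetic:
    @pytest.mark.parametrize(
        "cells, expected",
        [
            ((12, 93, 162, 3), (0.800, 0.635, 0.644, 0.435)),
            ((19, 63, 79, 4), (0.826, 0.556, 0.594, 0.382)),
            ((1, 0, 1, 0), (1.0, 1.0, 1.0, 1.0)),
        ],
    )
    def test_published_rows_and_perfect_case(self, cells, expected):
        m = metrics_from_confusion(ConfusionMatrix(*cells))
        got = tuple(
            round_half_up(m[k], 3)
            for k in ("sensitivity", "specificity", "accuracy", "youden")
        )
        assert got == expected

    def test_youden_identity_exact(self):
        m = metrics_from_confusion(ConfusionMatrix(7, 11, 13, 5))
        assert m["youden"] == m["sensitivity"] + m["specificity"] - 1.0

    def test_undefined_metrics_raise(self):
        with pytest.raises(UndefinedMetricError, match="no positive"):
            metrics_from_confusion(ConfusionMatrix(0, 5, 5, 0))
        with pytest.raises(UndefinedMetricError, match="no negative"):
            metrics_from_confusion(ConfusionMatrix(5, 0, 0, 5))


class TestAUC:
    def test_perfect_separation(self):
        assert auc([1, 2, 10, 11], [False, False, True, True]) == 1.0

    def test_pure_ties(self):
        assert auc([5, 5, 5, 5], [True, False, True, False]) == 0.5

    def test_matches_pair_counting_oracle(self, rng):
        for _ in range(50):
            n = rng.integers(4, 50)
            scores = rng.integers(0, 301, n)
            labels = rng.random(n) < 0.5
            if labels.all() or not labels.any():
                continue
            assert auc(scores, labels) == pytest.approx(
                pair_count_auc(scores, labels), abs=1e-12
            )

    def test_single_class_errors(self):
        with pytest.raises(UndefinedMetricError):
            auc([1, 2], [True, True])


class TestOptimalCutoff:
    def test_tie_break_smallest(self):
        m = optimal_cutoff_youden([10, 20, 200, 210], [False, False, True, True])
        assert m.cutoff == 21 and m.youden == 1.0

    def test_matches_exhaustive_oracle(self, rng):
        for _ in range(50):
            n = rng.integers(4, 40)
            scores = rng.integers(0, 301, n)
            labels = rng.random(n) < 0.4
            if labels.all() or not labels.any():
                continue
            m = optimal_cutoff_youden(scores, labels)
            c, j = brute_force_best_cutoff(scores, labels)
            assert m.cutoff == c
            assert m.youden == pytest.approx(j, abs=1e-12)

    def test_table2_fixture_step1_youden_lower_bound(self, table2_cohort):
        # The published cutoff's Youden bounds the maximum from below on any
        # cohort reproducing the published cells.
        scores = table2_cohort.admission_scores
        labels = table2_cohort.td_levels >= 3
        m = optimal_cutoff_youden(scores, labels)
        assert m.youden >= 0.435 - 1e-12

    def test_excluded_candidates_skip_values(self):
        scores = [10, 20, 200, 210]
        labels = [False, False, True, True]
        m = optimal_cutoff_youden(scores, labels, excluded_candidates={21})
        assert m.cutoff == 22  # next-smallest maximizer

    def test_single_class_errors(self):
        with pytest.raises(UndefinedMetricError):
            optimal_cutoff_youden([1, 2], [False, False])
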