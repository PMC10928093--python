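"""Diagnostic metrics, operating points, bootstrap, splits, agreement."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spongemil import evaluation as ev


def brute_force_auroc(scores, labels):
    """Pairwise Mann-Whitney statistic with ties counted one half."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))


class TestAuroc:
    def test_perfect_separation(self):
        assert ev.auroc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_all_tied_scores_give_half(self):
        assert ev.auroc([0.5] * 6, [0, 1, 0, 1, 0, 1]) == 0.5

    def test_six_point_toy_matches_pair_counting(self):
        scores = [0.2, 0.4, 0.4, 0.6, 0.7, 0.3]
        labels = [0, 1, 0, 1, 1, 0]
        assert ev.auroc(scores, labels) == pytest.approx(
            brute_force_auroc(scores, labels))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            ev.auroc([0.1, 0.9], [1, 1])

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(st.integers(0, 10_000))
    def test_equals_brute_force_on_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 50))
        labels = np.zeros(n, dtype=int)
        labels[:max(1, int(rng.integers(1, n)))] = 1
        rng.shuffle(labels)
        if labels.sum() in (0, n):
            labels[0] = 1 - labels[0]
        scores = rng.choice(np.linspace(0, 1, 11), size=n)  # induce ties
        assert ev.auroc(scores, labels) == pytest.approx(
            brute_force_auroc(scores, labels), abs=1e-12)


class TestConfusionMetrics:
    def test_hand_built_two_by_two(self):
        # TP=8, FN=2, FP=3, TN=7
        scores = [0.9] * 8 + [0.1] * 2 + [0.9] * 3 + [0.1] * 7
        labels = [1] * 10 + [0] * 10
        m = ev.confusion_metrics(scores, labels, 0.5)
        assert m["sensitivity"] == pytest.approx(0.8)
        assert m["specificity"] == pytest.approx(0.7)
        assert m["accuracy"] == pytest.approx(0.75)

    def test_threshold_zero_gives_full_sensitivity(self):
        m = ev.confusion_metrics([0.0, 0.3, 0.9], [1, 1, 1, ][0:3], 0.0)
        assert m["sensitivity"] == 1.0

    def test_threshold_above_one_gives_full_specificity(self):
        m = ev.confusion_metrics([0.2, 0.9], [0, 0], 1.0 + 1e-9)
        assert m["specificity"] == 1.0

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(3)
        scores = rng.random(200)
        labels = (rng.random(200) < 0.4).astype(int)
        prev_sens, prev_spec = 1.1, -0.1
        for thr in np.linspace(0, 1.01, 30):
            m = ev.confusion_metrics(scores, labels, thr)
            assert m["sensitivity"] <= prev_sens + 1e-12
            assert m["specificity"] >= prev_spec - 1e-12
            prev_sens, prev_spec = m["sensitivity"], m["specificity"]


class TestChooseThreshold:
    def brute_force(self, scores, labels, target):
        candidates = sorted(set(scores), reverse=True)
        for cand in candidates:
            sens = ev.confusion_metrics(scores, labels, cand)["sensitivity"]
            if sens >= target:
                return cand
        return min(scores)

    def test_matches_exhaustive_scan(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            scores = np.round(rng.random(10), 2)
            labels = (rng.random(10) < 0.5).astype(int)
            if labels.sum() == 0:
                labels[0] = 1
            for target in (0.5, 0.85, 1.0):
                op = ev.choose_threshold(scores, labels, target)
                assert op.threshold == pytest.approx(
                    self.brute_force(list(scores), labels, target))
                assert op.achieved_sensitivity >= target or \
                    op.threshold == scores.min()

    def test_target_one_at_most_min_positive_score(self):
        scores = np.array([0.1, 0.4, 0.6, 0.8])
        labels = np.array([0, 1, 0, 1])
        op = ev.choose_threshold(scores, labels, 1.0)
        assert op.threshold <= 0.4
        assert op.achieved_sensitivity == 1.0

    def test_no_positives_rejected(self):
        with pytest.raises(ValueError):
            ev.choose_threshold([0.2, 0.3], [0, 0], 0.85)


class TestBootstrap:
    def test_constant_metric_gives_point_interval(self):
        scores = np.array([0.9] * 10 + [0.1] * 10)
        labels = np.array([1] * 10 + [0] * 10)
        acc = lambda s, l: ev.confusion_metrics(s, l, 0.5)["accuracy"]
        lo, hi = ev.bootstrap_ci(acc, scores, labels, n_boot=200, seed=0)
        assert lo == hi == 1.0

    def test_seeded_determinism(self):
        rng = np.random.default_rng(8)
        scores = rng.random(50)
        labels = (rng.random(50) < 0.5).astype(int)
        a = ev.bootstrap_ci(ev.auroc, scores, labels, n_boot=100, seed=3)
        b = ev.bootstrap_ci(ev.auroc, scores, labels, n_boot=100, seed=3)
        assert a == b

    def test_interval_ordered(self):
        rng = np.random.default_rng(9)
        scores = rng.random(60)
        labels = (rng.random(60) < 0.4).astype(int)
        lo, hi = ev.bootstrap_ci(ev.auroc, scores, labels, n_boot=200, seed=1)
        assert lo <= hi


class TestMetricSet:
    def test_perfect_classifier_all_ones_with_tight_cis(self):
        scores = np.array([0.9] * 8 + [0.1] * 8)
        labels = np.array([1] * 8 + [0] * 8)
        m = ev.metric_set(scores, labels, threshold=0.5, n_boot=100, seed=0)
        assert m.auroc == m.aupr == m.accuracy == 1.0
        assert m.sensitivity == m.specificity == 1.0
        for lo, hi in m.ci.values():
            assert lo <= hi <= 1.0


class TestStratifiedSplits:
    @staticmethod
    def _table(n=100):
        # exactly n/4 slides in each (label, pathway) stratum
        rows = []
        for i in range(n):
            rows.append({"slide_id": f"s{i}", "label": i % 2,
                         "pathway": ("surveillance", "screening")[(i // 2) % 2]})
        return pd.DataFrame(rows)

    def test_balanced_arithmetic(self):
        plan = ev.stratified_splits(self._table(100), n_folds=4,
                                    test_fraction=0.2, seed=0)
        assert (plan["split"] == "test").sum() == 20
        dev = plan[plan["split"] == "dev"]
        for fold in range(4):
            assert (dev["fold"] == fold).sum() == 20

    def test_stratum_proportions_within_one(self):
        labels = self._table(100)
        plan = ev.stratified_splits(labels, seed=1).merge(labels, on="slide_id")
        for (_, _), group in plan.groupby(["label", "pathway"]):
            n_stratum = len(group)
            n_test = (group["split"] == "test").sum()
            assert abs(n_test - 0.2 * n_stratum) <= 1
            dev = group[group["split"] == "dev"]
            for fold in range(4):
                assert abs((dev["fold"] == fold).sum() - len(dev) / 4) <= 1

    def test_partition_is_disjoint_and_total(self):
        labels = self._table(60)
        plan = ev.stratified_splits(labels, seed=2)
        assert sorted(plan["slide_id"]) == sorted(labels["slide_id"])
        assert plan["slide_id"].is_unique


class TestJaccard:
    def test_identical_sets(self):
        assert ev.jaccard_agreement({1, 2}, {1, 2}) == 1.0

    def test_disjoint_sets(self):
        assert ev.jaccard_agreement({1}, {2}) == 0.0

    def test_hand_case(self):
        assert ev.jaccard_agreement({1, 2, 3}, {2, 3, 4}) == 0.5

    def test_both_empty_defined_as_one(self):
        assert ev.jaccard_agreement(set(), set()) == 1.0


class TestCohortSummary:
    def test_positive_percentage_rounding(self):
        df = pd.DataFrame({"label": [1] * 348 + [0] * 564})
        out = ev.cohort_summary({"development": df})
        assert out.iloc[0]["pct_pos"] == 38.2

    def test_overall_row_sums(self):
        a = pd.DataFrame({"label": [1, 0, 0]})
        b = pd.DataFrame({"label": [1, 1, 0]})
        out = ev.cohort_summary({"a": a, "b": b})
        total = out[out["dataset"] == "total"].iloc[0]
        assert total["n"] == 6 and total["n_pos"] == 3

    def test_empty_table_no_crash(self):
        out = ev.cohort_summary({})
        assert len(out) == 0
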