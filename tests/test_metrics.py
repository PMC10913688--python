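import numpy as np
import pytest
from hypothesis import given, strategies as st

import oracles
from promoter5mc.metrics import (
    ConfusionCounts, MetricsReport, confusion, f1_from_confusion,
    mean_report, metrics_from_confusion, pr_auc, roc_auc,
)


def _random_scores(seed, n=50):
    rng = np.random.default_rng(seed)
    labels = rng.integers(0, 2, n)
    scores = np.round(rng.random(n), 2)  # rounding forces some ties
    if labels.min() == labels.max():
        labels[0] = 1 - labels[0]
    return labels, scores


class TestConfusion:
    def test_simple_tally(self):
        c = confusion([1, 0], [0.9, 0.1], 0.5)
        assert (c.tp, c.tn, c.fp, c.fn) == (1, 1, 0, 0)

    def test_threshold_zero_predicts_all_positive(self):
        c = confusion([1, 0, 1], [0.0, 0.3, 0.9], 0.0)
        assert c.tn == 0 and c.fn == 0
        assert c.tp == 2 and c.fp == 1

    def test_matches_loop_tally_on_random_data(self):
        labels, scores = _random_scores(0, n=200)
        c = confusion(labels, scores, 0.5)
        assert (c.tp, c.tn, c.fp, c.fn) == oracles.confusion_loop(labels, scores, 0.5)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            confusion([1, 0], [0.5])

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(1, 1, -1, 0)


class TestEq3Metrics:
    def test_perfect_classifier(self):
        assert metrics_from_confusion(ConfusionCounts(1, 1, 0, 0)) == (1, 1, 1, 1)

    def test_worked_example(self):
        sn, sp, acc, mcc = metrics_from_confusion(ConfusionCounts(3, 4, 1, 2))
        assert sn == pytest.approx(0.6)
        assert sp == pytest.approx(0.8)
        assert acc == pytest.approx(0.7)
        assert mcc == pytest.approx(10 / np.sqrt(600))

    def test_all_negative_predictions_convention(self):
        sn, sp, acc, mcc = metrics_from_confusion(ConfusionCounts(0, 5, 0, 3))
        assert sn == 0.0 and mcc == 0.0 and sp == 1.0

    @pytest.mark.parametrize("seed", range(10))
    def test_brute_force_recomputation(self, seed):
        # 200 random confusion matrices against the loop-free reference
        rng = np.random.default_rng(seed)
        for _ in range(20):
            tp, tn, fp, fn = (int(v) for v in rng.integers(0, 10_000, 4))
            if tp + tn + fp + fn == 0:
                continue
            got = metrics_from_confusion(ConfusionCounts(tp, tn, fp, fn))
            expected = oracles.eq3_metrics(tp, tn, fp, fn)
            np.testing.assert_allclose(got, expected, atol=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_acc_is_prevalence_weighted_combination(self, seed):
        rng = np.random.default_rng(seed)
        tp, tn, fp, fn = (int(v) for v in rng.integers(1, 1000, 4))
        sn, sp, acc, _ = metrics_from_confusion(ConfusionCounts(tp, tn, fp, fn))
        p, n = tp + fn, tn + fp
        assert acc == (p * sn + n * sp) / (p + n)

    def test_mcc_symmetric_under_class_swap(self):
        a = metrics_from_confusion(ConfusionCounts(30, 40, 10, 20))[3]
        b = metrics_from_confusion(ConfusionCounts(40, 30, 20, 10))[3]
        assert a == pytest.approx(b, abs=1e-15)


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9]) == 1.0

    def test_all_ties_give_half(self):
        assert roc_auc([0, 1, 0, 1], [0.5] * 4) == 0.5

    @pytest.mark.parametrize("seed", range(30))
    def test_equals_pairwise_statistic(self, seed):
        labels, scores = _random_scores(seed, n=30)
        assert roc_auc(labels, scores) == pytest.approx(
            oracles.pairwise_auc(labels, scores), abs=1e-12)

    def test_monotone_transform_invariance(self):
        labels, scores = _random_scores(3)
        transformed = scores ** 3  # strictly monotone on [0, 1]
        assert roc_auc(labels, scores) == pytest.approx(roc_auc(labels, transformed))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1, 1], [0.2, 0.4])


class TestPrAucAndF1:
    def test_perfect_classifier(self):
        assert pr_auc([0, 1], [0.1, 0.9]) == 1.0
        assert f1_from_confusion(ConfusionCounts(5, 5, 0, 0)) == 1.0

    def test_f1_worked_example(self):
        assert f1_from_confusion(ConfusionCounts(3, 0, 1, 2)) == pytest.approx(6 / 9)

    def test_f1_zero_denominator_convention(self):
        assert f1_from_confusion(ConfusionCounts(0, 10, 0, 0)) == 0.0

    @pytest.mark.parametrize("seed", range(20))
    def test_equals_threshold_sweep_oracle(self, seed):
        labels, scores = _random_scores(seed + 100, n=40)
        assert pr_auc(labels, scores) == pytest.approx(
            oracles.stepwise_pr_auc(labels, scores), abs=1e-12)

    def test_no_positives_rejected(self):
        with pytest.raises(ValueError):
            pr_auc([0, 0], [0.2, 0.4])


class TestReport:
    def test_from_scores_fields_in_range(self):
        labels, scores = _random_scores(1)
        r = MetricsReport.from_scores(labels, scores)
        for name in ("sn", "sp", "acc", "auc", "f1", "pr_auc"):
            assert 0.0 <= getattr(r, name) <= 1.0
        assert -1.0 <= r.mcc <= 1.0

    def test_mean_report_is_fieldwise_arithmetic_mean(self):
        reports = [MetricsReport.from_scores(*_random_scores(s)) for s in range(5)]
        mean = mean_report(reports)
        for name in ("sn", "sp", "acc", "mcc", "auc", "f1", "pr_auc"):
            expected = float(np.mean([getattr(r, name) for r in reports]))
            assert abs(getattr(mean, name) - expected) <= 1e-12

    @given(st.floats(0.05, 0.95))
    def test_threshold_recorded(self, threshold):
        labels, scores = _random_scores(2)
        assert MetricsReport.from_scores(labels, scores, threshold).threshold == threshold
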