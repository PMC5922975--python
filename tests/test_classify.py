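"""Window-label aggregation, SVM training, soft rule, metrics, ethograms."""

import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from hydramotion.classes import NAME_TO_CLASS
from hydramotion.classify import (
    Ethogram,
    aggregate_window_label,
    auc_trapezoid,
    class_weights,
    evaluate,
    predict_hard,
    predict_soft,
    roc_curve_points,
    summarize_ethogram,
    train,
)
from hydramotion.config import PipelineConfig

SIL = NAME_TO_CLASS["silent"].code          # 1
CON = NAME_TO_CLASS["contraction"].code     # 6


class TestWindowLabelRule:
    def test_prominent_minority_wins_within_threefold(self):
        labels = [SIL] * 18 + [CON] * 7
        assert aggregate_window_label(labels) == CON

    def test_majority_wins_beyond_threefold(self):
        labels = [SIL] * 20 + [CON] * 5
        assert aggregate_window_label(labels) == SIL

    def test_unanimous(self):
        elo = NAME_TO_CLASS["elongation"].code
        assert aggregate_window_label([elo] * 25) == elo

    def test_none_frames_ignored(self):
        assert aggregate_window_label([0] * 20 + [CON] * 5) == CON

    def test_all_none_window(self):
        assert aggregate_window_label([0] * 25) == 0

    def test_less_prominent_minority_never_wins(self):
        labels = [CON] * 18 + [SIL] * 7
        assert aggregate_window_label(labels) == CON


class TestTraining:
    def test_class_weights_formula(self):
        w = class_weights([1] * 100 + [2] * 300)
        assert w[1] == pytest.approx(4.0)
        assert w[2] == pytest.approx(4.0 / 3.0)

    def test_separable_two_class(self, rng):
        cfg = PipelineConfig(log2_c_grid=(-1, 3), log2_g_grid=(-3, 1))
        X = np.vstack([rng.normal(-5, 0.2, (30, 4)),
                       rng.normal(+5, 0.2, (30, 4))])
        y = np.array([1] * 30 + [2] * 30)
        model = train(X, y, cfg, seed=0)
        eth = predict_hard(model, X, config=cfg)
        assert np.mean(eth.hard_labels() == y) == 1.0

    def test_seed_determinism(self, rng):
        cfg = PipelineConfig(log2_c_grid=(-1, 3, 7), log2_g_grid=(-3, 1))
        X = np.vstack([rng.normal(-1, 1, (25, 4)), rng.normal(1, 1, (25, 4))])
        y = np.array([1] * 25 + [2] * 25)
        a = train(X, y, cfg, seed=5)
        b = train(X, y, cfg, seed=5)
        assert a.best_params == b.best_params
        Xq = rng.normal(0, 1, (10, 4))
        assert np.array_equal(predict_hard(a, Xq).hard_labels(),
                              predict_hard(b, Xq).hard_labels())

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError):
            train(rng.normal(0, 1, (20, 3)), [1] * 20)


class TestSoftRule:
    def _eth(self, probs):
        """Build the ethogram a model with these class probs would emit."""
        class FakeModel:
            classes = np.arange(1, len(probs) + 1)

            class pca:
                @staticmethod
                def transform(X):
                    return X

            class svc:
                @staticmethod
                def predict_proba(X):
                    return np.array([probs])

        return FakeModel()

    def test_second_kept_third_fails_strict(self):
        eth = predict_soft(self._eth([0.5, 0.3, 0.15, 0.05]), np.zeros((1, 1)))
        assert eth.labels[0] == [1, 2]      # 0.15 is not > 0.5*0.3

    def test_three_labels(self):
        eth = predict_soft(self._eth([0.4, 0.3, 0.2, 0.1]), np.zeros((1, 1)))
        assert eth.labels[0] == [1, 2, 3]

    def test_single_label(self):
        eth = predict_soft(self._eth([0.8, 0.2]), np.zeros((1, 1)))
        assert eth.labels[0] == [1]

    def test_hard_is_argmax(self):
        eth = predict_hard(self._eth([0.2, 0.7, 0.1]), np.zeros((1, 1)))
        assert eth.labels[0] == [2]

    def test_probabilities_non_increasing(self):
        eth = predict_soft(self._eth([0.25, 0.4, 0.35]), np.zeros((1, 1)))
        p = eth.probabilities[0]
        assert all(a >= b for a, b in zip(p, p[1:]))


def _ethogram(label_sets, window_s=5.0):
    return Ethogram([str(i) for i in range(len(label_sets))],
                    [list(s) for s in label_sets],
                    [[1.0 / len(s)] * len(s) for s in label_sets],
                    5.0, window_s)


class TestEvaluate:
    def test_plug_in_numbers(self):
        """TP=9 FP=1 TN=85 FN=5 -> Acc .94, Prc .9, Rec 9/14."""
        truth = [1] * 14 + [2] * 86
        preds = ([[1]] * 9          # TP
                 + [[2]] * 5        # FN
                 + [[1]] * 1        # FP
                 + [[2]] * 85)      # TN
        res = evaluate(_ethogram(preds), truth)
        m = res["per_class"][1]
        assert m["accuracy"] == pytest.approx(0.94)
        assert m["precision"] == pytest.approx(0.9)
        assert m["recall"] == pytest.approx(9 / 14)

    def test_chance_scores_auc_half(self, rng):
        n = 10_000
        truth = rng.integers(0, 2, n).astype(bool)
        scores = rng.uniform(0, 1, n)
        fpr, tpr = roc_curve_points(scores, truth)
        assert auc_trapezoid(fpr, tpr) == pytest.approx(0.5, abs=0.02)

    def test_perfect_scores_auc_one(self):
        truth = np.array([1, 1, 0, 0], bool)
        fpr, tpr = roc_curve_points(np.array([0.9, 0.8, 0.2, 0.1]), truth)
        assert auc_trapezoid(fpr, tpr) == pytest.approx(1.0)

    def test_auc_matches_sklearn(self, rng):
        truth = rng.integers(0, 2, 500).astype(bool)
        scores = rng.normal(truth.astype(float), 1.0)
        fpr, tpr = roc_curve_points(scores, truth)
        assert auc_trapezoid(fpr, tpr) == pytest.approx(
            roc_auc_score(truth, scores), abs=1e-9)

    def test_roc_monotone(self, rng):
        fpr, tpr = roc_curve_points(rng.normal(0, 1, 300),
                                    rng.integers(0, 2, 300).astype(bool))
        assert np.all(np.diff(fpr) >= 0)
        assert np.all(np.diff(tpr) >= 0)

    def test_confusion_rows_sum_to_truth_counts(self):
        truth = [1, 1, 2, 2, 2, 3]
        preds = [[1], [2], [2], [2], [3], [3]]
        res = evaluate(_ethogram(preds), truth)
        cm = res["confusion_matrix"]
        assert cm.loc[2].sum() == 3
        assert cm.loc[1].sum() == 2

    def test_soft_accuracy_at_least_hard(self):
        truth = [1, 2, 3, 1]
        hard_preds = [[1], [3], [3], [2]]
        soft_preds = [[1], [3, 2], [3], [2, 3, 1]]
        hard_acc = evaluate(_ethogram(hard_preds), truth)["overall_accuracy"]
        soft_acc = evaluate(_ethogram(soft_preds), truth)["overall_accuracy"]
        assert soft_acc >= hard_acc

    def test_absent_class_undefined(self):
        res = evaluate(_ethogram([[1], [1]]), [1, 1])
        # class 2 never occurs in truth; nothing to report
        assert 2 not in res["per_class"] or np.isnan(
            res["per_class"][2]["accuracy"])


class TestEthogramSummary:
    def test_all_one_class(self):
        eth = _ethogram([[1]] * 24, window_s=300.0)   # 2-hour ethogram
        summary = summarize_ethogram(eth, block_minutes=30)
        row = summary.set_index("behavior").loc[1]
        assert row["fraction"] == 1.0
        assert row["block_sd"] == 0.0

    def test_identical_blocks_zero_sd(self):
        # 6 windows per 30-min block, alternating 1/2 identically per block
        pattern = [[1], [2], [1], [2], [1], [2]]
        eth = _ethogram(pattern * 4, window_s=300.0)
        summary = summarize_ethogram(eth, block_minutes=30)
        assert (summary["block_sd"] == 0.0).all()

    def test_two_block_sd(self):
        # block 1: fraction 0.2 of class 2; block 2: fraction 0.4
        b1 = [[2]] * 2 + [[1]] * 8
        b2 = [[2]] * 4 + [[1]] * 6
        eth = _ethogram(b1 + b2, window_s=180.0)   # 10 windows per 30 min
        summary = summarize_ethogram(eth, block_minutes=30)
        row = summary.set_index("behavior").loc[2]
        assert row["fraction"] == pytest.approx(0.3)
        assert row["block_sd"] == pytest.approx(np.std([0.2, 0.4]))
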