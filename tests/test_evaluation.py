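"""Metrics against brute-force oracles; slice-weight visualization output."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from slicefuse.evaluation import (
    ConfusionCounts, average_precision, basic_metrics, confusion, evaluate,
    roc_auc, visualize_slices,
)


def _auc_pair_counting(labels, scores):
    """Probability a random positive outscores a random negative; ties 0.5."""
    labels = np.asarray(labels)
    scores = np.asarray(scores)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def _ap_threshold_sweep(labels, scores):
    """Exhaustive sweep over descending score thresholds."""
    labels = np.asarray(labels)
    scores = np.asarray(scores)
    order = np.argsort(-scores, kind="stable")
    labels = labels[order]
    scores = scores[order]
    n_pos = labels.sum()
    ap, prev_recall = 0.0, 0.0
    for thr in np.unique(scores)[::-1]:
        pred = scores >= thr
        tp = int((labels[pred] == 1).sum())
        precision = tp / pred.sum()
        recall = tp / n_pos
        ap += (recall - prev_recall) * precision
        prev_recall = recall
    return ap


class TestConfusion:
    def test_small_example(self):
        c = confusion([1, 1, 0, 0], [0.9, 0.2, 0.8, 0.1])
        assert (c.TP, c.FN, c.FP, c.TN) == (1, 1, 1, 1)

    def test_perfect_confident(self):
        c = confusion([1, 0, 1], [0.99, 0.01, 0.98])
        assert c.FP == 0 and c.FN == 0

    def test_tie_predicts_positive(self):
        c = confusion([0], [0.5])
        assert c.FP == 1 and c.TN == 0

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            confusion([1, 0], [0.5])


class TestBasicMetrics:
    def test_hand_arithmetic(self):
        acc, precision, recall, f1, warn = basic_metrics(
            ConfusionCounts(TP=3, TN=4, FP=2, FN=1))
        assert acc == pytest.approx(0.7)
        assert precision == pytest.approx(0.6)
        assert recall == pytest.approx(0.75)
        assert f1 == pytest.approx(2 / 3, abs=1e-9)
        assert warn == []

    def test_perfect(self):
        out = basic_metrics(ConfusionCounts(TP=5, TN=5, FP=0, FN=0))
        assert out[:4] == (1.0, 1.0, 1.0, 1.0)

    def test_zero_denominator_flagged(self):
        acc, precision, recall, f1, warn = basic_metrics(
            ConfusionCounts(TP=0, TN=3, FP=0, FN=1))
        assert precision == 0.0
        assert any("precision" in w for w in warn)

    def test_f1_is_harmonic_mean(self):
        _, p, r, f1, _ = basic_metrics(ConfusionCounts(TP=7, TN=1, FP=3, FN=2))
        assert f1 == pytest.approx(2 * p * r / (p + r))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            basic_metrics(ConfusionCounts(0, 0, 0, 0))


class TestAUC:
    def test_perfect_separation(self):
        assert roc_auc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9]) == 1.0

    def test_all_ties_half(self):
        assert roc_auc([0, 1, 0, 1], [0.5, 0.5, 0.5, 0.5]) == 0.5

    def test_matches_pair_counting_oracle(self, rng):
        for _ in range(10):
            n = int(rng.integers(6, 20))
            labels = rng.integers(0, 2, size=n)
            if len(np.unique(labels)) < 2:
                continue
            scores = np.round(rng.random(n), 2)  # rounding forces some ties
            assert roc_auc(labels, scores) == pytest.approx(
                _auc_pair_counting(labels, scores), abs=1e-10)

    @given(st.lists(st.tuples(st.integers(0, 1), st.floats(0, 1)),
                    min_size=4, max_size=20))
    @settings(deadline=None, max_examples=30)
    def test_monotone_invariance_and_reversal(self, pairs):
        labels = np.array([p[0] for p in pairs])
        # round so the exp transform below cannot merge distinct scores in float64
        scores = np.round(np.array([p[1] for p in pairs]), 3)
        if len(np.unique(labels)) < 2:
            return
        a = roc_auc(labels, scores)
        # strictly monotone transform preserves ranks
        assert roc_auc(labels, np.exp(3 * scores)) == pytest.approx(a, abs=1e-9)
        if len(np.unique(scores)) == len(scores):  # no ties
            assert roc_auc(labels, -scores) == pytest.approx(1 - a, abs=1e-9)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1, 1], [0.3, 0.4])


class TestAveragePrecision:
    def test_perfect_ranking(self):
        assert average_precision([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9]) == 1.0

    @pytest.mark.parametrize("n", [3, 5, 10])
    def test_single_positive_ranked_last(self, n):
        labels = np.zeros(n, int)
        labels[0] = 1
        scores = np.linspace(1.0, 0.1, n)  # positive gets the lowest... reversed below
        labels = labels[::-1].copy()       # positive is the last-ranked sample
        assert average_precision(labels, scores) == pytest.approx(1 / n, abs=1e-12)

    def test_matches_threshold_sweep_oracle(self, rng):
        for _ in range(10):
            n = int(rng.integers(5, 20))
            labels = rng.integers(0, 2, size=n)
            if labels.sum() == 0:
                continue
            scores = rng.random(n)
            assert average_precision(labels, scores) == pytest.approx(
                _ap_threshold_sweep(labels, scores), abs=1e-10)

    def test_no_positives_rejected(self):
        with pytest.raises(ValueError):
            average_precision([0, 0], [0.1, 0.9])


class TestEvaluate:
    def test_pooled_counts_match_independent_pass(self, rng):
        labels = rng.integers(0, 2, size=50)
        labels[:2] = [0, 1]
        scores = rng.random(50)
        rep = evaluate(labels, scores)
        # independent brute-force pass over (label, prediction) pairs
        pred = (scores >= 0.5).astype(int)
        acc = float((pred == labels).mean())
        assert rep.acc == pytest.approx(acc)
        assert rep.confusion.total == 50

    def test_report_serializes(self, rng):
        rep = evaluate([0, 1, 0, 1], [0.2, 0.7, 0.4, 0.9])
        d = rep.as_dict()
        assert set(d) >= {"acc", "auc", "f1", "precision", "recall", "ap", "confusion"}


class TestVisualization:
    def test_three_figures_and_csv(self, tmp_path, rng):
        from slicefuse.network import ModelConfig, build_model
        from slicefuse.volume_io import VolumeSample

        model = build_model(ModelConfig(backbone_id="tiny", pooling="lwp"), seed=0)
        v = VolumeSample("demo", rng.normal(size=(6, 16, 16)), 0)
        paths = visualize_slices(model, v, tmp_path)
        assert len(paths) == 3
        assert all(p.exists() for p in paths)
        data = np.loadtxt(tmp_path / "demo_slice_weights.csv", delimiter=",",
                          skiprows=1)
        assert data.shape == (6, 3)
        assert data[:, 2].sum() == pytest.approx(1.0, abs=1e-6)

    def test_uniform_logits_flat_weight_curve(self, tmp_path):
        from slicefuse.network import ModelConfig, build_model
        from slicefuse.volume_io import VolumeSample

        model = build_model(ModelConfig(backbone_id="tiny", pooling="lwp"), seed=0)
        model.slice_net.head.weight.data[:] = 0.0
        model.slice_net.head.bias.data[:] = 0.0
        v = VolumeSample("flat", np.random.default_rng(0).normal(size=(5, 16, 16)), 0)
        visualize_slices(model, v, tmp_path)
        data = np.loadtxt(tmp_path / "flat_slice_weights.csv", delimiter=",",
                          skiprows=1)
        np.testing.assert_allclose(data[:, 2], 0.2, atol=1e-6)
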