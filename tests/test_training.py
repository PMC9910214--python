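"""Class weights, weighted BCE, stratified folds, and the training loop."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from slicefuse.network import ModelConfig, build_model, prepare_stack
from slicefuse.synthetic import SyntheticSpec, generate_dataset
from slicefuse.training import (
    TrainConfig, compute_class_weights, cross_validate, make_folds, train_model,
    weighted_bce,
)


class TestClassWeights:
    def test_cohort_distribution(self):
        labels = np.array([0] * 214 + [1] * 167)
        w_p, w_n = compute_class_weights(labels)
        assert w_n == 1.0
        assert round(w_p, 2) == 1.28

    def test_balanced(self):
        assert compute_class_weights(np.array([0, 1, 0, 1])) == (1.0, 1.0)

    def test_three_to_one(self):
        assert compute_class_weights(np.array([0, 0, 0, 1])) == (3.0, 1.0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            compute_class_weights(np.ones(5))


class TestWeightedBCE:
    def test_symmetric_point(self):
        assert weighted_bce(0.5, 1) == pytest.approx(np.log(2), abs=1e-12)

    def test_weighted_positive(self):
        assert weighted_bce(0.5, 1, w_p=1.28) == pytest.approx(1.28 * np.log(2), abs=1e-10)

    def test_confident_correct_approaches_zero(self):
        assert weighted_bce(1.0 - 1e-9, 1) < 1e-6
        assert weighted_bce(1e-9, 0) < 1e-6

    def test_clamping_keeps_loss_finite(self):
        assert np.isfinite(weighted_bce(0.0, 1))
        assert np.isfinite(weighted_bce(1.0, 0))

    def test_reduces_to_standard_bce_on_grid(self):
        p = np.linspace(0.01, 0.99, 50)
        for label in (0, 1):
            ours = weighted_bce(p, label, w_p=1.0, w_n=1.0)
            std = -(label * np.log(p) + (1 - label) * np.log(1 - p))
            np.testing.assert_allclose(ours, std, atol=1e-10)


class TestMakeFolds:
    def test_cohort_sizes_and_stratification(self):
        labels = np.array([0] * 214 + [1] * 167)
        fa = make_folds(labels, 5, seed=0)
        sizes = sorted(np.bincount(fa.fold_index, minlength=5))
        assert sizes == [76, 76, 76, 76, 77]
        pos_per_fold = [int((labels[fa.test_indices(k)] == 1).sum()) for k in range(5)]
        assert set(pos_per_fold) <= {33, 34}

    def test_seeded_determinism(self):
        labels = np.array([0, 1] * 20)
        np.testing.assert_array_equal(make_folds(labels, 4, seed=3).fold_index,
                                      make_folds(labels, 4, seed=3).fold_index)

    def test_two_fold_tiny(self):
        fa = make_folds(np.array([0, 0, 1, 1]), 2, seed=0)
        for k in range(2):
            fold_labels = np.array([0, 0, 1, 1])[fa.test_indices(k)]
            assert sorted(fold_labels) == [0, 1]

    @given(st.integers(6, 60), st.integers(2, 5), st.integers(0, 100))
    @settings(deadline=None, max_examples=25)
    def test_partition_properties(self, n, K, seed):
        rng = np.random.default_rng(seed)
        labels = rng.integers(0, 2, size=n)
        if len(np.unique(labels)) < 2 or n < K:
            return
        fa = make_folds(labels, K, seed=seed)
        # exact partition
        assert np.all(fa.fold_index >= 0) and np.all(fa.fold_index < K)
        sizes = np.bincount(fa.fold_index, minlength=K)
        assert sizes.max() - sizes.min() <= 1
        # stratification within 1 of proportionality per fold
        for cls in (0, 1):
            counts = np.bincount(fa.fold_index[labels == cls], minlength=K)
            assert counts.max() - counts.min() <= 1

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            make_folds(np.array([0, 1]), 5)


def _tiny_setup(n_per_class=10, seed=0):
    cfg = ModelConfig(backbone_id="tiny", pooling="lwp", attention_mode="none")
    ds = generate_dataset(SyntheticSpec(n_per_class=n_per_class, shape=(8, 16, 16),
                                        seed=seed))
    stacks = np.stack([prepare_stack(s, cfg) for s in ds.samples])
    return cfg, ds, stacks


class TestTrainModel:
    def test_loss_decreases_on_separable_data(self):
        cfg, ds, stacks = _tiny_setup(10)
        model = build_model(cfg, seed=1)
        _, hist = train_model(model, stacks, ds.labels,
                              TrainConfig(epochs=8, lr=1e-3, seed=1))
        assert len(hist.epoch_loss) == 8
        assert hist.epoch_loss[-1] < hist.epoch_loss[0]
        assert all(np.isfinite(l) and l >= 0 for l in hist.epoch_loss)

    def test_zero_epochs_is_noop(self):
        cfg, ds, stacks = _tiny_setup(3)
        model = build_model(cfg, seed=1)
        before = [p.data.copy() for p in model.parameters()]
        _, hist = train_model(model, stacks, ds.labels,
                              TrainConfig(epochs=0, seed=1))
        assert hist.epoch_loss == []
        for p, b in zip(model.parameters(), before):
            np.testing.assert_array_equal(p.data, b)

    def test_training_is_deterministic(self):
        cfg, ds, stacks = _tiny_setup(4)
        histories = []
        for _ in range(2):
            model = build_model(cfg, seed=2)
            _, hist = train_model(model, stacks, ds.labels,
                                  TrainConfig(epochs=3, lr=1e-3, seed=2))
            histories.append(hist.epoch_loss)
        assert histories[0] == histories[1]

    def test_all_parameter_groups_updated(self):
        cfg = ModelConfig(backbone_id="tiny", pooling="lwp", attention_mode="dual")
        ds = generate_dataset(SyntheticSpec(n_per_class=4, shape=(8, 16, 16), seed=0))
        stacks = np.stack([prepare_stack(s, cfg) for s in ds.samples])
        model = build_model(cfg, seed=1)
        groups = {
            "slice_net": model.slice_net.parameters(),
            "backbone": model.backbone.parameters(),
            "attention": model.attention.parameters(),
            "classifier": model.fc1.parameters() + model.fc3.parameters(),
        }
        before = {k: [p.data.copy() for p in ps] for k, ps in groups.items()}
        train_model(model, stacks, ds.labels, TrainConfig(epochs=1, lr=1e-3, seed=1))
        for name, ps in groups.items():
            changed = any(not np.array_equal(p.data, b)
                          for p, b in zip(ps, before[name]))
            assert changed, f"{name} parameters did not update"

    def test_single_class_rejected(self):
        cfg, ds, stacks = _tiny_setup(3)
        with pytest.raises(ValueError, match="both classes"):
            train_model(build_model(cfg, seed=0), stacks, np.zeros(len(stacks), int),
                        TrainConfig(epochs=1))

    def test_fixed_wp_override(self):
        cfg, ds, stacks = _tiny_setup(3)
        model = build_model(cfg, seed=0)
        _, hist = train_model(model, stacks, ds.labels,
                              TrainConfig(epochs=1, lr=1e-3, seed=0, w_p=1.28))
        assert np.isfinite(hist.epoch_loss[0])


class TestCrossValidate:
    def test_partition_and_sanity_ceiling(self):
        cfg = ModelConfig(backbone_id="tiny", pooling="lwp", attention_mode="none")
        ds = generate_dataset(SyntheticSpec(n_per_class=9, shape=(8, 16, 16), seed=3))
        res = cross_validate(cfg, TrainConfig(epochs=8, lr=1e-3, folds=3, seed=0),
                             ds.samples)
        # every sample scored exactly once out-of-fold
        assert np.all(np.isfinite(res.oof_scores))
        assert len(res.fold_reports) == 3
        covered = np.concatenate([res.folds.test_indices(k) for k in range(3)])
        assert sorted(covered) == list(range(len(ds.samples)))
        # clearly separable phantoms -> near-ceiling pooled accuracy
        assert res.pooled.acc >= 0.9
        assert set(res.fold_mean) == {"acc", "auc", "f1", "precision", "recall", "ap"}

    def test_lwp_not_worse_than_avg_on_band_localized_data(self):
        # on band-localized signal, learnable pooling should hold its own
        # against fixed average pooling (small paired comparison)
        ds = generate_dataset(SyntheticSpec(n_per_class=12, shape=(12, 16, 16),
                                            seed=5))
        accs = {}
        for pooling in ("lwp", "avg"):
            cfg = ModelConfig(backbone_id="tiny", pooling=pooling,
                              attention_mode="none")
            res = cross_validate(cfg, TrainConfig(epochs=8, lr=1e-3, folds=3,
                                                  seed=2), ds.samples)
            accs[pooling] = res.pooled.acc
        assert accs["lwp"] >= accs["avg"] - 0.05

    def test_invalid_config(self):
        with pytest.raises(ValueError):
            TrainConfig(folds=1)
        with pytest.raises(ValueError):
            TrainConfig(lr=0)
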