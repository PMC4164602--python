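"""Backprop MLP: initialisation, forward pass, gradients, training, LOO."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gypsospec.nn_classifier import (
    MLPConfig,
    MLPModel,
    fold_seed,
    forward,
    gradients,
    init_mlp,
    loo_evaluate,
    loo_folds,
    loss,
    one_hot,
    predict_class,
    train,
)
from gypsospec.preprocess import preprocess_set
from gypsospec.spectra_io import CLASS_ORDER, Group


def sigmoid(z):
    return 1.0 / (1.0 + math.exp(-z))


class TestInit:
    def test_shapes_match_reference_architecture(self):
        model = init_mlp(MLPConfig(seed=0))
        assert [w.shape for w in model.weights] == [
            (1882, 100), (100, 100), (100, 3)]
        assert [b.shape for b in model.biases] == [(100,), (100,), (3,)]
        assert all(np.all(b == 0) for b in model.biases)

    def test_zero_init_scale_gives_zero_weights(self):
        model = init_mlp(MLPConfig(layer_sizes=(4, 3, 3), init_scale=0.0))
        assert all(np.all(w == 0) for w in model.weights)

    def test_same_seed_gives_identical_models(self):
        cfg = MLPConfig(layer_sizes=(5, 4, 3), seed=13)
        m1, m2 = init_mlp(cfg), init_mlp(cfg)
        for w1, w2 in zip(m1.weights, m2.weights):
            np.testing.assert_array_equal(w1, w2)

    def test_weights_bounded_by_init_scale(self):
        model = init_mlp(MLPConfig(layer_sizes=(50, 20, 3), init_scale=0.2))
        for w in model.weights:
            assert np.all(np.abs(w) <= 0.2)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            MLPConfig(layer_sizes=(5,))
        with pytest.raises(ValueError):
            MLPConfig(epochs=0)
        with pytest.raises(ValueError):
            MLPConfig(activation="relu")


class TestForward:
    def test_zero_weights_give_one_half_everywhere(self):
        model = init_mlp(MLPConfig(layer_sizes=(7, 4, 3), init_scale=0.0))
        out, acts = forward(model, np.random.default_rng(0).normal(size=7))
        np.testing.assert_allclose(out, 0.5)
        assert len(acts) == 3

    def test_outputs_strictly_inside_unit_interval(self):
        model = init_mlp(MLPConfig(layer_sizes=(6, 5, 3), seed=1))
        for scale in (1.0, 100.0):
            out, _ = forward(model,
                             scale * np.random.default_rng(2).normal(size=6))
            assert np.all(out > 0) and np.all(out < 1)

    def test_matches_hand_computation_on_2_2_1_network(self):
        cfg = MLPConfig(layer_sizes=(2, 2, 1))
        model = MLPModel(
            weights=[np.array([[0.1, -0.3], [0.5, 0.2]]),
                     np.array([[0.7], [-0.4]])],
            biases=[np.array([0.05, -0.1]), np.array([0.2])],
            config=cfg)
        x = np.array([0.3, -0.6])
        h1 = sigmoid(0.3 * 0.1 + (-0.6) * 0.5 + 0.05)
        h2 = sigmoid(0.3 * (-0.3) + (-0.6) * 0.2 + (-0.1))
        y = sigmoid(h1 * 0.7 + h2 * (-0.4) + 0.2)
        out, _ = forward(model, x)
        assert out[0] == pytest.approx(y, abs=1e-12)

    def test_dimension_mismatch_is_an_error(self):
        model = init_mlp(MLPConfig(layer_sizes=(4, 3, 3)))
        with pytest.raises(ValueError, match="input"):
            forward(model, np.zeros(5))


class TestGradients:
    @settings(deadline=None, max_examples=10)
    @given(seed=st.integers(0, 10_000))
    def test_backprop_matches_central_finite_differences(self, seed):
        rng = np.random.default_rng(seed)
        cfg = MLPConfig(layer_sizes=(4, 3, 3), seed=seed, init_scale=0.5)
        model = init_mlp(cfg)
        x = rng.normal(size=4)
        y = np.zeros(3)
        y[rng.integers(3)] = 1.0
        gw, gb = gradients(model, x, y)

        def f():
            out, _ = forward(model, x)
            return 0.5 * float(np.sum((out - y) ** 2))

        eps = 1e-6
        worst = 0.0
        for params, grads in ((model.weights, gw), (model.biases, gb)):
            for arr, g in zip(params, grads):
                flat = arr.ravel()
                it = np.random.default_rng(seed + 1).choice(
                    flat.size, size=min(10, flat.size), replace=False)
                for j in it:
                    orig = flat[j]
                    flat[j] = orig + eps
                    fp = f()
                    flat[j] = orig - eps
                    fm = f()
                    flat[j] = orig
                    num = (fp - fm) / (2 * eps)
                    # floor the denominator: central differences carry
                    # ~1e-10 roundoff, so near-zero entries are compared
                    # absolutely rather than relatively
                    denom = max(abs(num), abs(g.ravel()[j]), 1e-3)
                    worst = max(worst, abs(num - g.ravel()[j]) / denom)
        assert worst < 1e-6


class TestTrain:
    def test_zero_learning_rate_leaves_model_unchanged(self):
        cfg = MLPConfig(layer_sizes=(3, 4, 3), learning_rate=0.0, epochs=5)
        model = init_mlp(cfg)
        before = [w.copy() for w in model.weights]
        X = np.random.default_rng(0).normal(size=(6, 3))
        Y = one_hot([CLASS_ORDER[i % 3] for i in range(6)])
        train(model, X, Y, cfg)
        for w, b in zip(model.weights, before):
            np.testing.assert_array_equal(w, b)

    def test_learns_linearly_separable_clouds(self):
        rng = np.random.default_rng(0)
        a = rng.normal(loc=(-2, -2), scale=0.3, size=(12, 2))
        b = rng.normal(loc=(2, 2), scale=0.3, size=(12, 2))
        X = np.vstack([a, b])
        Y = np.zeros((24, 2))
        Y[:12, 0] = 1.0
        Y[12:, 1] = 1.0
        cfg = MLPConfig(layer_sizes=(2, 5, 2), epochs=2000,
                        learning_rate=0.05, seed=3)
        model = init_mlp(cfg)
        initial = loss(model, X, Y)
        train(model, X, Y, cfg)
        assert loss(model, X, Y) <= initial
        preds = [int(np.argmax(forward(model, x)[0])) for x in X]
        assert preds == [0] * 12 + [1] * 12

    def test_invalid_targets_rejected(self):
        cfg = MLPConfig(layer_sizes=(3, 3, 3), epochs=1)
        model = init_mlp(cfg)
        X = np.zeros((2, 3))
        with pytest.raises(ValueError, match="one-hot"):
            train(model, X, np.array([[0.5, 0.5, 0.0], [1, 0, 0]]), cfg)
        with pytest.raises(ValueError):
            train(model, X, np.ones((2, 2)), cfg)


class TestPredictClass:
    def test_maximal_node_wins(self):
        assert predict_class(np.array([0.9, 0.1, 0.2])) is CLASS_ORDER[0]
        assert predict_class(np.array([0.1, 0.2, 0.9])) is CLASS_ORDER[2]

    def test_ties_break_to_lowest_node_index(self):
        assert predict_class(np.array([0.5, 0.5, 0.1])) is CLASS_ORDER[0]

    def test_agrees_with_exhaustive_comparison(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            v = rng.uniform(size=3)
            best = 0
            for j in (1, 2):
                if v[j] > v[best]:
                    best = j
            assert predict_class(v) is CLASS_ORDER[best]

    def test_non_finite_outputs_rejected(self):
        with pytest.raises(ValueError):
            predict_class(np.array([np.nan, 0.1, 0.2]))


@pytest.fixture(scope="module")
def tiny_loo(separable_set):
    from gypsospec.preprocess import PreprocessConfig
    X, ids = preprocess_set(separable_set,
                            PreprocessConfig(window_width=21))
    cfg = MLPConfig(layer_sizes=(X.shape[1], 8, 8, 3), epochs=2500,
                    learning_rate=0.05, init_scale=0.5, seed=1)
    return X, list(separable_set.groups), ids, cfg


class TestLeaveOneOut:
    def test_folds_never_contain_their_held_out_case(self):
        for train_idx, i in loo_folds(20):
            assert i not in train_idx
            assert len(train_idx) == 19

    def test_fold_seed_is_stable_and_identity_based(self):
        assert fold_seed(1, "gv01") == fold_seed(1, "gv01")
        assert fold_seed(1, "gv01") != fold_seed(2, "gv01")
        assert fold_seed(1, "gv01") != fold_seed(1, "gv02")
        assert 0 <= fold_seed(123, "x") < 2 ** 31

    def test_separable_classes_give_diagonal_confusion(self, tiny_loo):
        X, labels, ids, cfg = tiny_loo
        res = loo_evaluate(X, labels, cfg, sample_ids=ids)
        counts = res.confusion.counts
        assert np.all(counts == np.diag([4, 4, 4]))
        assert res.n_correct == 12
        for _, _, out, _ in res.cases:
            assert np.all((out >= 0) & (out <= 1))

    def test_row_order_does_not_change_the_confusion(self, tiny_loo):
        X, labels, ids, cfg = tiny_loo
        res1 = loo_evaluate(X, labels, cfg, sample_ids=ids)
        perm = np.random.default_rng(0).permutation(len(labels))
        res2 = loo_evaluate(X[perm], [labels[i] for i in perm], cfg,
                            sample_ids=[ids[i] for i in perm])
        np.testing.assert_array_equal(res1.confusion.counts,
                                      res2.confusion.counts)
        by_id1 = {c[0]: c[2] for c in res1.cases}
        by_id2 = {c[0]: c[2] for c in res2.cases}
        for sid in by_id1:
            np.testing.assert_allclose(by_id1[sid], by_id2[sid],
                                       atol=1e-10)

    def test_group_with_single_member_is_an_error(self):
        X = np.zeros((3, 4))
        labels = [Group.GYPSOVAG, Group.GYPSOVAG, Group.WIDE_GYPSOPHILE]
        with pytest.raises(ValueError, match="fewer than 2"):
            loo_evaluate(X, labels, MLPConfig(layer_sizes=(4, 3, 3),
                                              epochs=1))

    def test_perfect_outputs_give_zero_errors(self):
        from gypsospec.evaluation import node_errors
        targets = one_hot([CLASS_ORDER[i % 3] for i in range(9)])
        mae, rmse = node_errors(targets.copy(), targets)
        np.testing.assert_array_equal(mae, np.zeros(3))
        np.testing.assert_array_equal(rmse, np.zeros(3))
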