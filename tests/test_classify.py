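"""Stratified splitting, the NumPy CNN, baselines and prediction contracts."""

import numpy as np
import pytest

from stresskit import (
    FeatureMatrix,
    predict,
    stratified_split,
    train_cnn,
    train_lda,
    train_svm,
)
from stresskit.classify import TEST, TRAIN, VAL
from stresskit.errors import ContractError, ParameterError, StratificationError
from stresskit.nn import CNN1D, CNNConfig, cross_entropy, softmax


def make_problem(rng, n_per_class=60, n_classes=4, length=8, sep=2.0):
    """Gaussian classes with means on a line, standardized per feature
    (classifiers in the pipeline always receive z-scored features)."""
    X, y = [], []
    for c in range(n_classes):
        mean = np.linspace(0, sep * c, length)
        X.append(rng.normal(mean, 1.0, size=(n_per_class, length)))
        y.extend([c] * n_per_class)
    X = np.vstack(X)
    X = (X - X.mean(axis=0)) / np.maximum(X.std(axis=0), 1e-12)
    return X, np.array(y)


class TestStratifiedSplit:
    def test_exact_70_15_15_at_100_per_class(self):
        labels = np.arange(6).repeat(100)
        split = stratified_split(labels, seed=0)
        for c in range(6):
            mask = labels == c
            assert (split.assignment[mask] == TRAIN).sum() == 70
            assert (split.assignment[mask] == VAL).sum() == 15
            assert (split.assignment[mask] == TEST).sum() == 15

    def test_deterministic_for_seed(self):
        labels = np.arange(6).repeat(37)
        a = stratified_split(labels, seed=3)
        b = stratified_split(labels, seed=3)
        np.testing.assert_array_equal(a.assignment, b.assignment)

    def test_largest_remainder_within_one_sample(self):
        labels = np.arange(6).repeat(37)
        split = stratified_split(labels, seed=1)
        for c in range(6):
            mask = labels == c
            for which, frac in zip((TRAIN, VAL, TEST), (0.70, 0.15, 0.15)):
                got = (split.assignment[mask] == which).sum()
                assert abs(got - frac * 37) <= 1

    def test_small_class_rejected(self):
        with pytest.raises(StratificationError):
            stratified_split([0, 0, 0, 1, 1])

    def test_bad_fractions_rejected(self):
        with pytest.raises(ParameterError):
            stratified_split(np.arange(3).repeat(10), fractions=(0.5, 0.2, 0.2))


class TestLossAndSoftmax:
    def test_cross_entropy_matches_naive_loop(self, rng):
        raw = rng.random((40, 6))
        proba = raw / raw.sum(axis=1, keepdims=True)
        labels = rng.integers(0, 6, 40)
        total = 0.0
        for i in range(40):
            onehot = np.zeros(6)
            onehot[labels[i]] = 1.0
            total += -sum(onehot[c] * np.log(proba[i, c]) for c in range(6))
        assert cross_entropy(proba, labels) == pytest.approx(total / 40, abs=1e-9)

    def test_softmax_rows_sum_to_one_and_stable(self, rng):
        logits = rng.normal(size=(10, 6)) * 100  # large magnitudes
        p = softmax(logits)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-9)
        assert np.all(np.isfinite(p))


class TestCNN:
    def test_separable_problem_learned(self, rng, fast_cnn_config):
        X, y = make_problem(rng, n_per_class=50, sep=3.0)
        split = stratified_split(y, seed=0)
        cfg = CNNConfig(**{**fast_cnn_config.__dict__, "n_classes": 4})
        features = FeatureMatrix(values=X, mode="test")
        model = train_cnn(features, y, split, cfg)
        proba, pred = predict(model, features)
        acc = (pred[split.test] == y[split.test]).mean()
        assert acc >= 0.9

    def test_training_loss_decreases_on_learnable_problem(self, rng, fast_cnn_config):
        X, y = make_problem(rng, n_per_class=40, sep=2.0)
        split = stratified_split(y, seed=0)
        cfg = CNNConfig(**{**fast_cnn_config.__dict__, "n_classes": 4})
        model = train_cnn(FeatureMatrix(values=X, mode="t"), y, split, cfg)
        losses = model.history.train_loss
        assert losses[-1] < losses[0]
        assert min(losses[-5:]) <= min(losses[:5])

    def test_shuffled_labels_give_chance_accuracy(self, rng):
        accs = []
        for seed in range(3):
            local = np.random.default_rng(seed)
            X = local.normal(size=(600, 8))
            y = local.integers(0, 6, 600)  # labels carry no signal
            split = stratified_split(y, seed=seed)
            cfg = CNNConfig(f1=8, f2=16, epochs=10, n_classes=6, seed=seed)
            model = train_cnn(FeatureMatrix(values=X, mode="t"), y, split, cfg)
            _, pred = predict(model, FeatureMatrix(values=X, mode="t"))
            accs.append((pred[split.test] == y[split.test]).mean())
        assert np.mean(accs) == pytest.approx(1 / 6, abs=0.08)

    def test_fixed_seed_reproducible_training(self, rng, fast_cnn_config):
        X, y = make_problem(rng, n_per_class=20)
        split = stratified_split(y, seed=0)
        cfg = CNNConfig(**{**fast_cnn_config.__dict__, "n_classes": 4, "epochs": 5})
        a = train_cnn(FeatureMatrix(values=X, mode="t"), y, split, cfg)
        b = train_cnn(FeatureMatrix(values=X, mode="t"), y, split, cfg)
        for key in a.model.params:
            np.testing.assert_array_equal(a.model.params[key], b.model.params[key])

    def test_test_rows_do_not_influence_training(self, rng, fast_cnn_config):
        X, y = make_problem(rng, n_per_class=20)
        split = stratified_split(y, seed=0)
        cfg = CNNConfig(**{**fast_cnn_config.__dict__, "n_classes": 4, "epochs": 5})
        a = train_cnn(FeatureMatrix(values=X, mode="t"), y, split, cfg)
        X2 = X.copy()
        X2[split.test] = rng.normal(size=(split.test.size, X.shape[1]))
        b = train_cnn(FeatureMatrix(values=X2, mode="t"), y, split, cfg)
        for key in a.model.params:
            np.testing.assert_array_equal(a.model.params[key], b.model.params[key])

    def test_backward_pass_matches_finite_differences(self, rng):
        cfg = CNNConfig(f1=3, f2=4, epochs=1, dropout=0.0, n_classes=3, seed=0)
        net = CNN1D(input_length=7, config=cfg)
        X = rng.normal(size=(5, 7))
        y = rng.integers(0, 3, 5)
        proba, cache = net._forward(X, train=False)
        grads = net._backward(proba, y, cache)
        eps = 1e-6
        for key in ("w1", "b2", "wd"):
            flat = net.params[key].ravel()
            idx = rng.integers(0, flat.size, 4)
            for i in idx:
                orig = flat[i]
                flat[i] = orig + eps
                lp = cross_entropy(net._forward(X)[0], y)
                flat[i] = orig - eps
                lm = cross_entropy(net._forward(X)[0], y)
                flat[i] = orig
                numeric = (lp - lm) / (2 * eps)
                assert grads[key].ravel()[i] == pytest.approx(numeric, abs=1e-5)

    def test_sequence_shorter_than_kernel_rejected(self):
        with pytest.raises(ParameterError):
            CNN1D(input_length=2, config=CNNConfig(kernel_size=3))

    def test_divergence_guard_config(self):
        with pytest.raises(ParameterError):
            CNNConfig(learning_rate=0.0)


class TestBaselines:
    def test_lda_separates_two_gaussians(self, rng):
        X, y = make_problem(rng, n_per_class=100, n_classes=2, sep=6.0)
        split = stratified_split(y, seed=0)
        model = train_lda(FeatureMatrix(values=X, mode="t"), y, split, n_classes=2)
        _, pred = predict(model, FeatureMatrix(values=X, mode="t"))
        assert (pred[split.test] == y[split.test]).mean() >= 0.95

    def test_lda_1d_boundary_at_midpoint(self, rng):
        # equal-covariance 1-D classes: decision crosses at the mean midpoint
        n = 4000
        X = np.concatenate([rng.normal(0, 1, n), rng.normal(4, 1, n)])[:, None]
        y = np.array([0] * n + [1] * n)
        split = stratified_split(y, seed=0)
        model = train_lda(FeatureMatrix(values=X, mode="t"), y, split, n_classes=2)
        grid = np.linspace(0, 4, 2001)[:, None]
        proba, _ = predict(model, FeatureMatrix(values=grid, mode="t"))
        crossing = grid[np.argmin(np.abs(proba[:, 1] - 0.5)), 0]
        assert crossing == pytest.approx(2.0, abs=0.15)

    def test_svm_probabilities_valid(self, rng):
        X, y = make_problem(rng, n_per_class=30, n_classes=3, sep=4.0)
        split = stratified_split(y, seed=0)
        model = train_svm(FeatureMatrix(values=X, mode="t"), y, split, n_classes=3)
        proba, _ = predict(model, FeatureMatrix(values=X, mode="t"))
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-6)


class TestPredictContract:
    def test_probability_rows_sum_to_one(self, rng, fast_cnn_config):
        X, y = make_problem(rng, n_per_class=20)
        split = stratified_split(y, seed=0)
        cfg = CNNConfig(**{**fast_cnn_config.__dict__, "n_classes": 4, "epochs": 3})
        model = train_cnn(FeatureMatrix(values=X, mode="t"), y, split, cfg)
        proba, _ = predict(model, FeatureMatrix(values=X, mode="t"))
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-6)

    def test_repeated_inference_identical(self, rng, fast_cnn_config):
        X, y = make_problem(rng, n_per_class=20)
        split = stratified_split(y, seed=0)
        cfg = CNNConfig(**{**fast_cnn_config.__dict__, "n_classes": 4, "epochs": 3})
        model = train_cnn(FeatureMatrix(values=X, mode="t"), y, split, cfg)
        a, _ = predict(model, FeatureMatrix(values=X, mode="t"))
        b, _ = predict(model, FeatureMatrix(values=X, mode="t"))
        np.testing.assert_array_equal(a, b)

    def test_batch_order_invariance(self, rng, fast_cnn_config):
        X, y = make_problem(rng, n_per_class=20)
        split = stratified_split(y, seed=0)
        cfg = CNNConfig(**{**fast_cnn_config.__dict__, "n_classes": 4, "epochs": 3})
        model = train_cnn(FeatureMatrix(values=X, mode="t"), y, split, cfg)
        perm = rng.permutation(X.shape[0])
        _, pred = predict(model, FeatureMatrix(values=X, mode="t"))
        _, pred_perm = predict(model, FeatureMatrix(values=X[perm], mode="t"))
        np.testing.assert_array_equal(pred[perm], pred_perm)

    def test_feature_mode_mismatch_rejected(self, rng, fast_cnn_config):
        X, y = make_problem(rng, n_per_class=20)
        split = stratified_split(y, seed=0)
        cfg = CNNConfig(**{**fast_cnn_config.__dict__, "n_classes": 4, "epochs": 2})
        model = train_cnn(FeatureMatrix(values=X, mode="rfe+indices"), y, split, cfg)
        with pytest.raises(ContractError):
            predict(model, FeatureMatrix(values=X, mode="pca"))
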