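"""CNN and SVM models: architecture, loss, training, prediction, tuning."""

import dataclasses

import numpy as np
import pytest

from prefog import nn
from prefog.model import (
    DEFAULT_SPACE,
    CNNResults,
    GaitCycleCNN,
    Hyperparameters,
    LinearSVMBaseline,
    LossConfig,
    TrainingDivergedError,
    build_cnn,
    class_weights,
    parameter_count,
    predict,
    sample_hyperparameters,
    train_cnn,
    tune_hyperparameters,
    weighted_cross_entropy,
)


class TestClassWeights:
    def test_balanced_gives_unit_weights(self):
        assert np.allclose(class_weights([0, 1, 0, 1]).alpha, [1.0, 1.0])

    def test_inverse_frequency(self):
        lc = class_weights([1] * 30 + [0] * 90)
        assert lc.alpha[1] == pytest.approx(2.0)
        assert lc.alpha[0] == pytest.approx(2.0 / 3.0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            class_weights([1, 1, 1])


class TestWeightedCrossEntropy:
    lc = LossConfig(np.array([1.0, 1.0]))

    @pytest.mark.parametrize(
        "Y,Yhat,alpha,expect",
        [
            ([0, 1], [0.5, 0.5], (1.0, 1.0), 0.6931471805599453),
            ([0, 1], [0.0, 1.0], (1.0, 1.0), 0.0),
            ([0, 1], [0.5, 0.5], (1.0, 2.0), 1.3862943611198906),
        ],
    )
    def test_known_values(self, Y, Yhat, alpha, expect):
        lc = LossConfig(np.array(alpha))
        assert weighted_cross_entropy(Y, Yhat, lc) == pytest.approx(expect, abs=1e-12)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            weighted_cross_entropy([[0, 1]], [[0.1, 0.2, 0.7]], self.lc)

    def test_probability_floor_keeps_loss_finite(self):
        assert np.isfinite(weighted_cross_entropy([0, 1], [1.0, 0.0], self.lc))


class TestBuildCNN:
    def test_closed_form_parameter_count(self):
        h = Hyperparameters(n_blocks=1, filters=8, kernel=9)
        net = build_cnn(h)
        assert net.n_parameters() == parameter_count(h) == 242

    @pytest.mark.parametrize("seed", range(10))
    def test_parameter_count_matches_enumeration(self, seed):
        rng = np.random.Generator(np.random.PCG64(seed))
        h = sample_hyperparameters(DEFAULT_SPACE, rng)
        net = build_cnn(h)
        total = sum(layer.W.size + layer.b.size for layer in net.parametric_layers())
        assert total == parameter_count(h) == net.n_parameters()

    def test_same_seed_same_initial_weights(self):
        h = Hyperparameters(seed=4)
        a, b = build_cnn(h), build_cnn(h)
        for la, lb in zip(a.parametric_layers(), b.parametric_layers()):
            assert np.array_equal(la.W, lb.W) and np.array_equal(la.b, lb.b)

    def test_forward_is_probability_vector(self):
        net = build_cnn(Hyperparameters())
        x = np.random.default_rng(0).uniform(-1, 1, (7, 101, 3))
        p = net.forward(x)
        assert p.shape == (7, 2)
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-6)
        assert np.all(p >= 0)

    def test_oversized_kernel_rejected(self):
        with pytest.raises(ValueError):
            build_cnn(Hyperparameters(n_blocks=3, kernel=25, pool_width=4))

    def test_invalid_hyperparameters_rejected(self):
        with pytest.raises(ValueError):
            Hyperparameters(dropout=1.0).validate()
        with pytest.raises(ValueError):
            Hyperparameters(kernel=8).validate()
        with pytest.raises(ValueError):
            Hyperparameters(max_norm=0.0).validate()


class TestTraining:
    def _toy_data(self, n=24):
        rng = np.random.default_rng(0)
        X = rng.uniform(-1, 1, (n, 101, 3))
        y = np.tile([0, 1], n // 2)
        X[y == 1, 40:60, :] += 1.5  # separable bump
        return X, y

    def test_zero_learning_rate_freezes_weights(self):
        X, y = self._toy_data()
        h = Hyperparameters(lr0=0.0, epochs=3, dropout=0.0)
        net = build_cnn(h)
        before = [l.W.copy() for l in net.parametric_layers()]
        train_cnn(net, X, y, class_weights(y), h)
        for W, l in zip(before, net.parametric_layers()):
            assert np.array_equal(W, l.W)

    def test_loss_decreases_on_separable_data(self):
        X, y = self._toy_data()
        h = Hyperparameters(epochs=20, schedule_midpoint=10, seed=1)
        net = build_cnn(h)
        hist = train_cnn(net, X, y, class_weights(y), h)
        assert hist["loss"].iloc[-1] < hist["loss"].iloc[0]

    def test_max_norm_cap_enforced(self):
        X, y = self._toy_data()
        h = Hyperparameters(max_norm=0.1, epochs=5)
        net = build_cnn(h)
        train_cnn(net, X, y, class_weights(y), h)
        assert np.all(net.weight_norms() <= 0.1 + 1e-9)

    def test_sigmoidal_learning_rate_schedule(self):
        from prefog.model import learning_rate_schedule

        h = Hyperparameters(lr0=1e-2, schedule_steepness=0.5, schedule_midpoint=10)
        lrs = [learning_rate_schedule(h, t) for t in range(21)]
        assert lrs[10] == pytest.approx(5e-3)
        assert np.all(np.diff(lrs) < 0)  # monotone decay
        assert lrs[0] < 1e-2 and lrs[0] > lrs[-1]

    def test_divergence_aborts_with_diagnostics(self):
        X, y = self._toy_data()
        X[0, 0, 0] = np.nan  # propagates to a non-finite loss
        h = Hyperparameters(epochs=5, batch_size=len(y))
        net = build_cnn(h)
        with pytest.raises(TrainingDivergedError, match="epoch"):
            train_cnn(net, X, y, class_weights(y), h)

    def test_single_class_rejected(self):
        X, _ = self._toy_data()
        with pytest.raises(ValueError):
            train_cnn(build_cnn(Hyperparameters()), X, np.zeros(len(X), int),
                      LossConfig(np.array([1.0, 1.0])), Hyperparameters())


class TestPredict:
    def test_inference_deterministic_and_normalized(self, trained_small, small_arrays):
        X, _, _ = small_arrays
        p1, l1 = trained_small.predict(X)
        p2, l2 = trained_small.predict(X)
        assert np.array_equal(p1, p2) and np.array_equal(l1, l2)
        assert np.allclose(p1.sum(axis=1), 1.0, atol=1e-6)

    def test_tie_breaks_to_functional_class(self):
        net = build_cnn(Hyperparameters())
        for layer in net.parametric_layers():
            layer.W[:] = 0.0
            layer.b[:] = 0.0
        _, labels = predict(net, np.random.default_rng(0).uniform(-1, 1, (5, 101, 3)))
        assert np.all(labels == 0)  # exact 0.5/0.5 goes to FGC

    def test_wrong_shape_rejected(self, trained_small):
        with pytest.raises(ValueError):
            trained_small.predict(np.zeros((3, 50, 3)))


class TestModelResultsSurface:
    def test_fit_returns_results_with_summary(self, trained_small):
        assert isinstance(trained_small, CNNResults)
        text = trained_small.summary()
        assert "trainable parameters" in text
        assert "training accuracy" in text
        assert len(trained_small.history) == trained_small.hyperparameters.epochs

    def test_training_separates_synthetic_classes(self, trained_small):
        # strongly separable cohort (delta=0.6, 1 deg noise): training fit is high
        assert trained_small.training_accuracy() > 0.9

    def test_checkpoint_roundtrip_preserves_predictions(self, tmp_path,
                                                        trained_small, small_arrays):
        X, _, _ = small_arrays
        path = tmp_path / "model.json"
        trained_small.network.save(path)
        net = nn.Network.load(path)
        p1, _ = trained_small.predict(X[:5])
        p2, _ = predict(net, X[:5])
        assert np.allclose(p1, p2, atol=1e-12)


class TestLinearSVM:
    def test_separates_well_separated_points(self):
        X = np.zeros((4, 101, 3))
        X[2:] += 1.0
        y = np.array([0, 0, 1, 1])
        res = LinearSVMBaseline(X, y).fit()
        assert np.array_equal(res.predict(X), y)

    def test_default_regularization(self):
        model = LinearSVMBaseline(np.zeros((2, 101, 3)), np.array([0, 1]))
        assert model.C == 0.01

    def test_deterministic_coefficients(self, small_arrays):
        X, y, _ = small_arrays
        a = LinearSVMBaseline(X, y, seed=0).fit()
        b = LinearSVMBaseline(X, y, seed=0).fit()
        assert np.array_equal(a.classifier.coef_, b.classifier.coef_)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            LinearSVMBaseline(np.zeros((3, 101, 3)), np.zeros(3, int)).fit()


class TestTuneHyperparameters:
    SPACE = {"filters": ("choice", [4, 6]), "lr0": ("loguniform", 1e-3, 1e-2)}

    def _tiny(self):
        rng = np.random.default_rng(3)
        X = rng.uniform(-1, 1, (24, 101, 3))
        y = np.tile([0, 1], 12)
        X[y == 1, 60:90, 1:] += 1.0
        subjects = np.repeat(["a", "b", "c"], 8)
        return X, y, subjects

    def test_budget_one_returns_single_sample(self):
        X, y, s = self._tiny()
        base = dataclasses.replace(Hyperparameters(), epochs=4)
        h = tune_hyperparameters(X, y, s, self.SPACE, budget=1, seed=0, base=base)
        rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence([0, 61])))
        expect = sample_hyperparameters(self.SPACE, rng, base)
        assert h == expect

    def test_selection_is_inner_argmax_and_deterministic(self):
        from prefog.model import inner_loso_accuracy, random_search

        X, y, s = self._tiny()
        base = dataclasses.replace(Hyperparameters(), epochs=4)
        h1 = tune_hyperparameters(X, y, s, self.SPACE, budget=3, seed=5, base=base)
        h2 = tune_hyperparameters(X, y, s, self.SPACE, budget=3, seed=5, base=base)
        assert h1 == h2
        rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence([5, 61])))
        candidates = random_search(self.SPACE, 3, rng, base)
        accs = [inner_loso_accuracy(h, X, y, s) for h in candidates]
        assert inner_loso_accuracy(h1, X, y, s) == max(accs)

    def test_invalid_budget_or_space_rejected(self):
        X, y, s = self._tiny()
        with pytest.raises(ValueError):
            tune_hyperparameters(X, y, s, self.SPACE, budget=0)
        with pytest.raises(ValueError):
            tune_hyperparameters(X, y, s, {}, budget=1)

    def test_pluggable_strategy(self):
        X, y, s = self._tiny()
        fixed = dataclasses.replace(Hyperparameters(), epochs=3, filters=4)

        def strategy(space, budget, rng, base):
            return [fixed]

        assert tune_hyperparameters(X, y, s, self.SPACE, budget=1,
                                    strategy=strategy) == fixed
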