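"""Training machinery: weights, loss, schedule, folds, SGD, search."""

import numpy as np
import pytest

from dualecg.network import ModelConfig, build_owcnn
from dualecg.trainer import (
    Dataset,
    SearchSpace,
    TrainConfig,
    class_weights,
    hyperparameter_search,
    lr_at_epoch,
    stratified_folds,
    train,
    weighted_cross_entropy,
)


class TestClassWeights:
    def test_published_training_distribution(self):
        w = class_weights([61911, 5346, 2214, 405])
        np.testing.assert_allclose(w, [0.28, 3.26, 7.89, 43.13], atol=0.01)

    def test_balanced_counts_give_unit_weights(self):
        np.testing.assert_allclose(class_weights([10, 10, 10, 10]), np.ones(4))

    def test_formula(self):
        np.testing.assert_allclose(class_weights([30, 10, 10, 10]),
                                   [0.5, 1.5, 1.5, 1.5])

    def test_mass_conservation(self, rng):
        counts = rng.integers(1, 1000, size=4)
        w = class_weights(counts)
        assert np.dot(w, counts) == pytest.approx(counts.sum())

    def test_zero_count_rejected(self):
        with pytest.raises(ValueError):
            class_weights([10, 0, 10, 10])


class TestWeightedCrossEntropy:
    def test_single_example(self):
        y = np.array([[0, 0, 1, 0]])
        y_hat = np.array([[0.1, 0.1, 0.7, 0.1]])
        assert weighted_cross_entropy(y, y_hat) == pytest.approx(0.35667, abs=1e-5)

    def test_perfect_prediction_zero_loss(self):
        y = np.eye(4)
        assert weighted_cross_entropy(y, y * (1 - 4e-7) + 1e-7) < 1e-5

    def test_class_weight_scales_loss(self):
        y = np.array([[0, 0, 1, 0]])
        y_hat = np.array([[0.1, 0.1, 0.7, 0.1]])
        w = np.array([1.0, 1.0, 7.89, 1.0])
        assert weighted_cross_entropy(y, y_hat, w) == pytest.approx(
            7.89 * -np.log(0.7), abs=1e-4)

    def test_unit_weights_equal_brute_force_mean(self, rng):
        # brute-force the definition over a 5-example batch
        y = np.zeros((5, 4))
        cls = rng.integers(0, 4, 5)
        y[np.arange(5), cls] = 1
        p = rng.dirichlet(np.ones(4), size=5)
        brute = -np.mean([np.log(p[i, cls[i]]) for i in range(5)])
        assert weighted_cross_entropy(y, p) == pytest.approx(brute)

    def test_zero_probability_clamped(self):
        y = np.array([[1, 0, 0, 0]])
        y_hat = np.array([[0.0, 0.5, 0.25, 0.25]])
        loss = weighted_cross_entropy(y, y_hat)
        assert np.isfinite(loss)
        assert loss == pytest.approx(-np.log(1e-7))


class TestLrSchedule:
    @pytest.mark.parametrize("epoch,expected", [
        (0, 0.01), (29, 0.01), (30, 0.001), (59, 0.001), (60, 1e-4), (95, 1e-5)])
    def test_step_decay(self, epoch, expected):
        assert lr_at_epoch(epoch, TrainConfig()) == pytest.approx(expected)

    def test_negative_epoch_rejected(self):
        with pytest.raises(ValueError):
            lr_at_epoch(-1, TrainConfig())


class TestStratifiedFolds:
    def test_exact_divisibility(self):
        labels = np.repeat([0, 1, 2, 3], [70, 10, 10, 10])
        folds = stratified_folds(labels, k=10, seed=0)
        for f in folds:
            counts = np.bincount(labels[f], minlength=4)
            np.testing.assert_array_equal(counts, [7, 1, 1, 1])

    def test_disjoint_and_exhaustive(self, rng):
        labels = rng.integers(0, 4, size=237)
        # ensure every class has >= 10 members
        labels[:40] = np.repeat(np.arange(4), 10)
        folds = stratified_folds(labels, k=10, seed=3)
        allidx = np.concatenate(folds)
        assert len(allidx) == len(set(allidx)) == 237
        for f in folds:
            counts = np.bincount(labels[f], minlength=4)
            full = np.bincount(labels, minlength=4)
            for c in range(4):
                assert abs(counts[c] - full[c] / 10) <= 1

    def test_determinism(self):
        labels = np.repeat([0, 1, 2, 3], 25)
        a = stratified_folds(labels, k=10, seed=5)
        b = stratified_folds(labels, k=10, seed=5)
        for fa, fb in zip(a, b):
            np.testing.assert_array_equal(fa, fb)

    def test_rare_class_rejected(self):
        with pytest.raises(ValueError):
            stratified_folds(np.array([0] * 50 + [1] * 3), k=10)


def _toy_dataset(n=400, seed=0):
    """Linearly separable 4-class toy problem in the model's input shapes."""
    rng = np.random.default_rng(seed)
    y = rng.integers(0, 4, size=n)
    x1 = rng.normal(0, 0.3, size=(n, 1201))
    x2 = rng.normal(0, 0.3, size=(n, 292))
    # class-dependent mean shifts in distinct regions
    for c in range(4):
        x1[y == c, c * 300 : c * 300 + 200] += 2.0
        x2[y == c, c * 70 : c * 70 + 50] += 2.0
    return Dataset.from_indices(x1, x2, y, np.array(["r0"] * n))


SMALL_MODEL = ModelConfig(initial_filters=4, dense_sizes=(32, 16, 8))


class TestTrain:
    def test_learns_separable_toy_problem(self):
        data = _toy_dataset(400)
        val = _toy_dataset(120, seed=1)
        model = build_owcnn(SMALL_MODEL, seed=0)
        cfg = TrainConfig(max_epochs=50, patience=20, seed=0)
        hist = train(model, data, val, cfg)
        assert hist.best_val_accuracy >= 0.95
        assert len(hist.epochs) <= 50

    def test_lr_history_follows_schedule(self):
        data = _toy_dataset(64)
        model = build_owcnn(SMALL_MODEL, seed=0)
        cfg = TrainConfig(max_epochs=4, patience=3, seed=0, decay_every=2)
        hist = train(model, data, data, cfg)
        assert hist.lr == [lr_at_epoch(e, cfg) for e in hist.epochs]

    def test_early_stopping_on_plateau(self):
        # constant inputs cannot be fit: validation accuracy plateaus
        n = 32
        x1, x2 = np.zeros((n, 1201)), np.zeros((n, 292))
        y = np.tile(np.arange(4), 8)
        data = Dataset.from_indices(x1, x2, y, np.array(["r"] * n))
        model = build_owcnn(SMALL_MODEL, seed=0)
        cfg = TrainConfig(max_epochs=50, patience=3, seed=0)
        hist = train(model, data, data, cfg)
        assert hist.stopped_early
        assert len(hist.epochs) < 50

    def test_best_weights_restored(self):
        data = _toy_dataset(200)
        val = _toy_dataset(80, seed=2)
        model = build_owcnn(SMALL_MODEL, seed=1)
        cfg = TrainConfig(max_epochs=12, patience=11, seed=0)
        hist = train(model, data, val, cfg)
        pred = model.predict(val.inputs1, val.inputs2)
        final_acc = float((pred == val.y).mean())
        assert final_acc == pytest.approx(hist.best_val_accuracy, abs=1e-9)


class TestHyperparameterSearch:
    def test_budget_one_returns_single_config(self):
        space = SearchSpace({"p": [0.1, 0.2]})
        best, trials = hyperparameter_search(space, lambda c: 1.0, budget=1)
        assert len(trials) == 1
        assert best == trials[0][0]

    @pytest.mark.parametrize("strategy", ["random", "model_based"])
    def test_finds_quadratic_optimum(self, strategy):
        space = SearchSpace({"dropout": (0.0, 1.0)})
        best, trials = hyperparameter_search(
            space, lambda c: -(c["dropout"] - 0.3) ** 2, budget=50,
            strategy=strategy, seed=0)
        assert len(trials) == 50
        assert abs(best["dropout"] - 0.3) < 0.05

    def test_random_strategy_deterministic(self):
        space = SearchSpace({"x": (0.0, 1.0), "c": [1, 2, 3]})
        obj = lambda c: c["x"]
        _, t1 = hyperparameter_search(space, obj, budget=10, seed=4)
        _, t2 = hyperparameter_search(space, obj, budget=10, seed=4)
        assert [c for c, _ in t1] == [c for c, _ in t2]

    def test_failing_objective_logged_not_fatal(self):
        space = SearchSpace({"x": (0.0, 1.0)})

        def objective(c):
            if c["x"] < 0.5:
                raise RuntimeError("boom")
            return c["x"]

        best, trials = hyperparameter_search(space, objective, budget=20, seed=0)
        assert any(s == -np.inf for _, s in trials)
        assert best["x"] >= 0.5
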