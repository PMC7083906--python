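from types import SimpleNamespace

import numpy as np
import pytest

from smlmclust import (
    FeatureMatrix,
    LabeledPool,
    TrainConfig,
    classify,
    cross_validate,
    evaluate,
    model_preset,
    train,
)
from smlmclust.models import PRESET_NAMES, TrainedModel


def separable_pool(n=1200, k=100, seed=0):
    """Clustered rows are the same sequences shrunk 10x: trivially separable."""
    rng = np.random.default_rng(seed)
    base = np.sort(rng.uniform(0.2, 1.0, size=(n // 2, k)), axis=1)
    X = np.vstack([base, 0.1 * base])
    y = np.r_[np.zeros(n // 2, int), np.ones(n - n // 2, int)]
    idx = rng.permutation(n)
    return X[idx], y[idx]


class TestPresets:
    @pytest.mark.parametrize(
        "name,input_k,n_classes,n_layers",
        [
            ("XPILJZ", 100, 2, 4),
            ("07VEJJ", 100, 2, 12),
            ("87B144", 1000, 2, 12),
            ("GAXJPR", 1000, 2, 4),
            ("3TXKFS", 1000, 3, 3),
        ],
    )
    def test_preset_topologies(self, name, input_k, n_classes, n_layers):
        spec = model_preset(name)
        assert spec.input_k == input_k
        assert spec.n_classes == n_classes
        assert spec.n_layers == n_layers

    def test_unknown_preset_lists_valid_names(self):
        with pytest.raises(ValueError) as err:
            model_preset("NOPE")
        for name in PRESET_NAMES:
            assert name in str(err.value)


class TestTrain:
    def test_separable_pool_high_validation_accuracy(self):
        X, y = separable_pool()
        tr = LabeledPool(X[:800], y[:800])
        va = LabeledPool(X[800:], y[800:], "validation")
        model = train(model_preset("XPILJZ"), tr, va, TrainConfig(epochs=10, batch_size=32, seed=1))
        assert max(model.history["val_accuracy"]) >= 0.99

    def test_same_seed_identical_history(self):
        X, y = separable_pool(n=400)
        tr = LabeledPool(X[:300], y[:300])
        va = LabeledPool(X[300:], y[300:], "validation")
        cfg = TrainConfig(epochs=3, seed=5)
        a = train(model_preset("XPILJZ"), tr, va, cfg)
        b = train(model_preset("XPILJZ"), tr, va, cfg)
        assert a.history["val_accuracy"] == b.history["val_accuracy"]

    def test_width_mismatch_errors_before_training(self):
        X, y = separable_pool(n=100, k=50)
        pool = LabeledPool(X, y)
        with pytest.raises(ValueError, match="width"):
            train(model_preset("XPILJZ"), pool, pool)

    def test_label_arity_mismatch_errors(self):
        X, _ = separable_pool(n=100)
        pool = LabeledPool(X, np.full(100, 2))
        with pytest.raises(ValueError, match="labels"):
            train(model_preset("XPILJZ"), pool, pool)

    def test_save_load_roundtrip(self, tmp_path):
        X, y = separable_pool(n=300)
        tr = LabeledPool(X[:200], y[:200])
        va = LabeledPool(X[200:], y[200:], "validation")
        model = train(model_preset("XPILJZ"), tr, va, TrainConfig(epochs=2, seed=0))
        model.save(tmp_path / "m")
        loaded = TrainedModel.load(tmp_path / "m")
        np.testing.assert_allclose(
            model.predict_scores(X[:10]), loaded.predict_scores(X[:10]), rtol=1e-12
        )


def _mock_binary_model(scores: np.ndarray):
    spec = SimpleNamespace(input_k=scores.shape[0] and 2, n_classes=2)
    return SimpleNamespace(spec=spec, predict_scores=lambda X: scores[: len(X)])


class TestEvaluate:
    def test_perfect_predictions(self):
        y = np.array([0, 1, 0, 1])
        scores = np.eye(2)[y]
        pool = LabeledPool(np.zeros((4, 2)), y)
        m = evaluate(_mock_binary_model(scores), pool)
        assert m.accuracy == 1.0 and m.f1 == 1.0
        assert m.confusion[0, 1] == 0 and m.confusion[1, 0] == 0

    def test_hand_computed_confusion(self):
        # 40 TN, 10 FP, 5 FN, 45 TP
        y = np.r_[np.zeros(50, int), np.ones(50, int)]
        pred = np.r_[np.zeros(40, int), np.ones(10, int), np.zeros(5, int), np.ones(45, int)]
        scores = np.eye(2)[pred]
        pool = LabeledPool(np.zeros((100, 2)), y)
        m = evaluate(_mock_binary_model(scores), pool)
        assert m.accuracy == pytest.approx(0.85)
        np.testing.assert_array_equal(m.confusion, [[40, 10], [5, 45]])
        # clustered-class values from the confusion matrix
        prec1 = 45 / 55
        rec1 = 0.90
        f1_1 = 2 * prec1 * rec1 / (prec1 + rec1)
        assert prec1 == pytest.approx(0.8182, abs=1e-4)
        assert f1_1 == pytest.approx(0.8571, abs=1e-4)
        # reported macro values average both classes
        prec0, rec0 = 40 / 45, 40 / 50
        assert m.precision == pytest.approx((prec0 + prec1) / 2)
        assert m.recall == pytest.approx((rec0 + rec1) / 2)

    def test_label_permutation_complement(self):
        rng = np.random.default_rng(9)
        y = rng.integers(0, 2, 200)
        pred = rng.integers(0, 2, 200)
        scores = np.eye(2)[pred]
        pool = LabeledPool(np.zeros((200, 2)), y)
        flipped = LabeledPool(np.zeros((200, 2)), 1 - y)
        acc = evaluate(_mock_binary_model(scores), pool).accuracy
        acc_flipped = evaluate(_mock_binary_model(scores), flipped).accuracy
        assert acc + acc_flipped == pytest.approx(1.0)

    def test_empty_pool_errors(self):
        with pytest.raises(ValueError, match="empty"):
            evaluate(
                _mock_binary_model(np.zeros((0, 2))),
                LabeledPool(np.zeros((0, 2)), np.zeros(0, int)),
            )


class TestCrossValidate:
    def test_separable_pool_stable_folds(self):
        X, y = separable_pool(n=600)
        pool = LabeledPool(X, y)
        mean, sd = cross_validate(
            model_preset("XPILJZ"), pool, n_folds=10, seed=0,
            config=TrainConfig(epochs=6, batch_size=32, seed=0),
        )
        assert mean >= 0.99
        assert sd <= 0.01

    def test_too_small_pool_errors(self):
        pool = LabeledPool(np.zeros((3, 100)), np.array([0, 1, 0]))
        with pytest.raises(ValueError):
            cross_validate(model_preset("XPILJZ"), pool, n_folds=5, seed=0)

    def test_two_folds_of_four_rows(self):
        from sklearn.model_selection import StratifiedKFold

        skf = StratifiedKFold(n_splits=2, shuffle=True, random_state=0)
        X = np.zeros((4, 1))
        y = np.array([0, 1, 0, 1])
        folds = [te for _, te in skf.split(X, y)]
        assert sorted(len(f) for f in folds) == [2, 2]
        assert sorted(np.concatenate(folds).tolist()) == [0, 1, 2, 3]


class TestClassify:
    def _model(self, scores):
        return _mock_binary_model(np.asarray(scores, float))

    def test_hard_labels_and_tie_rule(self):
        scores = np.array([[0.5, 0.5], [0.1, 0.9], [0.9, 0.1]])
        fm = FeatureMatrix(np.ones((3, 2)))
        out = classify(self._model(scores), fm, threshold=0.5)
        # a score exactly at threshold counts as clustered
        np.testing.assert_array_equal(out.label, [1, 1, 0])

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(11)
        p1 = rng.uniform(size=50)
        scores = np.column_stack([1 - p1, p1])
        fm = FeatureMatrix(np.ones((50, 2)))
        counts = [
            classify(self._model(scores), fm, threshold=t).label.sum()
            for t in (0.9, 0.5, 0.2, 0.05)
        ]
        assert counts == sorted(counts)

    def test_threshold_bounds(self):
        fm = FeatureMatrix(np.ones((1, 2)))
        with pytest.raises(ValueError):
            classify(self._model(np.array([[0.5, 0.5]])), fm, threshold=0.0)
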