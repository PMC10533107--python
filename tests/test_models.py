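"""Forest baselines, LSTM architectures, sample weighting, trivial predictor."""

import numpy as np
import pytest

from painmon.models import (
    ARCHITECTURES,
    LSTMClassifier,
    LSTMRegressor,
    RandomForestWindowClassifier,
    RandomForestWindowRegressor,
    apply_sample_weighting,
    sample_weight_indices,
    trivial_classifier_scores,
    trivial_regression,
)
from painmon.models.lstm import _LSTMNet, _softmax


def toy_classes(n=300, d=6, k=3, seed=0):
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((n, 10, d)) * 0.3
    y = rng.integers(0, k, n)
    for i in range(n):
        x[i, :, y[i]] += 2.0
    return x, y


class TestRandomForest:
    def test_config_echo_100_trees_depth_10(self):
        x, y = toy_classes(60)
        clf = RandomForestWindowClassifier(random_state=0).fit(x, y)
        assert clf.forest_.n_estimators == 100
        assert clf.forest_.max_depth == 10

    def test_constant_target_regression(self):
        x = np.random.default_rng(0).standard_normal((30, 10, 4))
        reg = RandomForestWindowRegressor(random_state=0).fit(x, np.full(30, 0.4))
        assert np.allclose(reg.predict(x), 0.4)

    def test_separable_classes_fit(self):
        x, y = toy_classes()
        clf = RandomForestWindowClassifier(random_state=0).fit(x, y)
        assert (clf.predict(x) == y).mean() >= 0.99

    def test_single_class_rejected(self):
        x = np.zeros((10, 10, 3))
        with pytest.raises(ValueError):
            RandomForestWindowClassifier().fit(x, np.zeros(10, dtype=int))

    def test_deterministic_given_seed(self):
        x, y = toy_classes(100)
        p1 = RandomForestWindowClassifier(random_state=5).fit(x, y).predict_proba(x)
        p2 = RandomForestWindowClassifier(random_state=5).fit(x, y).predict_proba(x)
        assert np.array_equal(p1, p2)


class TestLSTMArchitectures:
    @pytest.mark.parametrize("arch,units,dense,k", [
        ("A(c)", 4, 128, 7), ("B(c)", 8, 64, 7),
        ("C(c)", 4, 128, 4), ("D(c)", 8, 64, 4),
    ])
    def test_classification_shapes(self, arch, units, dense, k):
        est = LSTMClassifier.from_architecture(arch, epochs=1)
        assert (est.units, est.dense_units, est.n_classes) == (units, dense, k)

    @pytest.mark.parametrize("arch,units,dense", [
        ("A(r)", 4, 128), ("B(r)", 8, 64), ("C(r)", 4, 128), ("D(r)", 8, 64),
    ])
    def test_regression_shapes(self, arch, units, dense):
        est = LSTMRegressor.from_architecture(arch, epochs=1)
        assert (est.units, est.dense_units) == (units, dense)

    def test_task_mismatch_rejected(self):
        with pytest.raises(ValueError):
            LSTMRegressor.from_architecture("A(c)")

    def test_architecture_table_outputs(self):
        assert ARCHITECTURES["A(c)"][2] == 7
        assert ARCHITECTURES["C(c)"][2] == 4
        assert ARCHITECTURES["A(r)"][2] == 1


class TestLSTMTraining:
    def test_backprop_matches_numerical_gradient(self):
        rng = np.random.default_rng(0)
        net = _LSTMNet(n_features=3, units=4, dense_units=5, n_outputs=3,
                       window=6, rng=rng)
        x = rng.standard_normal((5, 6, 3))
        y = rng.integers(0, 3, 5)

        def loss():
            p = _softmax(net.forward(x))
            return -np.log(p[np.arange(5), y]).mean()

        logits, cache = net.forward(x, cache=True)
        p = _softmax(logits)
        d = p.copy()
        d[np.arange(5), y] -= 1
        grads = net.backward(d / 5, cache)
        eps = 1e-6
        for key, v in net.params.items():
            for idx in [tuple(rng.integers(0, s) for s in v.shape) for _ in range(5)]:
                orig = v[idx]
                v[idx] = orig + eps
                lp = loss()
                v[idx] = orig - eps
                lm = loss()
                v[idx] = orig
                num = (lp - lm) / (2 * eps)
                ana = grads[key][idx]
                assert abs(num - ana) <= 1e-5 * max(1.0, abs(num)), key

    def test_classifier_scores_normalized_and_fits(self):
        x, y = toy_classes(n=400, k=3, seed=1)
        clf = LSTMClassifier(n_classes=3, units=4, dense_units=32, lr=3e-3,
                             epochs=40, batch_size=128, random_state=0).fit(x, y)
        proba = clf.predict_proba(x)
        assert np.allclose(proba.sum(axis=1), 1.0)
        assert proba.min() >= 0
        assert (clf.predict(x) == y).mean() >= 0.95

    def test_regressor_bounded_and_fits(self):
        x, y = toy_classes(n=400, k=4, seed=2)
        target = y / 3.0
        reg = LSTMRegressor(units=4, dense_units=32, lr=3e-3, epochs=40,
                            batch_size=128, random_state=0).fit(x, target)
        pred = reg.predict(x)
        assert pred.min() >= 0 and pred.max() <= 1
        assert np.corrcoef(pred, target)[0, 1] > 0.9

    def test_seeded_training_reproducible(self):
        x, y = toy_classes(n=120)
        p1 = LSTMClassifier(n_classes=3, epochs=3, lr=1e-3,
                            random_state=9).fit(x, y).predict_proba(x)
        p2 = LSTMClassifier(n_classes=3, epochs=3, lr=1e-3,
                            random_state=9).fit(x, y).predict_proba(x)
        assert np.array_equal(p1, p2)

    def test_shape_mismatch_rejected(self):
        x, y = toy_classes(n=50)
        clf = LSTMClassifier(n_classes=3, epochs=1).fit(x, y)
        with pytest.raises(ValueError):
            clf.predict_proba(np.zeros((4, 10, 99)))

    def test_empty_prediction_set(self):
        x, y = toy_classes(n=50)
        clf = LSTMClassifier(n_classes=3, epochs=1).fit(x, y)
        assert clf.predict_proba(np.empty((0, 10, 6))).shape == (0, 3)

    def test_sklearn_params_roundtrip(self):
        est = LSTMClassifier(n_classes=4, lr=1e-4)
        clone = LSTMClassifier(**est.get_params())
        assert clone.get_params() == est.get_params()


class TestSampleWeighting:
    def _set(self, n=120, seed=0):
        rng = np.random.default_rng(seed)
        fad = rng.standard_normal((n, 10, 8)) * 0.2
        y = rng.integers(0, 3, n)
        # half the windows get a strong class-specific response
        expressive = np.arange(n) % 2 == 0
        for i in np.flatnonzero(expressive):
            fad[i, :, y[i]] += 3.0
        return fad, y

    def test_size_n_plus_k_counted_independently(self):
        fad, y = self._set()
        idx = sample_weight_indices(fad, y, random_state=1)
        # independent count of qualifying rows with an identical forest
        from painmon.models.rf import RandomForestWindowClassifier

        rf = RandomForestWindowClassifier(random_state=1).fit(fad, y)
        proba = rf.predict_proba(fad)
        cols = np.searchsorted(rf.classes_, y)
        k = int((proba[np.arange(len(y)), cols] > 0.3).sum())
        assert idx.shape[0] == len(y) + k
        assert k > 0

    def test_threshold_above_one_is_identity(self):
        fad, y = self._set()
        idx = sample_weight_indices(fad, y, threshold=1.1, random_state=1)
        assert np.array_equal(idx, np.arange(len(y)))

    def test_output_superset_and_stable_order(self):
        fad, y = self._set()
        idx = sample_weight_indices(fad, y, random_state=1)
        assert set(idx.tolist()) == set(range(len(y)))       # never removes
        assert np.all(np.diff(idx) >= 0)                     # stable order

    def test_apply_duplicates_features_and_targets_together(self):
        fad, y = self._set(60)
        feats = np.arange(60.0)[:, None]
        x2, y2 = apply_sample_weighting(feats, y, fad, y, random_state=1)
        assert x2.shape[0] == y2.shape[0] >= 60
        # duplicated rows stay adjacent to their originals
        assert np.all(np.diff(x2[:, 0]) >= 0)


class TestTrivial:
    def test_all_bl_classification(self):
        scores = trivial_classifier_scores(5, 7)
        assert scores.shape == (5, 7)
        assert np.all(np.argmax(scores, axis=1) == 0)
        assert np.allclose(scores.sum(axis=1), 1.0)

    def test_regression_constant_zero(self):
        assert np.all(trivial_regression(4) == 0.0)

    def test_empty(self):
        assert trivial_classifier_scores(0, 4).shape == (0, 4)
        assert trivial_regression(0).shape == (0,)
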