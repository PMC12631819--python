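"""Dual-path CNN: architecture constraints, gradients, training, metrics."""

import numpy as np
import pytest
from sklearn.metrics import matthews_corrcoef, roc_auc_score

import rnagrid as rg
from rnagrid.model import ShapeScheduleError, cross_entropy

TINY = dict(block1_filters=2, block2_filters=4)  # fast configs for training tests


def _random_batch(rng, n, d_shape=(28, 27, 14), g_shape=(27, 27, 17)):
    return (rng.random((n,) + d_shape), rng.random((n,) + g_shape))


class TestArchitecture:
    def test_each_path_ends_in_192_maps_of_10x10(self, rng):
        model = rg.build_dual_path_model(rg.ModelConfig(seed=0))
        xd, xg = _random_batch(rng, 2)
        md, mg = model.feature_maps(xd, xg)
        assert md.shape == (2, 10, 10, 192)
        assert mg.shape == (2, 10, 10, 192)
        assert model.embedding_dim == 384

    def test_softmax_rows_sum_to_one(self, rng):
        model = rg.build_dual_path_model(rg.ModelConfig(n_classes=5, seed=1))
        xd, xg = _random_batch(rng, 4)
        proba = model.forward(xd, xg)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-6)
        assert proba.shape == (4, 5)

    def test_grid_too_small_names_dimension(self):
        with pytest.raises(ShapeScheduleError, match="8"):
            rg.build_dual_path_model(rg.ModelConfig(), d_grid=(8, 27))

    def test_config_validation(self):
        with pytest.raises(ValueError):
            rg.ModelConfig(n_classes=1)
        with pytest.raises(ValueError):
            rg.ModelConfig(batch_size=0)
        with pytest.raises(ValueError):
            rg.ModelConfig(learning_rate=0.0)


def test_analytic_gradients_match_numerical(rng):
    """Backprop through both paths agrees with central finite differences."""
    cfg = rg.ModelConfig(seed=3, dtype="float64", **TINY)
    model = rg.build_dual_path_model(cfg)
    xd, xg = _random_batch(rng, 3)
    y = np.array([0, 1, 0])

    grads = {}
    ed, _, cd = model._path_forward(xd, "d", True)
    eg, _, cg = model._path_forward(xg, "g", True)
    e = np.concatenate([ed, eg], axis=1)
    z = e @ model.params["head_w"] + model.params["head_b"]
    ez = np.exp(z - z.max(axis=1, keepdims=True))
    proba = ez / ez.sum(axis=1, keepdims=True)
    dz = proba.copy()
    dz[np.arange(3), y] -= 1
    dz /= 3
    grads["head_w"] = e.T @ dz
    grads["head_b"] = dz.sum(axis=0)
    de = dz @ model.params["head_w"].T
    m = model.n_maps
    model._path_backward(de[:, :m], cd, "d", grads)
    model._path_backward(de[:, m:], cg, "g", grads)

    eps = 1e-6
    for key in ("head_w", "d_w0", "d_w1b", "d_w2c", "g_w0", "g_w2a",
                "d_b1a", "g_b2c"):
        arr = model.params[key]
        for _ in range(3):
            ix = tuple(rng.integers(0, s) for s in arr.shape)
            old = arr[ix]
            arr[ix] = old + eps
            lp = cross_entropy(model.forward(xd, xg), y)
            arr[ix] = old - eps
            lm = cross_entropy(model.forward(xd, xg), y)
            arr[ix] = old
            num = (lp - lm) / (2 * eps)
            assert grads[key][ix] == pytest.approx(num, rel=1e-4, abs=1e-7)


class TestTraining:
    def test_overfits_ten_samples(self, rng):
        """Capacity check: 10 samples memorised to loss < 0.05 within 200 epochs."""
        cfg = rg.ModelConfig(seed=5, learning_rate=3e-3, epochs=200,
                             batch_size=10)
        model = rg.build_dual_path_model(cfg)
        xd, xg = _random_batch(rng, 10)
        y = np.array([0, 1] * 5)
        hist = model.train(xd, xg, y)
        assert hist["loss"][-1] < 0.05
        assert hist["loss"][-1] < hist["loss"][0]

    def test_deterministic_given_seed(self, rng):
        xd, xg = _random_batch(rng, 12)
        y = np.array([0, 1] * 6)
        weights = []
        for _ in range(2):
            cfg = rg.ModelConfig(seed=9, epochs=2, **TINY)
            model = rg.build_dual_path_model(cfg)
            model.train(xd, xg, y)
            weights.append(model.params)
        for k in weights[0]:
            np.testing.assert_array_equal(weights[0][k], weights[1][k])

    def test_single_class_rejected(self, rng):
        model = rg.build_dual_path_model(rg.ModelConfig(seed=0, epochs=1, **TINY))
        xd, xg = _random_batch(rng, 6)
        with pytest.raises(ValueError):
            model.train(xd, xg, np.zeros(6, dtype=int))

    def test_shape_mismatch_rejected(self, rng):
        model = rg.build_dual_path_model(rg.ModelConfig(seed=0, epochs=1, **TINY))
        xd, xg = _random_batch(rng, 6)
        with pytest.raises(ValueError, match="shape"):
            model.train(xg, xd, np.array([0, 1] * 3))

    def test_untrained_predict_rejected(self, rng):
        model = rg.build_dual_path_model(rg.ModelConfig(seed=0))
        xd, xg = _random_batch(rng, 2)
        with pytest.raises(RuntimeError, match="untrained"):
            model.predict_proba(xd, xg)

    def test_cross_validation_returns_one_report_per_fold(self, rng):
        cfg = rg.ModelConfig(seed=1, epochs=1, **TINY)
        xd, xg = _random_batch(rng, 30)
        y = np.array([0, 1] * 15)
        reports = rg.cross_validate(cfg, xd, xg, y, n_folds=5)
        assert len(reports) == 5
        for rep in reports:
            assert 0.0 <= rep.acc <= 1.0


@pytest.fixture(scope="module")
def trained():
    rng = np.random.default_rng(0)
    cfg = rg.ModelConfig(seed=2, epochs=1, dtype="float64", **TINY)
    model = rg.build_dual_path_model(cfg)
    xd, xg = _random_batch(rng, 8)
    model.train(xd, xg, np.array([0, 1] * 4))
    return model


class TestPredictProba:

    def test_batch_equals_single_sample(self, trained, rng):
        xd, xg = _random_batch(rng, 5)
        batch = trained.predict_proba(xd, xg)
        for i in range(5):
            single = trained.predict_proba(xd[i:i + 1], xg[i:i + 1])
            np.testing.assert_allclose(single[0], batch[i], atol=1e-6)

    def test_duplicated_input_rows_agree(self, trained, rng):
        xd, xg = _random_batch(rng, 1)
        xd2 = np.repeat(xd, 2, axis=0)
        xg2 = np.repeat(xg, 2, axis=0)
        proba = trained.predict_proba(xd2, xg2)
        np.testing.assert_array_equal(proba[0], proba[1])


def test_model_save_load_round_trip(tmp_path, rng):
    cfg = rg.ModelConfig(seed=4, epochs=1, **TINY)
    model = rg.build_dual_path_model(cfg)
    xd, xg = _random_batch(rng, 6)
    model.train(xd, xg, np.array([0, 1] * 3))
    rg.save_model(model, tmp_path / "m.npz")
    back = rg.load_model(tmp_path / "m.npz")
    np.testing.assert_allclose(back.predict_proba(xd, xg),
                               model.predict_proba(xd, xg))


class TestMetrics:
    def test_perfect_separation(self):
        y = np.array([0, 0, 1, 1])
        s = np.array([0.1, 0.2, 0.8, 0.9])
        rep = rg.compute_metrics(y, s)
        assert rep.mcc == 1.0 and rep.auc == 1.0 and rep.acc == 1.0

    def test_balanced_symmetry_gives_zero_mcc(self):
        y = np.array([1] * 25 + [0] * 25 + [0] * 25 + [1] * 25)
        s = np.array([0.9] * 25 + [0.1] * 25 + [0.9] * 25 + [0.1] * 25)
        rep = rg.compute_metrics(y, s)
        assert rep.mcc == 0.0
        assert rep.acc == 0.5
        assert rep.confusion.tolist() == [[25, 25], [25, 25]]

    def test_closed_form_matches_indicator_correlation(self):
        # TP=40, TN=35, FP=15, FN=10
        y = np.array([1] * 40 + [0] * 35 + [0] * 15 + [1] * 10)
        s = np.array([0.9] * 40 + [0.1] * 35 + [0.9] * 15 + [0.1] * 10)
        rep = rg.compute_metrics(y, s)
        pred = (s >= 0.5).astype(int)
        assert rep.mcc == pytest.approx(np.corrcoef(y, pred)[0, 1], abs=1e-12)
        assert rep.sen == pytest.approx(40 / 50)
        assert rep.spe == pytest.approx(35 / 50)
        assert rep.pre == pytest.approx(40 / 55)

    def test_against_sklearn_cross_checks(self, rng):
        y = rng.integers(0, 2, 200)
        y[:2] = [0, 1]
        s = np.clip(rng.random(200) * 0.6 + y * 0.3, 0, 1)
        rep = rg.compute_metrics(y, s)
        assert rep.auc == pytest.approx(roc_auc_score(y, s), abs=1e-12)
        assert rep.mcc == pytest.approx(
            matthews_corrcoef(y, (s >= 0.5).astype(int)), abs=1e-12)

    def test_auc_mann_whitney_with_ties(self):
        y = np.array([0, 0, 1, 1])
        s = np.array([0.5, 0.2, 0.5, 0.9])
        assert rg.auc_mann_whitney(y, s) == pytest.approx(
            roc_auc_score(y, s), abs=1e-12)

    def test_multiclass_macro_metrics(self, rng):
        y = rng.integers(0, 3, 120)
        proba = rng.random((120, 3))
        proba /= proba.sum(axis=1, keepdims=True)
        rep = rg.compute_metrics(y, proba)
        for v in (rep.spe, rep.sen, rep.pre, rep.acc, rep.auc):
            assert 0.0 <= v <= 1.0
        assert rep.mcc == pytest.approx(
            matthews_corrcoef(y, proba.argmax(axis=1)), abs=1e-12)
        assert rep.confusion.shape == (3, 3)

    def test_degenerate_denominator_warns_and_zeroes(self):
        y = np.array([0, 0, 1, 1])
        s = np.array([0.1, 0.2, 0.3, 0.4])  # no predicted positives
        with pytest.warns(UserWarning):
            rep = rg.compute_metrics(y, s)
        assert rep.pre == 0.0
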