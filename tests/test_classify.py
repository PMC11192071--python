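"""Classifier unit tests: split protocol, MLC, MaxEnt, random forest."""

import warnings

import numpy as np
import pytest

from mulchmap import synthetic_scene as sc
from mulchmap.classify import (SplitSpec, UNCLASSIFIED, fit_maxent, fit_mlc,
                               fit_rf, load_model, maxent_objective,
                               predict_maxent, predict_mlc, predict_rf,
                               save_model, split_train_val)
from mulchmap.geo_io import GridTransform, MultibandRaster, TrainingSet


def toy_training(means, n_per_class=50, scale=0.5, n_polys=2, seed=0,
                 band_names=None):
    """Gaussian blobs, one class per mean, polygons assigned round-robin."""
    rng = np.random.default_rng(seed)
    means = np.atleast_2d(np.asarray(means, dtype=float))
    C, B = means.shape
    X = np.vstack([rng.normal(m, scale, size=(n_per_class, B))
                   for m in means])
    y = np.repeat(np.arange(C), n_per_class)
    pid = np.concatenate([c * n_polys + (np.arange(n_per_class) % n_polys)
                          for c in range(C)])
    return TrainingSet(X, y, pid, [f"c{i}" for i in range(C)],
                       band_names or [f"b{i}" for i in range(B)])


class TestSplit:
    def test_polygon_count_arithmetic(self):
        ts = toy_training([[0.0], [10.0]], n_per_class=100, n_polys=10)
        train, val = split_train_val(ts, SplitSpec(0.8, seed=1))
        for c in (0, 1):
            assert len(np.unique(train.polygon_id[train.y == c])) == 8
            assert len(np.unique(val.polygon_id[val.y == c])) == 2

    def test_whole_polygons_and_coverage(self):
        ts = toy_training([[0.0], [10.0]], n_per_class=60, n_polys=5)
        train, val = split_train_val(ts, SplitSpec(seed=2))
        assert len(train) + len(val) == len(ts)
        assert not set(map(tuple, zip(train.y, train.polygon_id))) & \
            set(map(tuple, zip(val.y, val.polygon_id)))

    def test_deterministic_under_seed(self):
        ts = toy_training([[0.0], [10.0]], n_polys=6)
        a = split_train_val(ts, SplitSpec(seed=7))
        b = split_train_val(ts, SplitSpec(seed=7))
        np.testing.assert_array_equal(a[0].polygon_id, b[0].polygon_id)

    def test_val_side_has_every_class(self, swir_training):
        """A field-survey-sized polygon plan leaves at least one validation
        polygon per class."""
        train, val = split_train_val(swir_training, SplitSpec(seed=3))
        assert set(val.y) == set(swir_training.y)
        assert set(train.y) == set(swir_training.y)

    def test_too_few_polygons_rejected(self):
        ts = toy_training([[0.0], [10.0]], n_polys=1)
        with pytest.raises(ValueError):
            split_train_val(ts)


def label_raster_from_X(X, shape, band_names, pixel_size=1.0):
    vals = np.asarray(X, dtype=float).T.reshape(len(band_names), *shape)
    tf = GridTransform(pixel_size, 0.0, shape[0] * pixel_size)
    return MultibandRaster(vals, list(band_names), tf)


class TestMLC:
    def test_equal_variance_boundary_at_midpoint(self):
        """Equal-variance 1-D classes at 0 and 10 with uniform priors give
        a decision boundary exactly at 5."""
        from mulchmap.classify import MLCModel
        m = MLCModel(["a", "b"], ["b0"], np.array([[0.0], [10.0]]),
                     np.ones((2, 1, 1)), np.zeros(2),
                     np.log([0.5, 0.5]), 0.0)
        g = m.discriminants(np.array([[5.0], [4.999], [5.001]]))
        assert g[0, 0] == pytest.approx(g[0, 1])  # exactly on the boundary
        assert np.argmax(g[1]) == 0 and np.argmax(g[2]) == 1

    def test_parameter_recovery_on_synthetic_scene(self, library,
                                                   swir_training):
        """Estimated class means lie within ~3 SE of the generating means."""
        for c in np.unique(swir_training.y):
            Xc = swir_training.X[swir_training.y == c]
            if len(Xc) < 100:
                continue
            cname = swir_training.class_names[c]
            mu, cov = library.marginal(cname, sc.SWIR_BANDS)
            se = np.sqrt(np.diag(cov) / len(Xc))
            m = fit_mlc(swir_training)
            assert np.all(np.abs(m.means[c] - mu) <= 3.5 * se)

    def test_single_class_degenerate(self):
        rng = np.random.default_rng(0)
        X = rng.normal(5.0, 1.0, size=(50, 2))
        ts = TrainingSet(X, np.zeros(50, int), np.arange(50) % 2,
                         ["only"], ["b0", "b1"])
        m = fit_mlc(ts)
        assert np.all(m.predict(rng.normal(0, 10, size=(20, 2))) == 0)

    def test_posteriors_sum_to_one(self, swir_training):
        m = fit_mlc(swir_training)
        P = m.posterior(swir_training.X[:100])
        np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-9)

    def test_raster_prediction_matches_bruteforce_oracle(self, rng):
        """Vectorised raster path equals a per-pixel Bayes-discriminant
        loop to 1e-10 (labels exactly, posteriors numerically)."""
        ts = toy_training([[0, 0], [4, 1], [1, 5]], n_per_class=60, seed=3)
        m = fit_mlc(ts)
        X = rng.uniform(-1, 6, size=(100, 2))
        raster = label_raster_from_X(X, (10, 10), ts.band_names)
        cr = predict_mlc(m, raster)
        # independent brute force: solve per class per pixel
        for i, x in enumerate(X):
            g = np.empty(3)
            for c in range(3):
                d = x - m.means[c]
                g[c] = (m.log_priors[c] - 0.5 * m.log_dets[c]
                        - 0.5 * d @ np.linalg.solve(m.covariances[c], d))
            e = np.exp(g - g.max())
            post = e / e.sum()
            r, col = divmod(i, 10)
            assert cr.labels[r, col] == np.argmax(g)
            np.testing.assert_allclose(cr.posterior[:, r, col], post,
                                       atol=1e-10)

    def test_nodata_pixels_unclassified(self):
        ts = toy_training([[0.0], [10.0]])
        m = fit_mlc(ts)
        vals = np.array([[[0.0, 10.0], [-1.0, 0.0]]])
        raster = MultibandRaster(vals, ["b0"], GridTransform(1, 0, 2),
                                 nodata=-1.0)
        cr = predict_mlc(m, raster)
        assert cr.labels[1, 0] == UNCLASSIFIED
        assert cr.labels[0, 0] == 0 and cr.labels[0, 1] == 1

    def test_band_mismatch_rejected(self):
        ts = toy_training([[0.0], [10.0]])
        m = fit_mlc(ts)
        raster = label_raster_from_X(np.zeros((4, 1)), (2, 2), ["other"])
        with pytest.raises(ValueError):
            predict_mlc(m, raster)


class TestMaxEnt:
    def test_separable_training_accuracy(self):
        ts = toy_training([[-1.0], [1.0]], scale=0.05, n_per_class=100)
        m = fit_maxent(ts)
        assert (m.predict(ts.X) == ts.y).mean() == 1.0

    def test_strong_penalty_gives_uniform_probabilities(self):
        ts = toy_training([[-1.0], [0.0], [1.0]], scale=0.3)
        m = fit_maxent(ts, l2=1e6)
        assert np.abs(m.weights).max() < 1e-3
        P = m.predict_proba(ts.X[:10])
        np.testing.assert_allclose(P, 1.0 / 3.0, atol=1e-3)

    def test_gradient_matches_finite_differences(self, rng):
        """Analytic gradient of the penalised log-likelihood agrees with a
        central finite-difference oracle to 1e-5."""
        n, B, C = 30, 3, 4
        Phi = np.hstack([np.ones((n, 1)), rng.normal(size=(n, B))])
        Y = np.zeros((n, C))
        Y[np.arange(n), rng.integers(C, size=n)] = 1.0
        w = rng.normal(scale=0.5, size=C * (B + 1))
        _, grad = maxent_objective(w, Phi, Y, 1e-3)
        eps = 1e-6
        fd = np.empty_like(w)
        for i in range(len(w)):
            wp, wm = w.copy(), w.copy()
            wp[i] += eps
            wm[i] -= eps
            fp, _ = maxent_objective(wp, Phi, Y, 1e-3)
            fm, _ = maxent_objective(wm, Phi, Y, 1e-3)
            fd[i] = (fp - fm) / (2 * eps)
        np.testing.assert_allclose(grad, fd, atol=1e-5)

    def test_probabilities_sum_to_one_on_raster(self):
        ts = toy_training([[0.0, 0.0], [3.0, 3.0]])
        m = fit_maxent(ts)
        raster = label_raster_from_X(np.random.default_rng(0).uniform(
            0, 3, size=(16, 2)), (4, 4), ts.band_names)
        cr = predict_maxent(m, raster)
        np.testing.assert_allclose(cr.posterior.sum(axis=0), 1.0, atol=1e-9)

    def test_single_class_rejected(self):
        ts = toy_training([[0.0]])
        with pytest.raises(ValueError):
            fit_maxent(ts)


class TestRandomForest:
    def test_single_tree_separable(self):
        ts = toy_training([[0.0], [10.0]], scale=0.1)
        m = fit_rf(ts, n_trees=1, features_per_split=1, seed=0)
        assert (m.predict(ts.X) == ts.y).mean() == 1.0

    def test_deterministic_under_seed(self):
        ts = toy_training([[0, 0], [3, 1], [1, 4]], n_per_class=40)
        a = fit_rf(ts, n_trees=20, seed=5)
        b = fit_rf(ts, n_trees=20, seed=5)
        X = np.random.default_rng(1).uniform(0, 4, size=(50, 2))
        np.testing.assert_array_equal(a.votes(X), b.votes(X))

    def test_raster_prediction_roundtrip(self):
        ts = toy_training([[0.0], [10.0]], scale=0.2)
        m = fit_rf(ts, n_trees=5, seed=2)
        raster = label_raster_from_X(
            np.array([[0.1], [9.8], [0.3], [10.2]]), (2, 2), ts.band_names)
        cr = predict_rf(m, raster)
        np.testing.assert_array_equal(cr.labels, [[0, 1], [0, 1]])

    def test_vote_ties_break_to_lowest_class(self):
        # two stumps voting for different classes on the same point
        from mulchmap.classify import ForestModel
        trees = [{"leaf": 1}, {"leaf": 0}]
        m = ForestModel(["a", "b"], ["b0"], trees, 1, 0)
        assert m.predict(np.array([[0.0]]))[0] == 0

    def test_invalid_tree_count(self):
        ts = toy_training([[0.0], [1.0]])
        with pytest.raises(ValueError):
            fit_rf(ts, n_trees=0)


class TestPersistence:
    @pytest.mark.parametrize("fitter", [
        lambda ts: fit_mlc(ts),
        lambda ts: fit_maxent(ts),
        lambda ts: fit_rf(ts, n_trees=10, seed=1),
    ], ids=["mlc", "maxent", "rf"])
    def test_json_round_trip_preserves_predictions(self, tmp_path, fitter):
        ts = toy_training([[0, 0], [4, 1], [1, 5]], n_per_class=40)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = fitter(ts)
        path = tmp_path / "model.json"
        save_model(model, path)
        back = load_model(path)
        X = np.random.default_rng(2).uniform(0, 5, size=(50, 2))
        np.testing.assert_array_equal(model.predict(X), back.predict(X))
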