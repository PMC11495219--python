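import numpy as np
import pytest
from sklearn.decomposition import PCA as SkPCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.neighbors import KNeighborsClassifier

from codi import (
    SpectraSet, SpectralAxis,
    evaluate, fit_binary, fit_identifier, fit_log_trend, load_model,
    predict, save_model,
)
from codi.classify import EvalResult
from codi.errors import (
    AxisMismatchError, DegenerateTaskError, InsufficientClassError,
    InsufficientDataError, LabelDomainError, ParameterError,
)


def _set(data, labels, axis=None):
    data = np.atleast_2d(np.asarray(data, dtype=float))
    if axis is None:
        axis = SpectralAxis(np.arange(data.shape[1], dtype=float) + 1.0)
    return SpectraSet(axis, data, np.asarray(labels, dtype=str))


def _gaussian_blobs(rng, means, n_each, sd=1.0):
    data, labels = [], []
    for k, mu in enumerate(means):
        data.append(rng.normal(loc=mu, scale=sd, size=(n_each, len(mu))))
        labels += [f"c{k}"] * n_each
    return np.vstack(data), np.array(labels)


class TestFitIdentifier:
    def test_auto_selects_one_nn_for_single_instances(self):
        rng = np.random.default_rng(0)
        train = _set(rng.normal(size=(31, 10)), [f"p{i}" for i in range(31)])
        model = fit_identifier(train, "auto")
        assert model.kind == "one_nn"

    def test_auto_selects_lda_for_multiple_instances(self):
        rng = np.random.default_rng(0)
        X, y = _gaussian_blobs(rng, [[0, 0], [5, 5]], 10)
        assert fit_identifier(_set(X, y), "auto").kind == "pca_lda"

    def test_one_nn_self_accuracy_is_one(self):
        rng = np.random.default_rng(1)
        train = _set(rng.normal(size=(20, 8)), [f"p{i}" for i in range(20)])
        model = fit_identifier(train, "auto")
        assert evaluate(model, train).accuracy == 1.0

    def test_two_gaussians_held_out_accuracy(self):
        rng = np.random.default_rng(2)
        X, y = _gaussian_blobs(rng, [[0.0, 0.0], [10.0, 0.0]], 100)
        model = fit_identifier(_set(X, y), "pca_lda", variance_kept=1.0)
        Xt, yt = _gaussian_blobs(rng, [[0.0, 0.0], [10.0, 0.0]], 100)
        assert evaluate(model, _set(Xt, yt)).accuracy > 0.99

    def test_single_class_rejected(self):
        with pytest.raises(DegenerateTaskError):
            fit_identifier(_set(np.eye(3), ["a", "a", "a"]))

    def test_variance_kept_domain(self):
        rng = np.random.default_rng(3)
        train = _set(rng.normal(size=(4, 3)), ["a", "b", "c", "d"])
        for bad in (0.0, 1.5, -0.1):
            with pytest.raises(ParameterError):
                fit_identifier(train, variance_kept=bad)

    def test_pca_reconstruction_bound(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(50, 20)) @ rng.normal(size=(20, 20))
        kept = 0.9
        model = fit_identifier(_set(X, [f"c{i % 5}" for i in range(50)]),
                               "pca_lda", variance_kept=kept)
        Z = model.project(X)
        recon = Z @ model.basis.T + model.center
        lost = ((X - recon) ** 2).sum() / ((X - X.mean(0)) ** 2).sum()
        assert lost <= 1 - kept + 1e-9

    def test_component_count_matches_sklearn(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(40, 15))
        model = fit_identifier(_set(X, [f"c{i % 4}" for i in range(40)]),
                               "pca_lda", variance_kept=0.95)
        sk = SkPCA(n_components=0.95, svd_solver="full").fit(X)
        assert model.n_components == sk.n_components_


class TestPredict:
    def test_training_row_maps_to_own_label(self):
        rng = np.random.default_rng(6)
        train = _set(rng.normal(size=(10, 6)), [f"p{i}" for i in range(10)])
        model = fit_identifier(train, "one_nn")
        np.testing.assert_array_equal(predict(model, train), train.labels)

    def test_tie_breaks_to_lowest_index(self):
        train = _set([[0.0, 1.0], [2.0, 1.0], [4.0, 1.0], [0.0, 1.0]],
                     ["a", "b", "c", "d"])
        model = fit_identifier(train, "one_nn", variance_kept=1.0)
        # test row equidistant from training rows 0 and 3 (identical points)
        out = predict(model, _set([[0.0, 1.0]], ["a"]))
        assert out[0] == "a"

    def test_empty_test_set(self):
        train = _set(np.eye(3), ["a", "b", "c"])
        model = fit_identifier(train, "one_nn")
        empty = SpectraSet(train.axis, np.empty((0, 3)), np.array([], dtype=str))
        assert predict(model, empty).size == 0

    def test_axis_mismatch(self):
        train = _set(np.eye(3), ["a", "b", "c"])
        model = fit_identifier(train, "one_nn")
        other = _set(np.eye(3), ["a", "b", "c"],
                     axis=SpectralAxis(np.array([9.0, 10.0, 11.0])))
        with pytest.raises(AxisMismatchError):
            predict(model, other)

    @pytest.mark.filterwarnings("ignore::UserWarning")  # sklearn: many classes
    def test_one_nn_matches_sklearn_in_projected_space(self):
        rng = np.random.default_rng(7)
        train = _set(rng.normal(size=(25, 12)), [f"p{i}" for i in range(25)])
        test = _set(rng.normal(size=(40, 12)), ["p0"] * 40)
        model = fit_identifier(train, "one_nn")
        Ztr, Zte = model.project(train.data), model.project(test.data)
        sk = KNeighborsClassifier(n_neighbors=1).fit(Ztr, train.labels)
        np.testing.assert_array_equal(predict(model, test), sk.predict(Zte))

    def test_lda_matches_sklearn_predictions(self):
        rng = np.random.default_rng(8)
        X, y = _gaussian_blobs(rng, [[0, 0, 0], [3, 0, 0], [0, 3, 0]], 40)
        model = fit_identifier(_set(X, y), "pca_lda", variance_kept=1.0)
        Z = model.project(X)
        sk = LinearDiscriminantAnalysis(solver="lsqr").fit(Z, y)
        Xt, yt = _gaussian_blobs(rng, [[0, 0, 0], [3, 0, 0], [0, 3, 0]], 30)
        Zt = model.project(Xt)
        ours = predict(model, _set(Xt, yt))
        np.testing.assert_array_equal(ours, sk.predict(Zt))


class TestFitBinary:
    def test_separable_data_has_finite_weights(self):
        X = np.array([[0.0], [0.1], [0.2], [5.0], [5.1], [5.2]])
        # 1-D toy input padded to 2 channels for a valid axis
        s = _set(np.hstack([X, np.zeros_like(X)]), ["a", "a", "a", "b", "b", "b"])
        model = fit_binary(s, ridge_strength=1.0)
        assert np.all(np.isfinite(model.params["weights"]))

    def test_duplicated_feature_weights_equal(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=(60, 1))
        y = (x[:, 0] + 0.5 * rng.normal(size=60) > 0)
        X = np.hstack([x, x, rng.normal(size=(60, 1))])
        model = fit_binary(_set(X, np.where(y, "b", "a")))
        w = model.params["weights"]
        assert abs(w[0] - w[1]) < 1e-6

    def test_class_size_requirement(self):
        with pytest.raises(InsufficientClassError):
            fit_binary(_set(np.eye(3), ["a", "b", "b"]))

    def test_needs_two_classes(self):
        with pytest.raises(DegenerateTaskError):
            fit_binary(_set(np.eye(4), ["a"] * 4))

    def test_permutation_null_auc(self):
        rng = np.random.default_rng(10)
        aucs = []
        for _ in range(5):
            X = rng.normal(size=(500, 8))
            y = rng.permutation(["a"] * 250 + ["b"] * 250)
            model = fit_binary(_set(X[:400], y[:400]))
            aucs.append(evaluate(model, _set(X[400:], y[400:])).auc)
        assert abs(np.mean(aucs) - 0.5) < 0.1


class TestEvaluate:
    def test_perfect_predictions(self):
        train = _set(np.eye(4) * 5, ["a", "b", "c", "d"])
        model = fit_identifier(train, "one_nn")
        assert evaluate(model, train).accuracy == 1.0

    def test_confusion_accuracy_arithmetic(self):
        res = EvalResult(accuracy=0.7, per_class={}, n_test=10,
                         confusion=np.array([[3, 1], [2, 4]]))
        assert np.trace(res.confusion) / res.confusion.sum() == pytest.approx(0.7)

    def test_accuracy_equals_confusion_trace(self):
        rng = np.random.default_rng(11)
        X, y = _gaussian_blobs(rng, [[0, 0], [2, 2], [4, 0]], 20)
        model = fit_identifier(_set(X, y), "pca_lda")
        Xt, yt = _gaussian_blobs(rng, [[0, 0], [2, 2], [4, 0]], 15)
        res = evaluate(model, _set(Xt, yt))
        assert res.accuracy == pytest.approx(
            np.trace(res.confusion) / res.confusion.sum())

    def test_tied_scores_auc_half(self):
        rng = np.random.default_rng(12)
        X = np.zeros((40, 3))  # all test rows identical => identical scores
        train = _set(rng.normal(size=(40, 3)),
                     ["a"] * 20 + ["b"] * 20)
        model = fit_binary(train)
        res = evaluate(model, _set(X, ["a"] * 20 + ["b"] * 20))
        assert res.auc == pytest.approx(0.5)

    def test_unknown_label_rejected(self):
        train = _set(np.eye(3), ["a", "b", "c"])
        model = fit_identifier(train, "one_nn")
        with pytest.raises(LabelDomainError):
            evaluate(model, _set(np.eye(3), ["a", "b", "zzz"]))

    def test_label_permutation_null_accuracy(self):
        rng = np.random.default_rng(13)
        K, n = 8, 25
        X = rng.normal(size=(K * n, 10))
        y = rng.permutation(np.repeat([f"c{k}" for k in range(K)], n))
        model = fit_identifier(_set(X, y), "pca_lda")
        Xt = rng.normal(size=(400, 10))
        yt = rng.choice([f"c{k}" for k in range(K)], size=400)
        acc = evaluate(model, _set(Xt, yt)).accuracy
        p = 1.0 / K
        assert abs(acc - p) <= 3 * np.sqrt(p * (1 - p) / 400)


class TestLogTrend:
    def test_exact_logarithmic_data(self):
        sizes = np.array([2, 4, 8, 16, 32])
        acc = 0.95 - 0.04 * np.log2(sizes)
        slope, intercept, r2 = fit_log_trend(sizes, acc)
        assert slope == pytest.approx(-0.04, abs=1e-9)
        assert intercept == pytest.approx(0.95, abs=1e-9)
        assert r2 == pytest.approx(1.0, abs=1e-12)

    def test_constant_accuracies_convention(self):
        slope, _, r2 = fit_log_trend([2, 4, 8], [0.5, 0.5, 0.5])
        assert slope == 0.0 and r2 == 0.0

    def test_collinear_points(self):
        slope, intercept, r2 = fit_log_trend([2, 4, 8], [0.9, 0.8, 0.7])
        assert slope == pytest.approx(-0.1)
        assert intercept == pytest.approx(1.0)
        assert r2 == pytest.approx(1.0)

    def test_too_few_points(self):
        with pytest.raises(InsufficientDataError):
            fit_log_trend([2, 4], [0.9, 0.8])

    def test_sizes_must_be_at_least_two(self):
        with pytest.raises(ParameterError):
            fit_log_trend([1, 2, 4], [1.0, 0.9, 0.8])


class TestPersistence:
    @pytest.mark.parametrize("kind", ["one_nn", "pca_lda", "ridge_logistic"])
    def test_save_load_round_trip(self, kind, tmp_path):
        rng = np.random.default_rng(14)
        if kind == "ridge_logistic":
            X, y = _gaussian_blobs(rng, [[0, 0, 0], [2, 2, 2]], 20)
            model = fit_binary(_set(X, y))
        elif kind == "pca_lda":
            X, y = _gaussian_blobs(rng, [[0, 0, 0], [2, 2, 2]], 20)
            model = fit_identifier(_set(X, y), "pca_lda")
        else:
            X = rng.normal(size=(10, 3))
            y = [f"p{i}" for i in range(10)]
            model = fit_identifier(_set(X, y), "one_nn")
        test = _set(rng.normal(size=(25, 3)), [str(y[0])] * 25)
        path = tmp_path / "m.json"
        save_model(model, path)
        back = load_model(path)
        assert back.kind == model.kind
        np.testing.assert_array_equal(predict(back, test), predict(model, test))
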