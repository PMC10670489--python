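import numpy as np
import pytest
from sklearn.decomposition import PCA as SkPCA

from ramancell import chemometrics as cm
from ramancell.spectra import NON_TUMOR, TUMOR


class TestPCA:
    def test_eigenvalues_match_dense_eigensolver(self):
        """Covariance-matrix PCA agrees with a brute-force eigendecomposition
        and with the SVD-based sklearn implementation on a toy matrix."""
        rng = np.random.default_rng(0)
        X = rng.normal(size=(10, 20))
        model = cm.pca_fit(X)
        C = np.cov(X - X.mean(axis=0), rowvar=False, ddof=1)
        brute = np.sort(np.linalg.eigvalsh(C))[::-1]
        assert np.allclose(model.explained_variance, np.clip(brute, 0, None),
                           atol=1e-10)
        sk = SkPCA().fit(X)
        k = sk.explained_variance_.size
        assert np.allclose(model.explained_variance[:k], sk.explained_variance_,
                           atol=1e-8)

    def test_planar_data_has_two_nonzero_eigenvalues(self):
        rng = np.random.default_rng(1)
        basis = rng.normal(size=(2, 15))
        X = rng.normal(size=(40, 2)) @ basis + rng.normal(size=15)
        model = cm.pca_fit(X)
        assert np.sum(model.explained_variance > 1e-10) == 2

    def test_full_reconstruction(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(12, 8))
        model = cm.pca_fit(X)
        back = model.inverse_transform(model.transform(X))
        assert np.max(np.abs(back - X)) < 1e-8

    def test_variance_percentages_sum_and_order(self):
        rng = np.random.default_rng(3)
        model = cm.pca_fit(rng.normal(size=(30, 12)))
        assert model.explained_variance_pct.sum() == pytest.approx(100.0, abs=1e-6)
        assert np.all(np.diff(model.explained_variance_pct) <= 1e-12)

    def test_loadings_orthonormal(self):
        rng = np.random.default_rng(4)
        model = cm.pca_fit(rng.normal(size=(25, 10)))
        G = model.components @ model.components.T
        assert np.allclose(G, np.eye(G.shape[0]), atol=1e-10)


class TestMetrics:
    def test_tuned_lda_confusion_worked_example(self):
        """Confusion counts TN=31, FP=2, FN=6, TP=34 give 89% accuracy,
        85.00% sensitivity and 93.94% specificity."""
        m = cm.Metrics(tn=31, fp=2, fn=6, tp=34)
        assert round(100 * m.accuracy) == 89
        assert m.as_percent(m.sensitivity) == 85.00
        assert m.as_percent(m.specificity) == 93.94

    def test_cnn_confusion_worked_example(self):
        m = cm.Metrics(tn=33, fp=3, fn=2, tp=35)
        assert round(100 * m.accuracy) == 93

    def test_all_correct_gives_unit_rates(self):
        y = [TUMOR, NON_TUMOR, TUMOR, NON_TUMOR]
        m = cm.compute_metrics(y, y)
        assert m.accuracy == m.sensitivity == m.specificity == m.precision == 1.0
        assert m.f1 == 1.0

    def test_agrees_with_counting_oracle_on_random_vectors(self):
        """compute_metrics matches an explicit four-way counter on 1000
        random label-vector pairs."""
        rng = np.random.default_rng(7)
        classes = np.array([NON_TUMOR, TUMOR])
        for _ in range(1000):
            n = int(rng.integers(2, 25))
            y_true = classes[rng.integers(0, 2, n)]
            y_pred = classes[rng.integers(0, 2, n)]
            m = cm.compute_metrics(y_true, y_pred)
            tp = sum(t == TUMOR and p == TUMOR for t, p in zip(y_true, y_pred))
            tn = sum(t == NON_TUMOR and p == NON_TUMOR for t, p in zip(y_true, y_pred))
            fp = sum(t == NON_TUMOR and p == TUMOR for t, p in zip(y_true, y_pred))
            fn = sum(t == TUMOR and p == NON_TUMOR for t, p in zip(y_true, y_pred))
            assert (m.tn, m.fp, m.fn, m.tp) == (tn, fp, fn, tp)
            assert m.n == n

    def test_empty_and_mismatched_inputs_rejected(self):
        with pytest.raises(ValueError):
            cm.compute_metrics([], [])
        with pytest.raises(ValueError):
            cm.compute_metrics([TUMOR], [TUMOR, TUMOR])

    def test_f1_is_harmonic_mean(self):
        assert cm.harmonic_f1(1.0, 0.5) == pytest.approx(2 / 3)
        m = cm.Metrics(tn=5, fp=3, fn=2, tp=10)
        assert m.f1 == pytest.approx(cm.harmonic_f1(m.precision, m.sensitivity))


def _two_gaussians(n, separation, seed, p=10):
    rng = np.random.default_rng(seed)
    X0 = rng.normal(size=(n // 2, p))
    X1 = rng.normal(size=(n - n // 2, p))
    X1[:, 0] += separation
    X = np.vstack([X0, X1])
    y = np.array([NON_TUMOR] * (n // 2) + [TUMOR] * (n - n // 2))
    return X, y


class TestLDA:
    def test_widely_separated_classes_classified_perfectly(self):
        X, y = _two_gaussians(200, separation=10.0, seed=0)
        Xt, yt = _two_gaussians(200, separation=10.0, seed=1)[0], \
            _two_gaussians(200, separation=10.0, seed=1)[1]
        model = cm.lda_fit(X, y)
        assert np.mean(model.predict(Xt) == yt) == 1.0

    def test_identical_distributions_give_chance_accuracy(self):
        X, y = _two_gaussians(1000, separation=0.0, seed=2)
        Xt, yt = _two_gaussians(1000, separation=0.0, seed=3)
        model = cm.lda_fit(X, y)
        assert np.mean(model.predict(Xt) == yt) == pytest.approx(0.5, abs=0.05)

    def test_single_class_rejected(self):
        X = np.random.default_rng(0).normal(size=(10, 3))
        with pytest.raises(ValueError):
            cm.lda_fit(X, np.array([TUMOR] * 10))

    def test_decision_boundary_is_linear_between_means(self):
        """The equal-covariance discriminant is linear: the margin along
        the inter-mean segment is affine and flips sign exactly once."""
        X, y = _two_gaussians(400, separation=4.0, seed=4)
        model = cm.lda_fit(X, y)
        m0 = X[y == NON_TUMOR].mean(axis=0)
        m1 = X[y == TUMOR].mean(axis=0)
        ts = np.linspace(0, 1, 201)
        points = np.outer(1 - ts, m0) + np.outer(ts, m1)
        margin = model.estimator.decision_function(points)
        assert np.max(np.abs(np.diff(margin, 2))) < 1e-8  # affine in t
        assert margin[0] < 0 < margin[-1]
        crossings = np.sum((margin[:-1] < 0) & (margin[1:] >= 0))
        assert crossings == 1


class TestTunedLDA:
    def test_single_point_grid_equals_plain_fit(self):
        X, y = _two_gaussians(80, separation=2.0, seed=5)
        tuned, history = cm.tune_lda_grid(X, y, grid=[{"solver": "svd"}])
        plain = cm.lda_fit(X, y)
        assert len(history) == 1
        assert np.array_equal(tuned.predict(X), plain.predict(X))

    def test_best_cv_accuracy_bounds_default(self):
        X, y = _two_gaussians(120, separation=1.0, seed=6)
        cv = cm.CVConfig(k=5, seed=6)
        _, history = cm.tune_lda_grid(X, y, cv=cv)
        default_acc = cm._cv_accuracy({"solver": "svd"}, X, y, cv)
        assert max(acc for _, acc in history) >= default_acc

    def test_empty_grid_rejected(self):
        X, y = _two_gaussians(40, separation=1.0, seed=7)
        with pytest.raises(ValueError):
            cm.tune_lda_grid(X, y, grid=[])

    def test_shrinkage_helps_in_high_dimension(self):
        """With many more channels than training spectra, the regularized
        (tuned) discriminant beats the plain one on held-out data, on
        average over seeds."""
        deltas = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            n, p = 40, 150
            X = rng.normal(size=(n, p))
            y = np.array([NON_TUMOR, TUMOR] * (n // 2))
            X[y == TUMOR, :3] += 1.0
            Xt = rng.normal(size=(400, p))
            yt = np.array([NON_TUMOR, TUMOR] * 200)
            Xt[yt == TUMOR, :3] += 1.0
            plain = cm.lda_fit(X, y)
            tuned, _ = cm.tune_lda_grid(X, y, cv=cm.CVConfig(k=4, seed=seed))
            deltas.append(
                np.mean(tuned.predict(Xt) == yt) - np.mean(plain.predict(Xt) == yt)
            )
        assert np.mean(deltas) > 0


class TestPCALDA:
    def test_separable_two_pc_structure_selects_lower_bound(self):
        rng = np.random.default_rng(8)
        basis = rng.normal(size=(2, 30))
        scores = rng.normal(size=(60, 2))
        y = np.where(scores[:, 0] > 0, TUMOR, NON_TUMOR)
        scores[:, 0] += np.where(scores[:, 0] > 0, 3.0, -3.0)
        X = scores @ basis + 0.01 * rng.normal(size=(60, 30))
        n_pc, model, detail = cm.pca_lda_loocv(X, y, pc_range=range(2, 11, 2))
        assert n_pc == 2
        assert detail["loocv_error"][2] == 0.0

    def test_selected_error_bounds_range_endpoints(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(50, 25))
        y = np.array([NON_TUMOR, TUMOR] * 25)
        X[y == TUMOR, 0] += 1.5
        n_pc, _, detail = cm.pca_lda_loocv(X, y, pc_range=range(2, 9))
        errs = detail["loocv_error"]
        assert errs[n_pc] <= errs[min(errs)] and errs[n_pc] <= errs[max(errs)]

    def test_cumulative_variance_reported(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(40, 15))
        y = np.array([NON_TUMOR, TUMOR] * 20)
        _, _, detail = cm.pca_lda_loocv(X, y, pc_range=[3, 5])
        assert 0 < detail["cumulative_variance_pct"] <= 100


class _Memorizer:
    """Predicts perfectly on anything it has seen; first class otherwise."""

    def fit(self, X, y):
        self._bank = {tuple(row): label for row, label in zip(X, y)}
        self._default = y[0]
        return self

    def predict(self, X):
        return np.array([self._bank.get(tuple(row), self._default) for row in X])


class TestLearningCurve:
    def test_memorizing_model_has_unit_train_accuracy(self):
        X, y = _two_gaussians(100, separation=0.5, seed=11)
        curve = cm.learning_curve(_Memorizer, X, y,
                                  cv=cm.CVConfig(k=4, seed=11),
                                  train_sizes=[20, 40, 60])
        assert all(train_acc == 1.0 for _, train_acc, _ in curve)

    def test_curve_length_matches_grid(self):
        X, y = _two_gaussians(100, separation=2.0, seed=12)
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        sizes = [20, 40, 60]
        curve = cm.learning_curve(
            LinearDiscriminantAnalysis, X, y,
            cv=cm.CVConfig(k=4, seed=12), train_sizes=sizes,
        )
        assert [n for n, _, _ in curve] == sizes

    def test_oversized_request_rejected(self):
        X, y = _two_gaussians(40, separation=2.0, seed=13)
        with pytest.raises(ValueError):
            cm.learning_curve(_Memorizer, X, y, cv=cm.CVConfig(k=4, seed=0),
                              train_sizes=[1000])

    def test_cv_accuracy_improves_with_more_data(self):
        """Average CV accuracy is higher with the largest training size
        than with the smallest, over multiple seeds."""
        gains = []
        for seed in range(8):
            X, y = _two_gaussians(120, separation=1.0, seed=20 + seed, p=30)
            from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

            curve = cm.learning_curve(
                LinearDiscriminantAnalysis, X, y,
                cv=cm.CVConfig(k=4, seed=seed), train_sizes=[12, 80],
            )
            gains.append(curve[-1][2] - curve[0][2])
        assert np.mean(gains) > 0


class TestSplits:
    def test_stratified_split_preserves_class_ratio(self):
        X, y = _two_gaussians(100, separation=1.0, seed=14)
        X_tr, X_te, y_tr, y_te = cm.stratified_split(X, y, seed=14)
        assert abs(np.sum(y_te == TUMOR) - 0.2 * np.sum(y == TUMOR)) <= 1
        assert len(y_tr) + len(y_te) == 100

    def test_cell_split_keeps_cells_together(self):
        rng = np.random.default_rng(15)
        X = rng.normal(size=(60, 5))
        y = np.array([NON_TUMOR, TUMOR] * 30)
        groups = np.repeat(np.arange(12), 5)
        X_tr, X_te, y_tr, y_te = cm.cell_split(X, y, groups, seed=15)
        # recover group ids by matching rows
        def ids(subset):
            out = set()
            for row in subset:
                idx = int(np.argmin(np.linalg.norm(X - row, axis=1)))
                out.add(groups[idx])
            return out

        assert ids(X_tr).isdisjoint(ids(X_te))
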