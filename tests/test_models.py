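"""PLS(-DA), KNN and grid-searched SVM baseline models."""

import numpy as np
import pytest
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from gastronir.models import (
    GridSearchSVM,
    KNNConfig,
    KNNModel,
    PLSCalibration,
    PLSDAClassifier,
    classify_plsda,
    fit_plsr,
    knn_predict,
    svm_grid_search,
)


class TestPLSCalibration:
    def test_rank_one_relationship_recovered_with_one_component(self, rng):
        # spectra vary along a single direction; y proportional to it
        t = rng.normal(size=30)
        v = rng.normal(size=10)
        X = np.outer(t, v)
        y = 2.0 * t
        model = fit_plsr(X, y, n_latent=1)
        pred = model.predict(X)
        ss_res = np.sum((pred - y) ** 2)
        assert 1 - ss_res / np.sum((y - y.mean()) ** 2) > 1 - 1e-10

    def test_full_rank_equals_least_squares(self, rng):
        # independent oracle: normal-equations solution on centered data
        X = rng.normal(size=(20, 5))
        y = rng.normal(size=20)
        model = fit_plsr(X, y, n_latent=5)
        Xc = X - X.mean(axis=0)
        beta = np.linalg.solve(Xc.T @ Xc, Xc.T @ (y - y.mean()))
        ols_pred = (X - X.mean(axis=0)) @ beta + y.mean()
        np.testing.assert_allclose(model.predict(X), ols_pred, atol=1e-8)

    def test_scores_mutually_orthogonal(self, rng):
        X = rng.normal(size=(25, 8))
        y = rng.normal(size=25)
        model = fit_plsr(X, y, n_latent=5)
        G = model.x_scores_.T @ model.x_scores_
        off = G - np.diag(np.diag(G))
        assert np.abs(off).max() < 1e-8

    def test_training_residual_nonincreasing_in_components(self, rng):
        X = rng.normal(size=(40, 12))
        y = X @ rng.normal(size=12) + 0.1 * rng.normal(size=40)
        rmses = []
        for nc in range(1, 9):
            model = fit_plsr(X, y, nc)
            rmses.append(np.sqrt(np.mean((model.predict(X) - y) ** 2)))
        assert all(b <= a + 1e-10 for a, b in zip(rmses, rmses[1:]))

    def test_excessive_components_rejected(self, rng):
        X = rng.normal(size=(10, 4))
        with pytest.raises(ValueError, match="n_components"):
            fit_plsr(X, rng.normal(size=10), n_latent=8)


class TestPLSDAThresholdRule:
    @pytest.mark.parametrize("pred,expected", [
        (1.2, 1), (2.4, 2), (0.2, 1), (13.7, 11),
        (1.5, 1), (2.5, 2),   # boundary k+0.5 assigned to the lower class
        (10.4, 10), (10.6, 11),
    ])
    def test_threshold_assignment(self, pred, expected):
        assert classify_plsda(None, np.array([pred]), n_classes=11)[0] == expected

    def test_separated_classes_fit_perfectly(self, rng):
        # classes 1..5 spaced along one spectral direction
        codes = np.repeat(np.arange(1, 6), 8)
        X = np.outer(codes, np.ones(12)) + 0.01 * rng.normal(size=(40, 12))
        model = PLSDAClassifier(n_components=1).fit(X, codes)
        assert np.mean(model.predict(X) == codes) == 1.0


class TestKNN:
    def test_345_triangle_distance_orders_neighbors(self):
        X_train = np.array([[3.0, 4.0], [1.0, 0.0]])
        y_train = np.array([10, 20])
        # query at origin: d=5 vs d=1 -> nearest is the second sample
        pred = knn_predict(X_train, y_train, np.array([[0.0, 0.0]]),
                           KNNConfig(k=1))
        assert pred[0] == 20

    def test_k3_regression_mean_of_nearest(self):
        X_train = np.array([[0.0], [1.0], [2.0], [50.0]])
        y_train = np.array([1.0, 2.0, 3.0, 100.0])
        pred = knn_predict(X_train, y_train, np.array([[1.0]]),
                           KNNConfig(k=3, task="regress"))
        assert pred[0] == pytest.approx(2.0)

    def test_matches_sklearn_on_generic_data(self, rng):
        X = rng.normal(size=(40, 6))
        y = rng.integers(1, 4, size=40)
        Xq = rng.normal(size=(15, 6))
        ours = KNNModel(k=5).fit(X, y).predict(Xq)
        theirs = KNeighborsClassifier(n_neighbors=5).fit(X, y).predict(Xq)
        np.testing.assert_array_equal(ours, theirs)

    def test_feature_permutation_and_shift_invariance(self, rng):
        X = rng.normal(size=(30, 8))
        y = rng.integers(1, 4, size=30)
        Xq = rng.normal(size=(10, 8))
        base = knn_predict(X, y, Xq, KNNConfig(k=3))
        perm = rng.permutation(8)
        np.testing.assert_array_equal(
            base, knn_predict(X[:, perm], y, Xq[:, perm], KNNConfig(k=3))
        )
        np.testing.assert_array_equal(
            base, knn_predict(X + 7.5, y, Xq + 7.5, KNNConfig(k=3))
        )

    def test_vote_tie_goes_to_smallest_class(self):
        X = np.array([[0.0], [2.0]])
        y = np.array([5, 2])
        # k=2: one vote each; the smaller class code wins
        pred = knn_predict(X, y, np.array([[1.0]]), KNNConfig(k=2))
        assert pred[0] == 2

    def test_equidistant_neighbors_lowest_index_first(self):
        X = np.array([[1.0], [-1.0], [1.0]])
        y = np.array([7, 8, 9])
        pred = knn_predict(X, y, np.array([[0.0]]), KNNConfig(k=1))
        assert pred[0] == 7  # index 0 beats the equidistant index 1 and 2

    def test_empty_or_overlarge_k_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            knn_predict(np.empty((0, 2)), np.empty(0), np.ones((1, 2)),
                        KNNConfig(k=1))
        with pytest.raises(ValueError, match="exceeds"):
            knn_predict(np.ones((2, 2)), np.ones(2), np.ones((1, 2)),
                        KNNConfig(k=5))


class TestGridSearchSVM:
    def _blobs(self, rng, n=30):
        X = np.vstack([
            rng.normal(0.0, 0.3, (n, 2)),
            rng.normal(5.0, 0.3, (n, 2)),
        ])
        y = np.array([1] * n + [2] * n)
        return X, y

    def test_separable_blobs_perfect_training_accuracy(self, rng):
        X, y = self._blobs(rng)
        model = svm_grid_search(X, y, c_grid=(0.1, 1, 10), g_grid=(0.01, 0.1, 1),
                                folds=3, task="classify", seed=0)
        assert np.mean(model.predict(X) == y) == 1.0

    def test_selection_matches_independent_cv_table(self, rng):
        # oracle: recompute the 3x3 CV-accuracy grid with sklearn directly
        X = rng.normal(size=(60, 4))
        y = rng.integers(1, 3, size=60)
        c_grid, g_grid = (0.5, 1.0, 2.0), (0.05, 0.2, 1.0)
        model = GridSearchSVM(c_grid, g_grid, folds=3, task="classify",
                              random_state=7).fit(X, y)
        skf = StratifiedKFold(3, shuffle=True, random_state=7)
        table = np.zeros((3, 3))
        for ic, c in enumerate(c_grid):
            for ig, g in enumerate(g_grid):
                hits = 0
                for tr, te in skf.split(X, y):
                    clf = SVC(C=c, gamma=g).fit(X[tr], y[tr])
                    hits += np.sum(clf.predict(X[te]) == y[te])
                table[ic, ig] = hits / len(y)
        best = np.unravel_index(np.argmax(table), table.shape)
        assert (model.c_, model.g_) == (c_grid[best[0]], g_grid[best[1]])
        np.testing.assert_allclose(model.cv_scores_, table)

    def test_deterministic_given_seed(self, rng):
        X, y = self._blobs(rng, n=20)
        kwargs = dict(c_grid=(0.5, 2.0), g_grid=(0.1, 1.0), folds=4,
                      task="classify")
        m1 = GridSearchSVM(random_state=3, **kwargs).fit(X, y)
        m2 = GridSearchSVM(random_state=3, **kwargs).fit(X, y)
        assert (m1.c_, m1.g_) == (m2.c_, m2.g_)
        np.testing.assert_array_equal(m1.predict(X), m2.predict(X))

    def test_regression_task_minimizes_rmse(self, rng):
        X = rng.uniform(-1, 1, (50, 3))
        y = X @ np.array([1.0, -2.0, 0.5]) + 0.01 * rng.normal(size=50)
        model = svm_grid_search(X, y, c_grid=(1.0, 10.0), g_grid=(0.1, 1.0),
                                folds=3, task="regress", seed=0)
        rmse = np.sqrt(np.mean((model.predict(X) - y) ** 2))
        assert rmse < 0.2

    def test_sparse_class_stratification_error(self, rng):
        X = rng.normal(size=(10, 2))
        y = np.array([1] * 9 + [2])
        with pytest.raises(ValueError, match="stratify"):
            GridSearchSVM(folds=5, task="classify").fit(X, y)
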