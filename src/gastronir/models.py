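"""Baseline chemometric model families.

Three classical families benchmarked against the 1D-CNN:

* PLSR and its discriminant variant PLS-DA.  PLS-DA regresses a single
  continuous response of integer class codes 1..K and assigns each
  prediction to the nearest code: a prediction in (k - 0.5, k + 0.5) maps
  to class k, the boundary k + 0.5 to the lower class k, and out-of-range
  predictions clip to [1, K].
* K-nearest neighbours with the Euclidean metric (majority vote /
  neighbour-mean).  Ties are deterministic: the smallest class code wins a
  vote tie and the lowest training index wins an equidistance tie.
* RBF-kernel SVM/SVR with an exhaustive c-g grid search scored by k-fold
  cross-validation (accuracy for classification, RMSE for regression);
  grid ties resolve to the smallest c, then the smallest g.

Latent-variable and k selection, where not fixed by the caller, use 5-fold
cross-validation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator, ClassifierMixin, RegressorMixin, clone
from sklearn.cross_decomposition import PLSRegression
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.svm import SVC, SVR
from sklearn.utils.validation import check_is_fitted, check_X_y, check_array

__all__ = [
    "PLSCalibration",
    "PLSDAClassifier",
    "fit_plsr",
    "classify_plsda",
    "KNNConfig",
    "KNNModel",
    "knn_predict",
    "GridSearchSVM",
    "svm_grid_search",
    "DEFAULT_CG_GRID",
]

DEFAULT_CG_GRID = tuple(2.0 ** k for k in range(-8, 9))


# ---------------------------------------------------------------------------
# PLS
# ---------------------------------------------------------------------------

class PLSCalibration(RegressorMixin, BaseEstimator):
    """PLS regression with optional CV selection of the component count.

    With ``n_components=None``, the count is chosen over
    ``1..max_components`` (bounded by ``min(n_samples - 1, n_features)``)
    by minimizing 5-fold CV RMSE.  ``scale=False`` keeps the model a pure
    mean-centered PLS so that a full-rank fit reproduces least squares.
    """

    def __init__(
        self,
        n_components: int | None = None,
        max_components: int = 20,
        cv: int = 5,
        random_state: int = 0,
    ):
        self.n_components = n_components
        self.max_components = max_components
        self.cv = cv
        self.random_state = random_state

    def _bound(self, n: int, p: int) -> int:
        return max(1, min(n - 1, p))

    def fit(self, X, y):
        X, y = check_X_y(X, y, y_numeric=True)
        bound = self._bound(*X.shape)
        if self.n_components is not None:
            if not 1 <= self.n_components <= bound:
                raise ValueError(
                    f"n_components must be in [1, {bound}], got {self.n_components}"
                )
            best = self.n_components
        else:
            candidates = range(1, min(self.max_components, bound) + 1)
            folds = KFold(self.cv, shuffle=True, random_state=self.random_state)
            best, best_rmse = 1, np.inf
            for nc in candidates:
                sq = 0.0
                ok = True
                for tr, te in folds.split(X):
                    if nc > self._bound(len(tr), X.shape[1]):
                        ok = False
                        break
                    m = PLSRegression(n_components=nc, scale=False).fit(X[tr], y[tr])
                    sq += float(np.sum((m.predict(X[te]).ravel() - y[te]) ** 2))
                if not ok:
                    break
                rmse = np.sqrt(sq / len(y))
                if rmse < best_rmse - 1e-12:
                    best, best_rmse = nc, rmse
        self.pls_ = PLSRegression(n_components=best, scale=False).fit(X, y)
        self.n_components_ = best
        self.x_scores_ = self.pls_.x_scores_
        return self

    def predict(self, X):
        check_is_fitted(self)
        return self.pls_.predict(check_array(X)).ravel()


def fit_plsr(X, y, n_latent: int) -> PLSCalibration:
    """Fit a PLS regression with a fixed number of latent variables."""
    return PLSCalibration(n_components=n_latent).fit(X, y)


class PLSDAClassifier(ClassifierMixin, BaseEstimator):
    """PLS discriminant analysis on integer-coded class labels.

    Classes are coded 1..K in sorted label order, the code regressed by
    PLS, and predictions assigned by the nearest-integer threshold rule
    described in the module docstring.
    """

    def __init__(
        self,
        n_components: int | None = None,
        max_components: int = 20,
        cv: int = 5,
        random_state: int = 0,
    ):
        self.n_components = n_components
        self.max_components = max_components
        self.cv = cv
        self.random_state = random_state

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        self.classes_ = np.unique(y)
        codes = np.searchsorted(self.classes_, y) + 1.0
        if self.n_components is not None:
            self.pls_ = PLSCalibration(n_components=self.n_components).fit(X, codes)
        else:
            # select the component count by CV classification accuracy
            bound = max(1, min(X.shape[0] - 1, X.shape[1]))
            folds = StratifiedKFold(
                self.cv, shuffle=True, random_state=self.random_state
            )
            best, best_acc = 1, -1.0
            for nc in range(1, min(self.max_components, bound) + 1):
                hits = 0
                ok = True
                for tr, te in folds.split(X, codes):
                    if nc > max(1, min(len(tr) - 1, X.shape[1])):
                        ok = False
                        break
                    m = PLSRegression(n_components=nc, scale=False).fit(
                        X[tr], codes[tr]
                    )
                    pred = _threshold_codes(
                        m.predict(X[te]).ravel(), len(self.classes_)
                    )
                    hits += int(np.sum(pred == codes[te]))
                if not ok:
                    break
                acc = hits / len(codes)
                if acc > best_acc + 1e-12:
                    best, best_acc = nc, acc
            self.pls_ = PLSCalibration(n_components=best).fit(X, codes)
        self.n_components_ = self.pls_.n_components_
        return self

    def decision_function(self, X):
        check_is_fitted(self)
        return self.pls_.predict(X)

    def predict(self, X):
        codes = _threshold_codes(self.decision_function(X), len(self.classes_))
        return self.classes_[codes.astype(int) - 1]


def _threshold_codes(y_pred: np.ndarray, n_classes: int) -> np.ndarray:
    """Nearest-integer assignment with boundary k+0.5 -> k and clipping."""
    codes = np.ceil(np.asarray(y_pred, dtype=float) - 0.5)
    return np.clip(codes, 1, n_classes)


def classify_plsda(model, X, n_classes: int) -> np.ndarray:
    """Threshold-rule class codes (1..n_classes) from a fitted PLS model."""
    y_pred = model.predict(X) if hasattr(model, "predict") else np.asarray(X)
    return _threshold_codes(np.asarray(y_pred).ravel(), n_classes).astype(int)


# ---------------------------------------------------------------------------
# KNN
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KNNConfig:
    """Neighbour count and task; k defaults to 3 (odd for vote stability)."""

    k: int = 3
    task: str = "classify"

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.task not in ("classify", "regress"):
            raise ValueError("task must be 'classify' or 'regress'")


class KNNModel(BaseEstimator):
    """Euclidean k-nearest-neighbour classifier/regressor.

    Implemented directly on the pairwise-distance matrix so the
    deterministic tie rules (lowest training index among equidistant
    neighbours, smallest class code on a split vote) hold exactly.  With
    ``k=None`` the neighbour count is selected by 5-fold CV over odd
    k in 1..15.
    """

    def __init__(
        self,
        k: int | None = 3,
        task: str = "classify",
        cv: int = 5,
        random_state: int = 0,
    ):
        self.k = k
        self.task = task
        self.cv = cv
        self.random_state = random_state

    def fit(self, X, y):
        X, y = check_X_y(X, y, y_numeric=self.task == "regress")
        self.X_ = X
        self.y_ = y
        if self.task == "classify":
            self.classes_ = np.unique(y)
        if self.k is not None:
            KNNConfig(self.k, self.task)
            if self.k > len(y):
                raise ValueError(f"k={self.k} exceeds n_train={len(y)}")
            self.k_ = self.k
        else:
            self.k_ = self._select_k(X, y)
        return self

    def _select_k(self, X, y) -> int:
        splitter = (
            StratifiedKFold(self.cv, shuffle=True, random_state=self.random_state)
            if self.task == "classify"
            else KFold(self.cv, shuffle=True, random_state=self.random_state)
        )
        best_k, best_score = 1, -np.inf
        for k in range(1, 16, 2):
            scores = []
            for tr, te in splitter.split(X, y):
                if k > len(tr):
                    continue
                pred = _knn_raw(X[tr], y[tr], X[te], k, self.task)
                if self.task == "classify":
                    scores.append(np.mean(pred == y[te]))
                else:
                    scores.append(-np.sqrt(np.mean((pred - y[te]) ** 2)))
            score = float(np.mean(scores))
            if score > best_score + 1e-12:
                best_k, best_score = k, score
        return best_k

    def predict(self, X):
        check_is_fitted(self)
        return _knn_raw(self.X_, self.y_, check_array(X), self.k_, self.task)


def _knn_raw(X_train, y_train, X_query, k: int, task: str) -> np.ndarray:
    dist = cdist(np.asarray(X_query, float), np.asarray(X_train, float))
    # stable sort keeps the lowest training index first among equidistant rows
    order = np.argsort(dist, axis=1, kind="stable")[:, :k]
    neigh_y = np.asarray(y_train)[order]
    if task == "regress":
        return neigh_y.mean(axis=1)
    classes = np.unique(y_train)
    votes = (neigh_y[:, :, None] == classes[None, None, :]).sum(axis=1)
    return classes[np.argmax(votes, axis=1)]  # argmax -> smallest class on ties


def knn_predict(X_train, y_train, X_query, cfg: KNNConfig) -> np.ndarray:
    """Predict labels (majority vote) or values (neighbour mean) per config."""
    X_train = np.asarray(X_train, float)
    if X_train.shape[0] == 0:
        raise ValueError("empty training set")
    if cfg.k > X_train.shape[0]:
        raise ValueError(f"k={cfg.k} exceeds n_train={X_train.shape[0]}")
    return _knn_raw(X_train, y_train, X_query, cfg.k, cfg.task)


# ---------------------------------------------------------------------------
# SVM / SVR
# ---------------------------------------------------------------------------

class GridSearchSVM(BaseEstimator):
    """RBF SVM/SVR with exhaustive, seeded c-g grid search.

    Every (c, g) pair is scored by k-fold cross-validation — accuracy for
    classification (stratified folds), RMSE for regression — and the model
    is refit on all data at the winning pair.  A tie selects the smallest
    c, then the smallest g.
    """

    def __init__(
        self,
        c_grid=DEFAULT_CG_GRID,
        g_grid=DEFAULT_CG_GRID,
        folds: int = 5,
        task: str = "classify",
        epsilon: float = 0.1,
        random_state: int = 0,
    ):
        self.c_grid = c_grid
        self.g_grid = g_grid
        self.folds = folds
        self.task = task
        self.epsilon = epsilon
        self.random_state = random_state

    def _base(self, c: float, g: float):
        if self.task == "classify":
            return SVC(C=c, gamma=g, kernel="rbf")
        if self.task == "regress":
            return SVR(C=c, gamma=g, kernel="rbf", epsilon=self.epsilon)
        raise ValueError("task must be 'classify' or 'regress'")

    def fit(self, X, y):
        X, y = check_X_y(X, y, y_numeric=self.task == "regress")
        if len(tuple(self.c_grid)) == 0 or len(tuple(self.g_grid)) == 0:
            raise ValueError("grids must be non-empty")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if self.task == "classify":
            _, counts = np.unique(y, return_counts=True)
            if counts.min() < self.folds:
                raise ValueError(
                    "a class has fewer samples than folds; cannot stratify"
                )
            splitter = StratifiedKFold(
                self.folds, shuffle=True, random_state=self.random_state
            )
        else:
            splitter = KFold(self.folds, shuffle=True, random_state=self.random_state)
        fold_pairs = list(splitter.split(X, y if self.task == "classify" else None))
        best = None
        scores = np.empty((len(tuple(self.c_grid)), len(tuple(self.g_grid))))
        for ic, c in enumerate(self.c_grid):
            for ig, g in enumerate(self.g_grid):
                if self.task == "classify":
                    hits = 0
                    for tr, te in fold_pairs:
                        m = self._base(c, g).fit(X[tr], y[tr])
                        hits += int(np.sum(m.predict(X[te]) == y[te]))
                    score = hits / len(y)
                else:
                    sq = 0.0
                    for tr, te in fold_pairs:
                        m = self._base(c, g).fit(X[tr], y[tr])
                        sq += float(np.sum((m.predict(X[te]) - y[te]) ** 2))
                    score = -np.sqrt(sq / len(y))
                scores[ic, ig] = score
                if best is None or score > best[0] + 1e-12:
                    best = (score, c, g)  # strict improvement keeps smallest c, g
        self.cv_scores_ = scores
        self.best_score_, self.c_, self.g_ = best
        self.model_ = self._base(self.c_, self.g_).fit(X, y)
        if self.task == "classify":
            self.classes_ = self.model_.classes_
        return self

    def predict(self, X):
        check_is_fitted(self)
        return self.model_.predict(check_array(X))


def svm_grid_search(
    X,
    y,
    c_grid=DEFAULT_CG_GRID,
    g_grid=DEFAULT_CG_GRID,
    folds: int = 5,
    task: str = "classify",
    seed: int = 0,
) -> GridSearchSVM:
    """Fit the grid-searched RBF SVM/SVR and return the estimator."""
    return GridSearchSVM(
        c_grid=c_grid, g_grid=g_grid, folds=folds, task=task, random_state=seed
    ).fit(X, y)
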