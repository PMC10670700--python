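"""Deterministic SPXY and Kennard-Stone train/test partitioning.

SPXY (sample-set partitioning based on the joint x-y distance) runs the
Kennard-Stone max-min accumulation on

    d_xy(i, j) = d_x(i, j) / max d_x + d_y(i, j) / max d_y

with Euclidean distances on the feature matrix and on the response.  The
two mutually most distant samples seed the selection; the selected set
becomes the training set and the remainder the test set.  Plain
Kennard-Stone is the special case with no response term.  All ties break
toward the lowest candidate index, so the procedure is fully
deterministic — no RNG is involved.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import squareform, pdist
from sklearn.base import BaseEstimator

__all__ = ["Split", "spxy_split", "ks_split", "SPXYSplitter"]


@dataclass(frozen=True)
class Split:
    """Disjoint train/test index partition covering all samples."""

    train_indices: tuple[int, ...]
    test_indices: tuple[int, ...]

    def __post_init__(self) -> None:
        train, test = set(self.train_indices), set(self.test_indices)
        if train & test:
            raise ValueError("train and test indices overlap")
        n = len(self.train_indices) + len(self.test_indices)
        if (train | test) != set(range(n)):
            raise ValueError("train and test must partition range(n)")

    @property
    def n_samples(self) -> int:
        return len(self.train_indices) + len(self.test_indices)


def _joint_distance(X: np.ndarray, y: np.ndarray | None) -> np.ndarray:
    D = squareform(pdist(X, metric="euclidean"))
    dx_max = D.max()
    if y is None:
        if dx_max == 0:
            raise ValueError("all samples identical; cannot partition")
        return D / dx_max
    Dy = squareform(pdist(y.reshape(len(y), -1), metric="euclidean"))
    dy_max = Dy.max()
    if dx_max == 0 and dy_max == 0:
        raise ValueError("all samples identical in X and y; cannot partition")
    # degenerate term vanishes: fall back to the informative distance alone
    out = np.zeros_like(D)
    if dx_max > 0:
        out += D / dx_max
    if dy_max > 0:
        out += Dy / dy_max
    return out


def _kennard_stone_select(D: np.ndarray, n_select: int) -> list[int]:
    """Greedy max-min selection on a distance matrix; lowest index wins ties."""
    n = D.shape[0]
    # seed: the mutually most distant pair, lexicographically first on ties
    flat = np.argmax(D)  # row-major argmax -> lowest (i, j) on ties
    i, j = divmod(int(flat), n)
    selected = [min(i, j), max(i, j)] if n_select >= 2 else [min(i, j)]
    min_dist = np.minimum(D[selected[0]], D[selected[-1]])
    min_dist[selected] = -np.inf
    while len(selected) < n_select:
        nxt = int(np.argmax(min_dist))  # argmax returns first max -> lowest index
        selected.append(nxt)
        min_dist = np.minimum(min_dist, D[nxt])
        min_dist[nxt] = -np.inf
    return selected


def _train_size(n: int, test_fraction: float) -> int:
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    return int(np.floor(n * (1.0 - test_fraction) + 0.5))


def spxy_split(
    X: np.ndarray, y: np.ndarray | None, test_fraction: float = 0.25
) -> Split:
    """SPXY partition of ``X`` (and response ``y``) into train/test.

    ``train = round(n * (1 - test_fraction))`` samples are accumulated by
    Kennard-Stone on the joint x-y distance; the study's 3:1 ratio on 240
    samples yields 180 training and 60 test samples.  ``y`` may be a
    continuous response or integer class codes; with ``y=None`` (or a
    constant y) this reduces to plain Kennard-Stone.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 3:
        raise ValueError("need a 2-D X with at least 3 samples")
    n = X.shape[0]
    if y is not None:
        y = np.asarray(y, dtype=float)
        if y.shape[0] != n:
            raise ValueError("y must align with X rows")
    n_train = _train_size(n, test_fraction)
    if not 2 <= n_train <= n - 1:
        raise ValueError(
            f"train size {n_train} out of range for n={n}; adjust test_fraction"
        )
    D = _joint_distance(X, y)
    selected = _kennard_stone_select(D, n_train)
    train = tuple(sorted(selected))
    test = tuple(i for i in range(n) if i not in set(train))
    return Split(train_indices=train, test_indices=test)


def ks_split(X: np.ndarray, test_fraction: float = 0.25) -> Split:
    """Plain Kennard-Stone partition (feature-space distance only)."""
    return spxy_split(X, None, test_fraction)


class SPXYSplitter(BaseEstimator):
    """Single-split cross-validator wrapping :func:`spxy_split`.

    Yields exactly one (train, test) pair, making the deterministic SPXY
    partition usable wherever scikit-learn expects a CV splitter.
    """

    def __init__(self, test_fraction: float = 0.25, use_y: bool = True):
        self.test_fraction = test_fraction
        self.use_y = use_y

    def split(self, X, y=None, groups=None):
        yy = y if (self.use_y and y is not None) else None
        s = spxy_split(np.asarray(X), None if yy is None else np.asarray(yy),
                       self.test_fraction)
        yield np.array(s.train_indices), np.array(s.test_indices)

    def get_n_splits(self, X=None, y=None, groups=None) -> int:
        return 1
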