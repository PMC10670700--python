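"""Training-set spectral augmentation: random offset, multiplicative and
slope effects.

Each original spectrum is retained and followed by ``factor - 1`` perturbed
copies

    x'(lambda) = x(lambda) * beta * r(lambda) + delta

with ``beta ~ U(mult_range)``, ``delta ~ U(-c*m, +c*m)`` where ``m`` is the
spectrum's own mean and ``c`` the offset coefficient (default 0.1), and
``r`` a linear ramp from 1 at the first wavelength to ``s ~ U(slope_range)``
at the last.  The defaults (offset 0.1 x mean, both ranges [0.95, 1.05],
factor 8) expand a 180-spectrum training set to 1440 spectra.  These
perturbations emulate instrument offset/scatter variation, so reference
contents of a perturbed copy equal the parent sample's contents.  Only the
training set is ever augmented.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from .spectra import SpectrumSet

__all__ = ["AugmentConfig", "SpectralAugmenter", "augment_spectra", "augment_matrix"]


@dataclass(frozen=True)
class AugmentConfig:
    """Augmentation settings; ``factor`` counts total copies per original."""

    factor: int = 8
    offset_coeff: float = 0.1
    mult_range: tuple[float, float] = (0.95, 1.05)
    slope_range: tuple[float, float] = (0.95, 1.05)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.factor < 1:
            raise ValueError(f"factor must be >= 1, got {self.factor}")
        if self.offset_coeff < 0:
            raise ValueError("offset_coeff must be >= 0")
        for name, (lo, hi) in (
            ("mult_range", self.mult_range),
            ("slope_range", self.slope_range),
        ):
            if lo > hi:
                raise ValueError(f"{name} must be a non-empty interval")
            if lo != hi and not lo <= 1.0 <= hi:
                raise ValueError(f"{name} must contain 1")


def augment_matrix(
    X: np.ndarray, cfg: AugmentConfig, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Augment a plain matrix; returns ``(X_aug, parent_index)``.

    Row order is each original immediately followed by its ``factor - 1``
    perturbed copies; ``parent_index[k]`` maps augmented row ``k`` back to
    its source row, so labels or reference values replicate as
    ``y[parent_index]``.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] == 0:
        raise ValueError("need a non-empty 2-D matrix")
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    n, p = X.shape
    ramp_base = np.linspace(0.0, 1.0, p)
    rows = np.empty((n * cfg.factor, p))
    parent = np.empty(n * cfg.factor, dtype=int)
    k = 0
    for i in range(n):
        rows[k] = X[i]
        parent[k] = i
        k += 1
        mean_i = X[i].mean()
        for _ in range(cfg.factor - 1):
            beta = rng.uniform(*cfg.mult_range)
            slope = rng.uniform(*cfg.slope_range)
            delta = rng.uniform(-cfg.offset_coeff * mean_i, cfg.offset_coeff * mean_i) \
                if cfg.offset_coeff > 0 else 0.0
            ramp = 1.0 + (slope - 1.0) * ramp_base
            rows[k] = X[i] * beta * ramp + delta
            parent[k] = i
            k += 1
    return rows, parent


def augment_spectra(spectra: SpectrumSet, cfg: AugmentConfig) -> SpectrumSet:
    """Augment a :class:`SpectrumSet`; copies get ``_a<k>`` id suffixes."""
    X_aug, parent = augment_matrix(spectra.absorbance, cfg)
    ids = []
    counter: dict[int, int] = {}
    for p in parent:
        c = counter.get(p, 0)
        ids.append(spectra.sample_ids[p] if c == 0 else f"{spectra.sample_ids[p]}_a{c}")
        counter[p] = c + 1
    labels = (
        None
        if spectra.origin_labels is None
        else [spectra.origin_labels[p] for p in parent]
    )
    return SpectrumSet(
        grid=spectra.grid, absorbance=X_aug, sample_ids=ids, origin_labels=labels
    )


class SpectralAugmenter(BaseEstimator):
    """Estimator-style interface over :func:`augment_matrix`.

    ``fit`` is a no-op; ``augment(X, y)`` returns the expanded matrix with
    targets replicated from each copy's parent sample.
    """

    def __init__(
        self,
        factor: int = 8,
        offset_coeff: float = 0.1,
        mult_range: tuple[float, float] = (0.95, 1.05),
        slope_range: tuple[float, float] = (0.95, 1.05),
        random_state: int = 0,
    ):
        self.factor = factor
        self.offset_coeff = offset_coeff
        self.mult_range = mult_range
        self.slope_range = slope_range
        self.random_state = random_state

    def _config(self) -> AugmentConfig:
        return AugmentConfig(
            factor=self.factor,
            offset_coeff=self.offset_coeff,
            mult_range=tuple(self.mult_range),
            slope_range=tuple(self.slope_range),
            seed=self.random_state,
        )

    def fit(self, X, y=None):
        self._config()  # validate
        self.n_features_in_ = np.asarray(X).shape[1]
        return self

    def augment(self, X, y=None):
        X_aug, parent = augment_matrix(X, self._config())
        if y is None:
            return X_aug, None
        y = np.asarray(y)
        return X_aug, y[parent]
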