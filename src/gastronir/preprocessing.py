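"""Spectral pre-treatments: Savitzky-Golay second derivative and row-wise
normalization, composable in that fixed order.

The second derivative (SD) removes baseline offset and slope and sharpens
overlapping absorption bands; normalization removes residual multiplicative
scatter.  Both are exposed as scikit-learn transformers operating on plain
matrices and as functions operating on :class:`~gastronir.spectra.SpectrumSet`.

The derivative is computed in per-index units (grid-step-agnostic); all
downstream models are scale-invariant after normalization, so physical
nm^-2 scaling is unnecessary.  With edge trimming, an n-point spectrum
yields ``n - (window - 1)`` features, which takes the instrument's 1050
recorded wavelengths to the 1030 features the network consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import savgol_filter
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .spectra import SpectrumSet, WavelengthGrid

__all__ = [
    "PreprocessConfig",
    "SavitzkyGolayDerivative",
    "RowNormalizer",
    "second_derivative",
    "normalize",
    "apply_pipeline",
    "DegenerateRowError",
]

NORM_METHODS = ("minmax", "snv", "none")


class DegenerateRowError(ValueError):
    """A constant spectrum cannot be normalized."""

    def __init__(self, message: str, rows: list[int] | None = None):
        super().__init__(message)
        self.rows = rows or []


@dataclass(frozen=True)
class PreprocessConfig:
    """SD + normalization settings.

    sd_window must be odd and larger than sd_polyorder (>= 2, since a
    second derivative needs at least a quadratic fit).
    """

    sd_window: int = 21
    sd_polyorder: int = 3
    sd_trim_edges: bool = True
    norm_method: str = "minmax"

    def __post_init__(self) -> None:
        if self.sd_window % 2 == 0 or self.sd_window <= self.sd_polyorder:
            raise ValueError(
                f"sd_window must be odd and > sd_polyorder, got "
                f"window={self.sd_window}, polyorder={self.sd_polyorder}"
            )
        if self.sd_polyorder < 2:
            raise ValueError("sd_polyorder must be >= 2 for a second derivative")
        if self.norm_method not in NORM_METHODS:
            raise ValueError(f"norm_method must be one of {NORM_METHODS}")


class SavitzkyGolayDerivative(TransformerMixin, BaseEstimator):
    """Row-wise smoothed second derivative.

    Parameters
    ----------
    window : odd filter length in points (default 21)
    polyorder : local polynomial order (default 3)
    trim_edges : drop (window-1)/2 points at each end where the filter
        relies on edge extrapolation (default True)
    """

    def __init__(self, window: int = 21, polyorder: int = 3, trim_edges: bool = True):
        self.window = window
        self.polyorder = polyorder
        self.trim_edges = trim_edges

    def fit(self, X, y=None):
        X = check_array(X)
        PreprocessConfig(self.window, self.polyorder, self.trim_edges)
        if self.window >= X.shape[1]:
            raise ValueError(
                f"window {self.window} must be smaller than the number of "
                f"wavelength points {X.shape[1]}"
            )
        self.n_features_in_ = X.shape[1]
        half = (self.window - 1) // 2
        self.n_features_out_ = X.shape[1] - 2 * half if self.trim_edges else X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self)
        X = check_array(X)
        out = savgol_filter(
            X, self.window, self.polyorder, deriv=2, delta=1.0, axis=1, mode="interp"
        )
        if self.trim_edges:
            half = (self.window - 1) // 2
            out = out[:, half : X.shape[1] - half]
        return out


class RowNormalizer(TransformerMixin, BaseEstimator):
    """Per-spectrum normalization.

    ``minmax`` maps each row affinely onto [0, 1]; ``snv`` (standard normal
    variate) centers each row to mean 0 and scales to unit sample (n-1)
    standard deviation; ``none`` is the identity.
    """

    def __init__(self, method: str = "minmax"):
        self.method = method

    def fit(self, X, y=None):
        if self.method not in NORM_METHODS:
            raise ValueError(f"method must be one of {NORM_METHODS}")
        X = check_array(X)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self)
        X = check_array(X)
        if self.method == "none":
            return X.copy()
        if self.method == "minmax":
            lo = X.min(axis=1, keepdims=True)
            hi = X.max(axis=1, keepdims=True)
            span = hi - lo
            self._raise_degenerate(span[:, 0] == 0)
            return (X - lo) / span
        mean = X.mean(axis=1, keepdims=True)
        std = X.std(axis=1, ddof=1, keepdims=True)
        self._raise_degenerate(std[:, 0] == 0)
        return (X - mean) / std

    @staticmethod
    def _raise_degenerate(mask) -> None:
        if mask.any():
            rows = np.flatnonzero(mask).tolist()
            raise DegenerateRowError(
                f"constant spectrum cannot be normalized (rows {rows})", rows=rows
            )


def _trimmed_grid(grid: WavelengthGrid, window: int) -> WavelengthGrid:
    half = (window - 1) // 2
    return WavelengthGrid(
        start_nm=grid.start_nm + half * grid.step_nm,
        step_nm=grid.step_nm,
        n_points=grid.n_points - 2 * half,
    )


def second_derivative(spectra: SpectrumSet, cfg: PreprocessConfig) -> SpectrumSet:
    """Savitzky-Golay second derivative of every spectrum."""
    sd = SavitzkyGolayDerivative(cfg.sd_window, cfg.sd_polyorder, cfg.sd_trim_edges)
    matrix = sd.fit(spectra.absorbance).transform(spectra.absorbance)
    grid = (
        _trimmed_grid(spectra.grid, cfg.sd_window)
        if cfg.sd_trim_edges
        else spectra.grid
    )
    return spectra.with_matrix(matrix, grid)


def normalize(spectra: SpectrumSet, method: str = "minmax") -> SpectrumSet:
    """Row-wise normalization; errors name the offending sample."""
    norm = RowNormalizer(method)
    try:
        matrix = norm.fit(spectra.absorbance).transform(spectra.absorbance)
    except DegenerateRowError as exc:
        names = [spectra.sample_ids[r] for r in exc.rows]
        raise DegenerateRowError(
            f"constant spectrum cannot be normalized (samples {names})",
            rows=exc.rows,
        ) from None
    return spectra.with_matrix(matrix)


def apply_pipeline(spectra: SpectrumSet, cfg: PreprocessConfig) -> SpectrumSet:
    """Second derivative followed by normalization (the study's SD+Norm order)."""
    out = second_derivative(spectra, cfg)
    if cfg.norm_method != "none":
        out = normalize(out, cfg.norm_method)
    return out
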