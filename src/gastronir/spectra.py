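"""Core spectral containers and CSV I/O.

A :class:`SpectrumSet` couples an absorbance matrix (samples x wavelengths)
with its :class:`WavelengthGrid` and sample identifiers, and is the X side of
every model in this package.  Spectra are exchanged as wide-format CSV:
``sample_id`` column, optional ``origin`` column, then one numeric column per
wavelength in nm.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "WavelengthGrid",
    "SpectrumSet",
    "SpectraFormatError",
    "read_spectra_csv",
    "write_spectra_csv",
    "average_replicates",
]

ID_COLUMN = "sample_id"
ORIGIN_COLUMN = "origin"


class SpectraFormatError(ValueError):
    """Raised when a spectra CSV violates the wide-format dialect."""


@dataclass(frozen=True)
class WavelengthGrid:
    """Evenly spaced wavelength axis in nanometres.

    The instrument used in the source study samples 400-2500 nm every 2 nm;
    nothing in the package assumes a particular point count, so other grids
    are equally valid.
    """

    start_nm: float
    step_nm: float
    n_points: int

    def __post_init__(self) -> None:
        if self.step_nm <= 0:
            raise ValueError(f"step_nm must be positive, got {self.step_nm}")
        if self.n_points < 2:
            raise ValueError(f"n_points must be >= 2, got {self.n_points}")

    @property
    def wavelengths(self) -> np.ndarray:
        return self.start_nm + self.step_nm * np.arange(self.n_points)

    @property
    def stop_nm(self) -> float:
        return self.start_nm + self.step_nm * (self.n_points - 1)

    def index_of(self, wavelength_nm: float) -> int:
        """Index of the grid point nearest to ``wavelength_nm``."""
        return int(np.argmin(np.abs(self.wavelengths - wavelength_nm)))


DEFAULT_GRID = WavelengthGrid(start_nm=400.0, step_nm=2.0, n_points=1050)


@dataclass
class SpectrumSet:
    """Absorbance spectra on a shared wavelength grid.

    Parameters
    ----------
    grid : WavelengthGrid
    absorbance : ndarray of shape (n_samples, grid.n_points)
    sample_ids : sequence of unique identifiers
    origin_labels : optional sequence of origin codes aligned with rows
    """

    grid: WavelengthGrid
    absorbance: np.ndarray
    sample_ids: list[str] = field(default_factory=list)
    origin_labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.absorbance.ndim != 2:
            raise ValueError("absorbance must be a 2-D matrix")
        if self.absorbance.shape[1] != self.grid.n_points:
            raise ValueError(
                f"matrix width {self.absorbance.shape[1]} != grid n_points "
                f"{self.grid.n_points}"
            )
        if not np.all(np.isfinite(self.absorbance)):
            raise ValueError("absorbance contains non-finite values")
        self.sample_ids = [str(s) for s in self.sample_ids]
        if len(self.sample_ids) != self.absorbance.shape[0]:
            raise ValueError("sample_ids length must match number of rows")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("sample_ids must be unique")
        if self.origin_labels is not None:
            self.origin_labels = [str(s) for s in self.origin_labels]
            if len(self.origin_labels) != self.absorbance.shape[0]:
                raise ValueError("origin_labels must align one-to-one with rows")

    @property
    def n_samples(self) -> int:
        return self.absorbance.shape[0]

    def select(self, indices: Sequence[int]) -> "SpectrumSet":
        """Row subset preserving order of ``indices``."""
        idx = list(indices)
        return SpectrumSet(
            grid=self.grid,
            absorbance=self.absorbance[idx],
            sample_ids=[self.sample_ids[i] for i in idx],
            origin_labels=None
            if self.origin_labels is None
            else [self.origin_labels[i] for i in idx],
        )

    def with_matrix(self, matrix: np.ndarray, grid: WavelengthGrid | None = None) -> "SpectrumSet":
        return replace(self, absorbance=matrix, grid=grid or self.grid)


def read_spectra_csv(path) -> SpectrumSet:
    """Read a wide-format spectra CSV into a :class:`SpectrumSet`.

    Header must be ``sample_id[,origin],<wl0>,<wl1>,...`` with strictly
    increasing, evenly spaced numeric wavelength headers.  Row order is
    preserved.
    """
    frame = pd.read_csv(path, dtype={0: str}, float_precision="round_trip")
    if frame.shape[1] < 3 or frame.columns[0] != ID_COLUMN:
        raise SpectraFormatError(
            f"expected '{ID_COLUMN}' first column followed by wavelength columns"
        )
    has_origin = frame.shape[1] > 1 and frame.columns[1] == ORIGIN_COLUMN
    wl_cols = list(frame.columns[2 if has_origin else 1 :])
    try:
        wavelengths = np.array([float(c) for c in wl_cols])
    except ValueError as exc:
        raise SpectraFormatError(f"non-numeric wavelength header: {exc}") from None
    if len(wavelengths) < 2:
        raise SpectraFormatError("need at least two wavelength columns")
    steps = np.diff(wavelengths)
    if np.any(steps <= 0):
        raise SpectraFormatError("wavelength headers must be strictly increasing")
    if not np.allclose(steps, steps[0], rtol=1e-9, atol=1e-9):
        raise SpectraFormatError("wavelength headers must be evenly spaced")
    values = frame[wl_cols].apply(pd.to_numeric, errors="coerce")
    bad = values.isna() & frame[wl_cols].notna() | frame[wl_cols].isna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise SpectraFormatError(
            f"non-numeric absorbance at row {r} (sample "
            f"{frame[ID_COLUMN].iloc[r]!r}), wavelength column {wl_cols[c]!r}"
        )
    grid = WavelengthGrid(float(wavelengths[0]), float(steps[0]), len(wavelengths))
    return SpectrumSet(
        grid=grid,
        absorbance=values.to_numpy(dtype=float),
        sample_ids=list(frame[ID_COLUMN]),
        origin_labels=list(frame[ORIGIN_COLUMN]) if has_origin else None,
    )


def write_spectra_csv(spectra: SpectrumSet, path, float_format: str = "%.8g") -> None:
    """Write the wide-format CSV read back by :func:`read_spectra_csv`."""
    cols = {ID_COLUMN: spectra.sample_ids}
    if spectra.origin_labels is not None:
        cols[ORIGIN_COLUMN] = spectra.origin_labels
    frame = pd.DataFrame(cols)
    wl = spectra.grid.wavelengths
    spec_frame = pd.DataFrame(
        spectra.absorbance, columns=[format(w, "g") for w in wl], index=frame.index
    )
    pd.concat([frame, spec_frame], axis=1).to_csv(
        path, index=False, float_format=float_format
    )


def average_replicates(
    spectra: SpectrumSet, replicate_groups: Mapping[str, Sequence[int]]
) -> SpectrumSet:
    """Average replicate measurements into one spectrum per sample.

    Each entry of ``replicate_groups`` maps an output sample id to the row
    indices of its replicate scans; the scan protocol in the source study
    measured each sample three times and used the mean.  Groups must be
    non-empty and disjoint.
    """
    seen: set[int] = set()
    rows = []
    ids = []
    labels: list[str] | None = [] if spectra.origin_labels is not None else None
    for gid, members in replicate_groups.items():
        members = list(members)
        if not members:
            raise ValueError(f"replicate group {gid!r} is empty")
        for m in members:
            if not 0 <= m < spectra.n_samples:
                raise IndexError(f"group {gid!r} references missing row {m}")
            if m in seen:
                raise ValueError(f"row {m} appears in more than one group")
            seen.add(m)
        rows.append(spectra.absorbance[members].mean(axis=0))
        ids.append(str(gid))
        if labels is not None:
            member_labels = {spectra.origin_labels[m] for m in members}
            if len(member_labels) > 1:
                raise ValueError(f"group {gid!r} mixes origins {sorted(member_labels)}")
            labels.append(member_labels.pop())
    return SpectrumSet(
        grid=spectra.grid,
        absorbance=np.array(rows),
        sample_ids=ids,
        origin_labels=labels,
    )
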