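"""Synthetic origin-structured Vis-NIR datasets.

The raw spectra behind the source study are not deposited, so this module
generates datasets with the statistical structure the analysis assumes:

* eleven origins with the published per-origin batch counts (240 samples
  in total) and per-origin mean contents of the six measured phenolics;
* Beer-Lambert mixing — absorbance is the concentration-weighted sum of
  pure-component absorptivity spectra, each a sum of Gaussian bands
  anchored at the O-H/C-H/N-H overtone positions seen in real spectra
  (~980, 1180, 1420-1440, 1500-1600, 1940, 2150 and 2350 nm);
* origin-level background constituents (water, polysaccharide, visible
  pigment) whose mean levels differ by origin — the overtone bands of
  these matrix constituents survive derivative preprocessing and carry
  the origin signature alongside composition, mirroring real spectra that
  overlap tightly yet differ subtly in absorption intensity;
* per-origin smooth baseline offset/slope, per-replicate scatter
  (random offset and tilt) and white instrument noise, with three
  replicate scans per sample.

Concentrations are truncated-at-zero normals around the origin means with
a configurable within-origin CV (default 15%).  Everything derives from a
single seed.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .contents import MEASURED_COMPONENTS, ContentTable, derive_composites
from .spectra import DEFAULT_GRID, SpectrumSet, WavelengthGrid
import pandas as pd

__all__ = [
    "OriginSpec",
    "SyntheticConfig",
    "SyntheticDataset",
    "component_spectra",
    "sample_concentrations",
    "generate_dataset",
    "DEFAULT_ORIGINS",
    "COMPONENT_BANDS",
    "MATRIX_BANDS",
]

Band = tuple[float, float, float]  # (center nm, width nm, amplitude weight)

# Component band patterns: centers sit at the observed overtone positions;
# the weight patterns are pairwise distinct so the mixture is identifiable.
COMPONENT_BANDS: Mapping[str, tuple[Band, ...]] = {
    "GA": ((980, 30, 0.020), (1430, 40, 0.030), (2350, 35, 0.018)),
    "HA": ((980, 28, 0.028), (1550, 45, 0.022), (2350, 30, 0.012)),
    "PE": ((1180, 35, 0.025), (1430, 45, 0.018), (2150, 40, 0.022)),
    "PB": ((1180, 32, 0.016), (1550, 42, 0.028), (2350, 38, 0.020)),
    "PC": ((980, 26, 0.035), (1180, 30, 0.020), (2150, 36, 0.028)),
    "PA": ((1430, 38, 0.014), (1550, 40, 0.016), (2150, 38, 0.018), (2350, 36, 0.014)),
}

# Background matrix constituents (arbitrary concentration units ~6-18).
MATRIX_BANDS: Mapping[str, tuple[Band, ...]] = {
    "water": ((1430, 70, 0.012), (1940, 85, 0.020)),
    "starch": ((1180, 60, 0.010), (2100, 70, 0.012), (2280, 55, 0.008)),
    "pigment": ((520, 80, 0.015), (660, 110, 0.010)),
}

MATRIX_NAMES = tuple(MATRIX_BANDS)


@dataclass(frozen=True)
class OriginSpec:
    """One origin: sample count, mean contents (mg/g, in the order GA, HA,
    PE, PB, PC, PA), matrix constituent levels and baseline shape."""

    code: str
    n_samples: int
    component_means: tuple[float, ...]
    matrix_levels: tuple[float, ...]  # water, starch, pigment
    baseline_offset: float = 0.0
    baseline_slope: float = 0.0

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError(f"origin {self.code}: n_samples must be >= 1")
        if len(self.component_means) != len(MEASURED_COMPONENTS):
            raise ValueError(f"origin {self.code}: need 6 component means")
        if any(m <= 0 for m in self.component_means):
            raise ValueError(f"origin {self.code}: component means must be > 0")
        if any(m < 0 for m in self.matrix_levels):
            raise ValueError(f"origin {self.code}: matrix levels must be >= 0")


def _default_origins() -> tuple[OriginSpec, ...]:
    # (code, batches, GA, HA, PE, PB, PC, PA) — published per-origin values
    rows = [
        ("DJ", 25, 4.7040, 1.1842, 2.6924, 3.9674, 1.5170, 10.3782),
        ("DAF", 40, 1.5117, 0.3898, 3.7303, 2.2392, 0.6245, 3.5280),
        ("LS", 40, 1.5864, 1.2674, 3.7008, 3.1863, 0.7102, 6.3293),
        ("PUA", 25, 3.5800, 1.1643, 2.9929, 3.9372, 1.1369, 9.7448),
        ("LP", 25, 1.1844, 0.5356, 5.8001, 2.6807, 0.4926, 5.8463),
        ("LJ", 5, 2.0826, 1.2167, 2.7562, 3.0411, 0.6751, 3.3120),
        ("ZT", 5, 1.3222, 1.1378, 4.9121, 2.5771, 0.5723, 2.6593),
        ("YC", 20, 1.0361, 0.9661, 3.8818, 2.4010, 0.4814, 4.7407),
        ("WF", 5, 1.2197, 0.8885, 4.2984, 2.7102, 0.5647, 6.0205),
        ("LY", 30, 1.5378, 0.6945, 1.9492, 2.6026, 0.7956, 6.7290),
        ("DF", 20, 1.2382, 0.5367, 2.7307, 2.0601, 0.5670, 3.4004),
    ]
    # distinct matrix-level grids per origin (different permutations per
    # constituent, so origins occupy distinct points in matrix space)
    water_rank = (3, 7, 0, 10, 5, 1, 8, 4, 9, 2, 6)
    starch_rank = (8, 2, 6, 1, 9, 4, 0, 10, 3, 7, 5)
    pigment_rank = (5, 0, 9, 4, 2, 10, 6, 1, 7, 3, 8)
    origins = []
    for i, (code, n, *means) in enumerate(rows):
        origins.append(
            OriginSpec(
                code=code,
                n_samples=n,
                component_means=tuple(means),
                matrix_levels=(
                    6.0 + 1.2 * water_rank[i],
                    6.0 + 1.2 * starch_rank[i],
                    2.0 + 0.6 * pigment_rank[i],
                ),
                baseline_offset=0.05 + 0.01 * water_rank[i],
                baseline_slope=0.002 * (pigment_rank[i] - 5),
            )
        )
    return tuple(origins)


DEFAULT_ORIGINS = _default_origins()


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator settings; the defaults emulate the study conditions
    (240 samples over 11 origins, 1050-point spectra, 3 replicates)."""

    grid: WavelengthGrid = DEFAULT_GRID
    origins: tuple[OriginSpec, ...] = DEFAULT_ORIGINS
    bands: Mapping[str, tuple[Band, ...]] = field(default_factory=lambda: COMPONENT_BANDS)
    matrix_bands: Mapping[str, tuple[Band, ...]] = field(
        default_factory=lambda: MATRIX_BANDS
    )
    within_cv: float = 0.15
    matrix_cv: float = 0.04
    noise_sigma: float = 0.002
    replicates: int = 3
    scatter_offset_sd: float = 0.01
    scatter_slope_sd: float = 0.01
    include_matrix: bool = True
    include_baseline: bool = True
    separation: float = 1.0

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if not self.origins:
            raise ValueError("need at least one origin")
        codes = [o.code for o in self.origins]
        if len(set(codes)) != len(codes):
            raise ValueError("origin codes must be unique")
        for name, bands in list(self.bands.items()) + list(self.matrix_bands.items()):
            for center, width, _ in bands:
                if not self.grid.start_nm <= center <= self.grid.stop_nm:
                    raise ValueError(
                        f"band at {center} nm of {name!r} lies outside the grid"
                    )
                if width <= 0:
                    raise ValueError(f"band width must be > 0 for {name!r}")

    @property
    def n_samples(self) -> int:
        return sum(o.n_samples for o in self.origins)

    @property
    def origin_codes(self) -> tuple[str, ...]:
        return tuple(o.code for o in self.origins)

    def class_codes(self, labels: Sequence[str]) -> np.ndarray:
        """Integer class codes 1..K in origin declaration order."""
        lookup = {c: i + 1 for i, c in enumerate(self.origin_codes)}
        return np.array([lookup[str(l)] for l in labels], dtype=int)

    def noiseless(self) -> "SyntheticConfig":
        """Pure Beer-Lambert variant: no matrix, baseline, scatter or noise,
        single replicate — absorbance is exactly the measured mixture."""
        return replace(
            self,
            noise_sigma=0.0,
            scatter_offset_sd=0.0,
            scatter_slope_sd=0.0,
            replicates=1,
            include_matrix=False,
            include_baseline=False,
        )

    def scaled(self, fraction: float) -> "SyntheticConfig":
        """Down-scaled sample counts (at least 2 per origin) for quick runs."""
        return replace(
            self,
            origins=tuple(
                replace(o, n_samples=max(2, round(o.n_samples * fraction)))
                for o in self.origins
            ),
        )


@dataclass
class SyntheticDataset:
    """Replicate-level spectra plus reference contents and labels."""

    spectra: SpectrumSet  # one row per replicate scan
    replicate_groups: dict[str, list[int]]
    contents: ContentTable | None  # one row per sample, derived columns included
    labels: list[str]  # origin code per sample
    config: SyntheticConfig | None  # None when wrapping external CSV data
    seed: int

    def averaged(self) -> SpectrumSet:
        from .spectra import average_replicates

        return average_replicates(self.spectra, self.replicate_groups)


def _gaussian_bands(grid: WavelengthGrid, bands: Sequence[Band]) -> np.ndarray:
    wl = grid.wavelengths
    out = np.zeros(grid.n_points)
    for center, width, amp in bands:
        out += amp * np.exp(-0.5 * ((wl - center) / width) ** 2)
    return out


def component_spectra(cfg: SyntheticConfig) -> np.ndarray:
    """Pure-component absorptivity matrix (6 x n_points), row order GA, HA,
    PE, PB, PC, PA.  Raises if any spectrum is degenerate or two components
    are spectrally indistinct (cosine similarity >= 0.999)."""
    E = np.array(
        [_gaussian_bands(cfg.grid, cfg.bands[c]) for c in MEASURED_COMPONENTS]
    )
    norms = np.linalg.norm(E, axis=1)
    if np.any(norms == 0):
        bad = [MEASURED_COMPONENTS[i] for i in np.flatnonzero(norms == 0)]
        raise ValueError(f"zero absorptivity spectrum for {bad}")
    unit = E / norms[:, None]
    cos = unit @ unit.T
    iu = np.triu_indices(len(E), k=1)
    if np.any(cos[iu] >= 0.999):
        raise ValueError("component spectra are not pairwise distinct")
    return E


def _matrix_spectra(cfg: SyntheticConfig) -> np.ndarray:
    return np.array(
        [_gaussian_bands(cfg.grid, cfg.matrix_bands[m]) for m in MATRIX_NAMES]
    )


def _truncated_normal(
    mean: float, cv: float, size: int, rng: np.random.Generator
) -> np.ndarray:
    if cv == 0 or mean == 0:
        return np.full(size, mean)
    sd = cv * mean
    a = (0.0 - mean) / sd  # truncate at zero
    return stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=size, random_state=rng)


def _separated(value: float, grand: float, separation: float) -> float:
    return grand + separation * (value - grand)


def _draw_samples(cfg: SyntheticConfig, rng: np.random.Generator):
    n_comp = len(MEASURED_COMPONENTS)
    grand_comp = np.mean([o.component_means for o in cfg.origins], axis=0)
    grand_mat = np.mean([o.matrix_levels for o in cfg.origins], axis=0)
    C_meas, C_mat, labels, origin_idx = [], [], [], []
    for oi, origin in enumerate(cfg.origins):
        cols = [
            _truncated_normal(
                _separated(origin.component_means[c], grand_comp[c], cfg.separation),
                cfg.within_cv,
                origin.n_samples,
                rng,
            )
            for c in range(n_comp)
        ]
        C_meas.append(np.column_stack(cols))
        mats = [
            _truncated_normal(
                _separated(origin.matrix_levels[m], grand_mat[m], cfg.separation),
                cfg.matrix_cv,
                origin.n_samples,
                rng,
            )
            for m in range(len(MATRIX_NAMES))
        ]
        C_mat.append(np.column_stack(mats))
        labels.extend([origin.code] * origin.n_samples)
        origin_idx.extend([oi] * origin.n_samples)
    return (
        np.vstack(C_meas),
        np.vstack(C_mat),
        labels,
        np.array(origin_idx),
    )


def sample_concentrations(
    cfg: SyntheticConfig, seed: int = 0
) -> tuple[ContentTable, list[str]]:
    """Draw per-sample concentrations; returns the derived content table and
    the aligned origin labels."""
    rng = np.random.default_rng(seed)
    C_meas, _, labels, _ = _draw_samples(cfg, rng)
    ids = [f"S{i + 1:04d}" for i in range(len(labels))]
    frame = pd.DataFrame(C_meas, columns=list(MEASURED_COMPONENTS), index=ids)
    frame.index.name = "sample_id"
    return derive_composites(frame), labels


def generate_dataset(cfg: SyntheticConfig, seed: int = 0) -> SyntheticDataset:
    """Full forward model: replicate-level absorbance spectra plus the
    matching content table and origin labels.

    Per replicate, A(lambda) = sum_i c_i eps_i(lambda) [+ matrix terms]
    [+ origin baseline] + scatter offset + scatter tilt + white noise.
    """
    rng = np.random.default_rng(seed)
    C_meas, C_mat, labels, origin_idx = _draw_samples(cfg, rng)
    n = len(labels)
    E = component_spectra(cfg)
    base = C_meas @ E
    if cfg.include_matrix:
        base = base + C_mat @ _matrix_spectra(cfg)
    if cfg.include_baseline:
        lam = np.linspace(0.0, 1.0, cfg.grid.n_points)
        offsets = np.array([cfg.origins[i].baseline_offset for i in origin_idx])
        slopes = np.array([cfg.origins[i].baseline_slope for i in origin_idx])
        base = base + offsets[:, None] + slopes[:, None] * lam[None, :]
    lam = np.linspace(0.0, 1.0, cfg.grid.n_points)
    rows, rep_ids, rep_labels = [], [], []
    groups: dict[str, list[int]] = {}
    sample_ids = [f"S{i + 1:04d}" for i in range(n)]
    k = 0
    for i in range(n):
        groups[sample_ids[i]] = []
        for r in range(cfg.replicates):
            spec = base[i].copy()
            if cfg.scatter_offset_sd > 0:
                spec = spec + rng.normal(0.0, cfg.scatter_offset_sd)
            if cfg.scatter_slope_sd > 0:
                spec = spec + rng.normal(0.0, cfg.scatter_slope_sd) * lam
            if cfg.noise_sigma > 0:
                spec = spec + rng.normal(0.0, cfg.noise_sigma, cfg.grid.n_points)
            rows.append(spec)
            rep_ids.append(f"{sample_ids[i]}_r{r + 1}")
            rep_labels.append(labels[i])
            groups[sample_ids[i]].append(k)
            k += 1
    spectra = SpectrumSet(
        grid=cfg.grid,
        absorbance=np.array(rows),
        sample_ids=rep_ids,
        origin_labels=rep_labels,
    )
    frame = pd.DataFrame(C_meas, columns=list(MEASURED_COMPONENTS), index=sample_ids)
    frame.index.name = "sample_id"
    return SyntheticDataset(
        spectra=spectra,
        replicate_groups=groups,
        contents=derive_composites(frame),
        labels=list(labels),
        config=cfg,
        seed=seed,
    )
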