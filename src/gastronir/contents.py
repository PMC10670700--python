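"""Reference-content tables for the six HPLC-quantified constituents.

The measured phenolics of *Gastrodia elata* are gastrodin (GA),
p-hydroxybenzyl alcohol (HA) and parishins E/B/C/A (PE, PB, PC, PA), in
mg/g of dried powder.  Two composite targets are always derived, never
read from disk: ``GA_HA`` (gastrodin + p-hydroxybenzyl alcohol) and
``total`` (sum of all six constituents).
"""

from __future__ import annotations

from dataclasses import dataclass
from collections.abc import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MEASURED_COMPONENTS",
    "DERIVED_COMPONENTS",
    "ALL_COMPONENTS",
    "ContentTable",
    "OriginSummary",
    "read_contents_csv",
    "write_contents_csv",
    "derive_composites",
    "summarize_by_origin",
]

MEASURED_COMPONENTS = ("GA", "HA", "PE", "PB", "PC", "PA")
DERIVED_COMPONENTS = ("GA_HA", "total")
ALL_COMPONENTS = MEASURED_COMPONENTS + DERIVED_COMPONENTS

ID_COLUMN = "sample_id"


@dataclass
class ContentTable:
    """Per-sample component concentrations (mg/g).

    ``data`` is indexed by sample id with the six measured columns and,
    after :func:`derive_composites`, the two derived columns.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in MEASURED_COMPONENTS if c not in self.data.columns]
        if missing:
            raise ValueError(f"content table missing columns {missing}")
        values = self.data[list(self.data.columns)].to_numpy(dtype=float)
        if not np.all(np.isfinite(values)):
            raise ValueError("content table contains non-finite values")
        if (values < 0).any():
            raise ValueError("concentrations must be >= 0")
        if self.data.index.has_duplicates:
            raise ValueError("sample ids must be unique")
        if self.has_derived:
            meas = self.data[list(MEASURED_COMPONENTS)].to_numpy(dtype=float)
            if not np.allclose(
                self.data["GA_HA"], meas[:, :2].sum(axis=1), atol=5e-4
            ) or not np.allclose(self.data["total"], meas.sum(axis=1), atol=5e-4):
                raise ValueError("derived columns inconsistent with measured ones")

    @property
    def has_derived(self) -> bool:
        return all(c in self.data.columns for c in DERIVED_COMPONENTS)

    @property
    def sample_ids(self) -> list[str]:
        return [str(i) for i in self.data.index]

    def values_for(self, component: str) -> np.ndarray:
        if component not in self.data.columns:
            raise KeyError(f"unknown component {component!r}")
        return self.data[component].to_numpy(dtype=float)

    def select(self, indices: Sequence[int]) -> "ContentTable":
        return ContentTable(self.data.iloc[list(indices)].copy())


@dataclass
class OriginSummary:
    """Per-origin mean contents with between-origin dispersion.

    ``cv_percent`` is the coefficient of variation (100 * sample standard
    deviation / mean, n-1 denominator) computed over the per-origin means,
    i.e. a between-origin dispersion measure; ``grand_mean`` is the
    unweighted mean of the per-origin means.
    """

    origin_means: pd.DataFrame  # origins x components
    grand_mean: pd.Series
    cv_percent: pd.Series


def read_contents_csv(path) -> ContentTable:
    """Read ``sample_id,GA,HA,PE,PB,PC,PA`` CSV; derived columns are ignored."""
    frame = pd.read_csv(path, dtype={ID_COLUMN: str}, float_precision="round_trip")
    if ID_COLUMN not in frame.columns:
        raise ValueError(f"content CSV must have a '{ID_COLUMN}' column")
    frame = frame.set_index(ID_COLUMN)
    return derive_composites(ContentTable(frame[list(MEASURED_COMPONENTS)].copy()))


def write_contents_csv(table: ContentTable, path, float_format: str = "%.6g") -> None:
    table.data.to_csv(path, index_label=ID_COLUMN, float_format=float_format)


def derive_composites(table: ContentTable | pd.DataFrame) -> ContentTable:
    """Append the GA_HA and total composite columns.

    Idempotent: derived columns are always recomputed from the measured six.
    """
    frame = table.data if isinstance(table, ContentTable) else table
    out = frame[list(MEASURED_COMPONENTS)].copy()
    out["GA_HA"] = out["GA"] + out["HA"]
    out["total"] = out[list(MEASURED_COMPONENTS)].sum(axis=1)
    return ContentTable(out)


def summarize_by_origin(
    table: ContentTable, labels: Sequence[str]
) -> OriginSummary:
    """Per-origin means plus between-origin grand mean and CV%.

    Every sample must carry an origin label.  The grand mean is the
    unweighted mean of the per-origin means and the CV uses the n-1
    standard deviation over those means, so a table of printed per-origin
    means reproduces its own summary rows exactly.
    """
    labels = [str(l) for l in labels]
    if len(labels) != len(table.data):
        raise ValueError("labels must align with table rows")
    frame = (
        table.data if table.has_derived else derive_composites(table).data
    ).copy()
    frame["_origin"] = labels
    counts = frame.groupby("_origin").size()
    if (counts == 0).any():  # defensive; groupby cannot yield empty groups
        raise ValueError("origin with zero samples")
    means = frame.groupby("_origin", sort=False).mean()
    means.index.name = "origin"
    grand = means.mean(axis=0)
    if len(means) < 2:
        raise ValueError("need at least two origins for a CV over origin means")
    cv = 100.0 * means.std(axis=0, ddof=1) / grand
    return OriginSummary(origin_means=means, grand_mean=grand, cv_percent=cv)
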