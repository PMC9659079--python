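"""Transfer matrices between dates and change statistics.

A transfer matrix cross-tabulates area (km²) between two dates: entry (i, j)
is the area occupying category i at the first date and category j at the
second, with categories either land-use classes or risk levels.  Pixels that
are nodata at either date are excluded from both marginals, so row sums equal
date-1 category areas and column sums date-2 areas, exactly on pixel counts.

Percent change is reported against an explicit denominator (start, end or
max of the two values) because regional studies mix conventions freely; the
choice is part of the result and is logged by the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .raster import LandUseRaster
from .risk import ERIField, LEVELS, RiskCellGrid

__all__ = ["ChangeStat", "landuse_transfer", "risk_transfer", "change_stats"]


@dataclass(frozen=True)
class ChangeStat:
    """start → end change: delta = end − start; pct = |delta|/denominator·100."""

    start_value: float
    end_value: float
    denominator: str  # "start" | "end" | "max"
    delta: float
    pct: float


def landuse_transfer(r1: LandUseRaster, r2: LandUseRaster) -> pd.DataFrame:
    """Cross-tabulate pixel transitions between two dates, scaled to km².

    Returns a class-name labelled k×k DataFrame (rows = date 1, columns =
    date 2) over the shared codebook.
    """
    if r1.shape != r2.shape:
        raise ValueError(f"shape mismatch: {r1.shape} vs {r2.shape}")
    if r1.pixel_size != r2.pixel_size:
        raise ValueError("pixel size mismatch")
    if dict(r1.codebook) != dict(r2.codebook):
        raise ValueError("codebook mismatch")
    codes = sorted(r1.codebook)
    names = [r1.codebook[c] for c in codes]
    k = len(codes)
    pos = {c: i for i, c in enumerate(codes)}
    both = r1.valid_mask & r2.valid_mask
    a = np.vectorize(pos.get, otypes=[np.int64])(r1.codes[both]) if both.any() else np.array([], dtype=np.int64)
    b = np.vectorize(pos.get, otypes=[np.int64])(r2.codes[both]) if both.any() else np.array([], dtype=np.int64)
    counts = np.bincount(a * k + b, minlength=k * k).reshape(k, k)
    mat = counts * r1.pixel_area_km2
    df = pd.DataFrame(mat, index=names, columns=names)
    df.index.name = "from"
    df.columns.name = "to"
    return df


def risk_transfer(
    f1: ERIField, f2: ERIField, grid: RiskCellGrid
) -> pd.DataFrame:
    """Cross-tabulate cell areas by (risk level at date 1, level at date 2)."""
    if not f1.table["cell_id"].equals(f2.table["cell_id"]):
        raise ValueError("risk fields are defined on different grids")
    areas = grid.cells.set_index("cell_id")["area_km2"].reindex(f1.table["cell_id"])
    l1 = f1.levels.to_numpy()
    l2 = f2.levels.to_numpy()
    df = pd.DataFrame(0.0, index=list(LEVELS), columns=list(LEVELS))
    for lev1, lev2, a in zip(l1, l2, areas.to_numpy()):
        df.loc[lev1, lev2] += a
    df.index.name = "from"
    df.columns.name = "to"
    return df


def change_stats(
    start_value: float, end_value: float, denominator: str = "end"
) -> ChangeStat:
    """Absolute and percent change between two values.

    ``pct`` is |end − start| over the chosen denominator × 100; full
    precision is retained (reports round to 1 decimal at write time).
    """
    denoms = {
        "start": start_value,
        "end": end_value,
        "max": max(start_value, end_value),
    }
    if denominator not in denoms:
        raise ValueError(f"denominator must be one of {sorted(denoms)}")
    d = denoms[denominator]
    if not d > 0:
        raise ValueError(f"denominator value must be > 0, got {d!r}")
    delta = end_value - start_value
    return ChangeStat(start_value, end_value, denominator, delta, abs(delta) / d * 100.0)
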