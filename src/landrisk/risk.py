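"""Risk-cell tessellation, the cell-wise ecological risk index, and classing.

The landscape is tiled with square assessment units ("risk cells") of side
L anchored at the raster's top-left origin.  Each retained cell k gets

    ERI_k = Σ_i (A_ki / A_k) · R_i

an area-weighted convex combination of the per-class loss indices R_i, and
the value is attributed to the cell centroid.  Cells whose valid-pixel
coverage falls below ``min_coverage`` (default 0.5) are dropped; retained
edge cells use their actual valid area as A_k.

ERI values are classed into five ordered levels, by default with fixed
breakpoints — lowest (≤0.10), low (≤0.15), medium (≤0.35), high (≤0.45),
highest (>0.45), right-closed so boundary values fall in the lower class —
or with data-driven 5-class Fisher–Jenks natural breaks.  The overall
landscape risk value is the sum of ERI over all retained cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .metrics import MetricWeights, class_metrics, local_loss_indices
from .raster import LandUseRaster

__all__ = [
    "LEVELS",
    "PAPER_BREAKS",
    "RiskCellGrid",
    "ERIField",
    "RiskClassing",
    "build_grid",
    "compute_eri",
    "classify_risk",
    "overall_risk",
    "level_areas",
    "jenks_breaks",
]

LEVELS = ("lowest", "low", "medium", "high", "highest")

#: Fixed upper breakpoints of the first four levels (right-closed).
PAPER_BREAKS = (0.10, 0.15, 0.35, 0.45)


@dataclass(frozen=True)
class RiskCellGrid:
    """Square tessellation over a raster.

    ``cells`` has one row per retained cell: cell_id, grid_row, grid_col,
    pixel bounds row0/row1/col0/col1 (half-open), centroid_x/centroid_y
    (projected meters, cell centers), area_km2 (valid area A_k), coverage,
    and one ``area_<class>`` column per land-use class (A_ki, km²).
    """

    cells: pd.DataFrame
    cell_side: float
    raster_shape: tuple[int, int]
    class_names: tuple[str, ...]

    def class_area_columns(self) -> list[str]:
        return [f"area_{c}" for c in self.class_names]

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def total_area_km2(self) -> float:
        return float(self.cells["area_km2"].sum())

    def centroids_km(self) -> np.ndarray:
        """(n, 2) centroid coordinates in km, for distance-band weights."""
        return self.cells[["centroid_x", "centroid_y"]].to_numpy() / 1000.0


@dataclass(frozen=True)
class RiskClassing:
    """Five-level classing scheme: fixed breakpoints or Fisher–Jenks."""

    scheme: str = "fixed_paper"
    breaks: tuple[float, ...] = PAPER_BREAKS
    labels: tuple[str, ...] = LEVELS

    def __post_init__(self) -> None:
        if self.scheme not in ("fixed_paper", "jenks"):
            raise ValueError(f"unknown classing scheme {self.scheme!r}")
        if list(self.breaks) != sorted(self.breaks) or len(set(self.breaks)) != len(
            self.breaks
        ):
            raise ValueError("breakpoints must be strictly increasing")
        if len(self.labels) != len(self.breaks) + 1:
            raise ValueError("need exactly one more label than breakpoints")


@dataclass(frozen=True)
class ERIField:
    """Per-cell ERI values (and, once classified, risk levels)."""

    table: pd.DataFrame  # columns: cell_id, row, col, centroid_x, centroid_y, eri[, level]
    classing: RiskClassing | None = None

    @property
    def values(self) -> np.ndarray:
        return self.table["eri"].to_numpy()

    @property
    def levels(self) -> pd.Series:
        if "level" not in self.table.columns:
            raise ValueError("field has not been classified yet")
        return self.table["level"]


def build_grid(
    raster: LandUseRaster, cell_side: float, min_coverage: float = 0.5
) -> RiskCellGrid:
    """Tile the raster with square cells of side ``cell_side`` (meters).

    Pixels are assigned to the cell containing their center; a cell is
    retained iff valid area / cell_side² ≥ ``min_coverage``.  Per-class
    areas A_ki come from exact pixel counting.
    """
    if not (isinstance(cell_side, (int, float)) and cell_side > 0):
        raise ValueError("cell_side must be a positive number")
    if cell_side < raster.pixel_size:
        raise ValueError("cell_side must be >= pixel_size")
    nr, nc = raster.shape
    px = raster.pixel_size
    # cell index per pixel, by pixel-center location
    row_cell = (((np.arange(nr) + 0.5) * px) // cell_side).astype(np.int64)
    col_cell = (((np.arange(nc) + 0.5) * px) // cell_side).astype(np.int64)
    n_cr = int(row_cell.max()) + 1
    n_cc = int(col_cell.max()) + 1
    cell_of_pixel = row_cell[:, None] * n_cc + col_cell[None, :]

    px_area = raster.pixel_area_km2
    valid = raster.valid_mask
    n_cells_all = n_cr * n_cc
    valid_counts = np.bincount(
        cell_of_pixel.reshape(-1), weights=valid.reshape(-1), minlength=n_cells_all
    )
    class_names = tuple(raster.codebook.values())
    name_of_code = raster.codebook
    class_counts = {}
    for code in sorted(raster.present_codes()):
        class_counts[name_of_code[code]] = np.bincount(
            cell_of_pixel.reshape(-1),
            weights=(raster.codes == code).reshape(-1),
            minlength=n_cells_all,
        )

    cell_area_km2 = (cell_side / 1000.0) ** 2
    coverage = valid_counts * px_area / cell_area_km2
    keep = coverage >= min_coverage

    ox, oy = raster.origin
    rows = []
    cid = 0
    # pixel bounds per cell row/col (monotone mapping -> contiguous blocks)
    row_bounds = [
        (int(np.searchsorted(row_cell, g, "left")), int(np.searchsorted(row_cell, g, "right")))
        for g in range(n_cr)
    ]
    col_bounds = [
        (int(np.searchsorted(col_cell, g, "left")), int(np.searchsorted(col_cell, g, "right")))
        for g in range(n_cc)
    ]
    for g in range(n_cells_all):
        if not keep[g]:
            continue
        gr, gc = divmod(g, n_cc)
        rec = {
            "cell_id": cid,
            "grid_row": gr,
            "grid_col": gc,
            "row0": row_bounds[gr][0],
            "row1": row_bounds[gr][1],
            "col0": col_bounds[gc][0],
            "col1": col_bounds[gc][1],
            "centroid_x": ox + (gc + 0.5) * cell_side,
            "centroid_y": oy - (gr + 0.5) * cell_side,
            "area_km2": valid_counts[g] * px_area,
            "coverage": coverage[g],
        }
        for name in class_names:
            counts = class_counts.get(name)
            rec[f"area_{name}"] = (counts[g] * px_area) if counts is not None else 0.0
        rows.append(rec)
        cid += 1
    if not rows:
        raise ValueError(
            "no cell meets the coverage threshold; lower min_coverage or cell_side"
        )
    cells = pd.DataFrame(rows)
    return RiskCellGrid(cells, float(cell_side), (nr, nc), class_names)


def compute_eri(
    grid: RiskCellGrid,
    metrics: pd.DataFrame,
    local_r: pd.DataFrame | None = None,
) -> ERIField:
    """ERI_k = Σ_i (A_ki/A_k)·R_i per retained cell.

    ``metrics`` is the global per-class table (column R); if ``local_r`` is
    given (cell_id × class loss indices from the local metric scope) the
    cell's own R values are used instead.
    """
    cells = grid.cells
    if (cells["area_km2"] <= 0).any():
        raise ValueError("cell with zero valid area")
    eri = np.zeros(len(cells))
    for name in grid.class_names:
        a_ki = cells[f"area_{name}"].to_numpy()
        if local_r is not None:
            if name in local_r.columns:
                r = local_r[name].reindex(cells["cell_id"]).fillna(0.0).to_numpy()
            else:
                r = 0.0
        else:
            if name in metrics.index:
                r = float(metrics.loc[name, "R"])
            else:
                if (a_ki > 0).any():
                    raise ValueError(f"class {name!r} present in cells but has no R")
                r = 0.0
        eri += a_ki / cells["area_km2"].to_numpy() * r
    table = cells[
        ["cell_id", "grid_row", "grid_col", "centroid_x", "centroid_y"]
    ].copy()
    table = table.rename(columns={"grid_row": "row", "grid_col": "col"})
    table["eri"] = eri
    return ERIField(table)


def jenks_breaks(values: Sequence[float], n_classes: int = 5) -> tuple[float, ...]:
    """Exact Fisher–Jenks natural breaks by dynamic programming.

    Returns the ``n_classes − 1`` inner break values (upper bound of each
    class but the last), minimizing total within-class sum of squared
    deviations.  O(k·n²); intended for the ~10³ risk cells of a county run.
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size
    if n < n_classes:
        raise ValueError(f"need at least {n_classes} values, got {n}")
    csum = np.concatenate(([0.0], np.cumsum(x)))
    csq = np.concatenate(([0.0], np.cumsum(x * x)))

    def sse(i: int, j: int) -> float:  # x[i:j]
        m = j - i
        s = csum[j] - csum[i]
        return (csq[j] - csq[i]) - s * s / m

    cost = np.full((n_classes + 1, n + 1), np.inf)
    split = np.zeros((n_classes + 1, n + 1), dtype=int)
    cost[0, 0] = 0.0
    for k in range(1, n_classes + 1):
        for j in range(k, n + 1):
            best, arg = np.inf, k - 1
            for i in range(k - 1, j):
                c = cost[k - 1, i] + sse(i, j)
                if c < best:
                    best, arg = c, i
            cost[k, j] = best
            split[k, j] = arg
    # recover class boundaries
    bounds = []
    j = n
    for k in range(n_classes, 0, -1):
        i = split[k, j]
        bounds.append(i)
        j = i
    bounds = bounds[::-1][1:]  # drop leading 0; indices of first element per class 2..k
    return tuple(float(x[b - 1]) for b in bounds)


def classify_risk(field: ERIField, classing: RiskClassing | None = None) -> ERIField:
    """Attach a risk level to every cell (right-closed intervals)."""
    classing = classing or RiskClassing()
    if classing.scheme == "jenks":
        breaks = jenks_breaks(field.values, n_classes=len(classing.labels))
        classing = RiskClassing("jenks", tuple(breaks), classing.labels)
    edges = np.array(classing.breaks)
    idx = np.searchsorted(edges, field.values, side="left")
    labels = np.asarray(classing.labels, dtype=object)[idx]
    table = field.table.copy()
    table["level"] = pd.Categorical(labels, categories=list(classing.labels), ordered=True)
    return ERIField(table, classing)


def overall_risk(field: ERIField) -> float:
    """Sum of ERI over all retained cells (the landscape trajectory value)."""
    if len(field.table) == 0:
        raise ValueError("empty field")
    return float(field.table["eri"].sum())


def level_areas(field: ERIField, grid: RiskCellGrid) -> pd.Series:
    """Valid area (km²) per risk level; absent levels reported as 0."""
    labels = field.levels
    areas = grid.cells.set_index("cell_id")["area_km2"].reindex(
        field.table["cell_id"]
    )
    out = areas.groupby(labels.to_numpy()).sum()
    out = out.reindex(list(LEVELS), fill_value=0.0)
    out.index.name = "level"
    out.name = "area_km2"
    return out
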