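"""Per-class landscape pattern metrics and the loss-index chain.

For each land-use class *i* the chain is

    C_i = n_i / A_i                        fragmentation  (patches per km²)
    N_i = (A / (2·A_i)) · sqrt(n_i / A)    separation
    D_i = (Q_i + M_i)/4 + L_i/2            dominance
    E_i = a·C_i + b·N_i + c·D_i            disturbance    (a+b+c = 1)
    R_i = E_i · F_i                        loss index

with n_i the patch count, A_i the class area (km²), A the landscape area,
Q_i the fraction of risk cells (quadrats) in which the class occurs, M_i its
share of all patches, L_i its share of total area, and F_i the rank-normalized
ecological fragility of the land-use type.  Fragility ranks the five types
from least to most sensitive — construction, forest, grass, cultivated,
water — and rescales the ranks linearly onto [0, 1]: 0, 0.25, 0.5, 0.75, 1.

Default indicator weights are a=0.5, b=0.3, c=0.2 (fragmentation weighted
highest as the leading imprint of human interference).  Classes with zero
area are omitted from the metrics table rather than carried as 0/0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import TYPE_CHECKING, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .raster import CLASS_NAMES, LandUseRaster

if TYPE_CHECKING:  # pragma: no cover
    from .risk import RiskCellGrid

__all__ = [
    "DEFAULT_FRAGILITY",
    "MetricWeights",
    "PatchSet",
    "label_patches",
    "fragmentation",
    "separation",
    "dominance",
    "disturbance",
    "fragility",
    "loss_index",
    "class_metrics",
    "local_loss_indices",
]

#: Fragility ordering, least to most fragile.
FRAGILITY_ORDER = ("construction", "forest", "grass", "cultivated", "water")

#: Rank-normalized fragility F_i = (rank − 1)/(k − 1).
DEFAULT_FRAGILITY: dict[str, float] = {
    name: rank / (len(FRAGILITY_ORDER) - 1)
    for rank, name in enumerate(FRAGILITY_ORDER)
}


@dataclass(frozen=True)
class MetricWeights:
    """Weights of fragmentation (a), separation (b), dominance (c) in E_i."""

    a: float = 0.5
    b: float = 0.3
    c: float = 0.2

    def __post_init__(self) -> None:
        if abs(self.a + self.b + self.c - 1.0) > 1e-9:
            raise ValueError(
                f"weights must sum to 1, got a+b+c = {self.a + self.b + self.c!r}"
            )


@dataclass(frozen=True)
class PatchSet:
    """Connected-component decomposition of a categorical raster.

    ``patches`` has one row per patch: patch_id, code, name, n_pixels,
    area_km2.  ``total_area_km2`` is the full non-nodata landscape area A.
    """

    patches: pd.DataFrame
    total_area_km2: float
    connectivity: int

    def class_summary(self) -> pd.DataFrame:
        """Per-class n_i (patch count) and A_i (km²), indexed by class name."""
        g = self.patches.groupby("name", sort=False).agg(
            n=("patch_id", "size"), area_km2=("area_km2", "sum")
        )
        return g


def _structure(connectivity: int) -> np.ndarray:
    if connectivity == 4:
        return ndimage.generate_binary_structure(2, 1)
    if connectivity == 8:
        return ndimage.generate_binary_structure(2, 2)
    raise ValueError(f"connectivity must be 4 or 8, got {connectivity}")


def label_patches(raster: LandUseRaster, connectivity: int = 8) -> PatchSet:
    """Extract maximal same-code connected components (nodata never joins)."""
    st = _structure(connectivity)
    px_area = raster.pixel_area_km2
    rows = []
    pid = 0
    for code in sorted(raster.present_codes()):
        lab, n = ndimage.label(raster.codes == code, structure=st)
        counts = np.bincount(lab.reshape(-1))[1:]  # skip background
        for c in counts:
            rows.append((pid, code, raster.codebook[code], int(c), int(c) * px_area))
            pid += 1
    patches = pd.DataFrame(
        rows, columns=["patch_id", "code", "name", "n_pixels", "area_km2"]
    )
    return PatchSet(patches, raster.total_area_km2, connectivity)


# ---------------------------------------------------------------------------
# Scalar index formulas
# ---------------------------------------------------------------------------

def fragmentation(n_i: int, area_i: float) -> float:
    """C_i = n_i / A_i (patches per km²)."""
    if not area_i > 0:
        raise ValueError("class area must be > 0")
    return n_i / area_i


def separation(total_area: float, area_i: float, n_i: int) -> float:
    """N_i = (A / (2·A_i)) · sqrt(n_i / A)."""
    if not total_area > 0 or not area_i > 0:
        raise ValueError("areas must be > 0")
    return (total_area / (2.0 * area_i)) * np.sqrt(n_i / total_area)


def dominance(q_i: float, m_i: float, l_i: float) -> float:
    """D_i = (Q_i + M_i)/4 + L_i/2, all inputs fractions in [0, 1]."""
    for v, nm in ((q_i, "Q"), (m_i, "M"), (l_i, "L")):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{nm} must be in [0, 1], got {v!r}")
    return (q_i + m_i) / 4.0 + l_i / 2.0


def disturbance(c_i: float, n_i: float, d_i: float, weights: MetricWeights = MetricWeights()) -> float:
    """E_i = a·C_i + b·N_i + c·D_i."""
    return weights.a * c_i + weights.b * n_i + weights.c * d_i


def fragility(
    class_name: str, order: Sequence[str] = FRAGILITY_ORDER
) -> float:
    """Rank-normalized fragility: rank r (1-based, least fragile first) in
    ``order`` mapped to (r − 1)/(len(order) − 1)."""
    if class_name not in order:
        raise KeyError(f"unknown class {class_name!r}; order = {tuple(order)}")
    return order.index(class_name) / (len(order) - 1)


def loss_index(e_i: float, f_i: float) -> float:
    """R_i = E_i · F_i."""
    if e_i < 0:
        raise ValueError("disturbance must be >= 0")
    if not 0.0 <= f_i <= 1.0:
        raise ValueError("fragility must be in [0, 1]")
    return e_i * f_i


# ---------------------------------------------------------------------------
# Full per-class table
# ---------------------------------------------------------------------------

def _quadrat_occurrence(raster: LandUseRaster, grid: "RiskCellGrid") -> pd.Series:
    """Q_i: fraction of retained risk cells in which each class occurs."""
    area_cols = grid.class_area_columns()
    occ = (grid.cells[area_cols] > 0).sum(axis=0) / len(grid.cells)
    occ.index = [c.removeprefix("area_") for c in area_cols]
    return occ


def class_metrics(
    raster: LandUseRaster,
    grid: "RiskCellGrid",
    weights: MetricWeights = MetricWeights(),
    connectivity: int = 8,
    fragility_table: Mapping[str, float] = DEFAULT_FRAGILITY,
) -> pd.DataFrame:
    """Landscape-wide per-class metrics table (global scope).

    Returns a DataFrame indexed by class name with columns n, area_km2, C,
    N, Q, M, L, D, E, F, R.  The risk-cell grid supplies the quadrats for
    Q_i.  Classes with zero area are skipped with a warning.
    """
    ps = label_patches(raster, connectivity)
    summ = ps.class_summary()
    A = ps.total_area_km2
    n_patches_total = len(ps.patches)
    q = _quadrat_occurrence(raster, grid)

    absent = [n for n in raster.codebook.values() if n not in summ.index]
    for name in absent:
        if name in set(map(raster.codebook.get, raster.present_codes())):
            warnings.warn(f"class {name!r} has zero area; skipped")

    rows = {}
    for name, row in summ.iterrows():
        n_i, a_i = int(row["n"]), float(row["area_km2"])
        c_i = fragmentation(n_i, a_i)
        sep_i = separation(A, a_i, n_i)
        m_i = n_i / n_patches_total
        l_i = a_i / A
        q_i = float(q.get(name, 0.0))
        d_i = dominance(q_i, m_i, l_i)
        e_i = disturbance(c_i, sep_i, d_i, weights)
        f_i = float(fragility_table[name])
        rows[name] = {
            "n": n_i, "area_km2": a_i, "C": c_i, "N": sep_i, "Q": q_i,
            "M": m_i, "L": l_i, "D": d_i, "E": e_i, "F": f_i,
            "R": loss_index(e_i, f_i),
        }
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "class"
    return df


def local_loss_indices(
    raster: LandUseRaster,
    grid: "RiskCellGrid",
    weights: MetricWeights = MetricWeights(),
    connectivity: int = 8,
    fragility_table: Mapping[str, float] = DEFAULT_FRAGILITY,
) -> pd.DataFrame:
    """Per-cell loss indices R_ki for the local metric scope.

    C_i and N_i are recomputed inside each risk cell (patches clipped to the
    cell boundary); dominance D_i stays global.  Returns a DataFrame indexed
    by cell_id with one column per class name (NaN where the class is absent
    from the cell).
    """
    global_df = class_metrics(raster, grid, weights, connectivity, fragility_table)
    st = _structure(connectivity)
    px_area = raster.pixel_area_km2
    out = {}
    for cell in grid.cells.itertuples():
        window = raster.codes[cell.row0:cell.row1, cell.col0:cell.col1]
        a_cell = float(cell.area_km2)
        r_row = {}
        for code in np.unique(window):
            if code == raster.nodata_code:
                continue
            name = raster.codebook[int(code)]
            mask = window == code
            _, n_i = ndimage.label(mask, structure=st)
            a_i = int(mask.sum()) * px_area
            c_i = fragmentation(n_i, a_i)
            sep_i = separation(a_cell, a_i, n_i)
            d_i = float(global_df.loc[name, "D"])
            e_i = disturbance(c_i, sep_i, d_i, weights)
            r_row[name] = loss_index(e_i, float(fragility_table[name]))
        out[cell.cell_id] = r_row
    df = pd.DataFrame.from_dict(out, orient="index")
    df.index.name = "cell_id"
    return df
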