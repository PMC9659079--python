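"""Categorical raster container and plain-text raster I/O.

The whole pipeline operates on a single in-memory unit, :class:`LandUseRaster`:
a 2-D integer code grid with square pixels, a nodata code and a codebook
mapping codes to land-use class names.  Conventions, fixed here once:

* 0-based row/col indices, row-major, row 0 is the northern (top) edge;
* ``pixel_size`` is in meters, all areas reported downstream are in km²
  (pixel area km² = ``(pixel_size / 1000) ** 2``);
* nodata pixels never contribute to any area, patch or quadrat count.

Two on-disk dialects are supported: ESRI ASCII grid (``ascii_grid``, the
canonical text format) and single-band TIFF (``tiff``/``geotiff``) written
with :mod:`tifffile`, carrying pixel size / nodata / origin / codebook in the
ImageDescription tag as JSON.  No CRS is stored; rasters are treated as
already projected with square pixels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CLASS_NAMES",
    "DEFAULT_CODEBOOK",
    "LandUseRaster",
    "read_landuse_raster",
    "write_raster",
    "write_report",
]

#: Canonical class order, least to most ecologically fragile.
CLASS_NAMES = ("construction", "forest", "grass", "cultivated", "water")

#: Default code assignment 1..5 in canonical fragility order.
DEFAULT_CODEBOOK: dict[int, str] = {i + 1: name for i, name in enumerate(CLASS_NAMES)}

_DIALECTS = ("ascii_grid", "tiff", "geotiff")


@dataclass(frozen=True)
class LandUseRaster:
    """Categorical land-use grid with georeferencing scalars.

    Parameters
    ----------
    codes
        2-D integer array of class codes, row 0 = north.
    pixel_size
        Edge length of a (square) pixel in meters.
    nodata_code
        Integer marking invalid pixels; excluded from all accounting.
    codebook
        Mapping class code -> class name. Every non-nodata code occurring
        in ``codes`` must be present.
    origin
        (x, y) projected coordinates in meters of the top-left corner.
    """

    codes: np.ndarray
    pixel_size: float
    nodata_code: int = -9999
    codebook: Mapping[int, str] = field(default_factory=lambda: dict(DEFAULT_CODEBOOK))
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        codes = np.asarray(self.codes)
        if codes.ndim != 2 or codes.size == 0:
            raise ValueError("codes must be a non-empty 2-D array")
        if not np.issubdtype(codes.dtype, np.integer):
            raise ValueError(f"codes must be integer, got dtype {codes.dtype}")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be > 0")
        object.__setattr__(self, "codes", codes)
        object.__setattr__(self, "codebook", dict(self.codebook))
        unknown = self.present_codes() - set(self.codebook)
        if unknown:
            raise ValueError(
                f"codes {sorted(unknown)} present in raster but absent from codebook"
            )

    # -- geometry -----------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.codes.shape

    @property
    def pixel_area_km2(self) -> float:
        return (self.pixel_size / 1000.0) ** 2

    @property
    def valid_mask(self) -> np.ndarray:
        return self.codes != self.nodata_code

    def present_codes(self) -> set[int]:
        """Distinct non-nodata codes occurring in the grid."""
        u = np.unique(self.codes)
        return {int(c) for c in u if c != self.nodata_code}

    # -- accounting ---------------------------------------------------------
    def class_areas(self) -> dict[str, float]:
        """Area in km² per class name, nodata excluded."""
        out = {}
        for code in sorted(self.present_codes()):
            out[self.codebook[code]] = (
                int((self.codes == code).sum()) * self.pixel_area_km2
            )
        return out

    @property
    def total_area_km2(self) -> float:
        return int(self.valid_mask.sum()) * self.pixel_area_km2

    def with_codes(self, codes: np.ndarray) -> "LandUseRaster":
        """Copy of this raster with a new code grid, same georeferencing."""
        return replace(self, codes=codes)


# ---------------------------------------------------------------------------
# ESRI ASCII grid
# ---------------------------------------------------------------------------

def _read_ascii_grid(path: Path) -> tuple[np.ndarray, float, float, tuple[float, float]]:
    header: dict[str, float] = {}
    with open(path) as fh:
        lines = fh.read().split("\n")
    n_header = 0
    for line in lines:
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in (
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
        ):
            header[parts[0].lower()] = float(parts[1])
            n_header += 1
        else:
            break
    for key in ("ncols", "nrows", "cellsize"):
        if key not in header:
            raise ValueError(f"ASCII grid {path} missing required header field {key!r}")
    body = "\n".join(lines[n_header:])
    data = np.array(body.split(), dtype=float)
    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    if data.size != nrows * ncols:
        raise ValueError(
            f"ASCII grid {path}: expected {nrows * ncols} values, found {data.size}"
        )
    grid = data.reshape(nrows, ncols)
    cellsize = header["cellsize"]
    nodata = header.get("nodata_value", -9999.0)
    xll = header.get("xllcorner", 0.0)
    yll = header.get("yllcorner", 0.0)
    origin = (xll, yll + nrows * cellsize)  # top-left corner
    return grid, cellsize, nodata, origin


def _write_ascii_grid(
    grid: np.ndarray,
    path: Path,
    cellsize: float,
    nodata: float,
    origin: tuple[float, float],
    integer: bool,
) -> None:
    nrows, ncols = grid.shape
    xll = origin[0]
    yll = origin[1] - nrows * cellsize
    fmt = "%d" if integer else "%.6f"
    nodata_repr = ("%d" % nodata) if integer else repr(float(nodata))
    header = (
        f"ncols {ncols}\n"
        f"nrows {nrows}\n"
        f"xllcorner {xll!r}\n"
        f"yllcorner {yll!r}\n"
        f"cellsize {cellsize!r}\n"
        f"NODATA_value {nodata_repr}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, grid, fmt=fmt)


# ---------------------------------------------------------------------------
# TIFF (single integer/float band, metadata in ImageDescription)
# ---------------------------------------------------------------------------

def _write_tiff(
    grid: np.ndarray,
    path: Path,
    cellsize: float,
    nodata: float,
    origin: tuple[float, float],
    codebook: Mapping[int, str] | None,
) -> None:
    import tifffile

    meta = {
        "pixel_size": cellsize,
        "nodata": nodata,
        "origin": list(origin),
        "codebook": {str(k): v for k, v in codebook.items()} if codebook else None,
    }
    tifffile.imwrite(path, grid, description=json.dumps(meta))


def _read_tiff(path: Path):
    import tifffile

    with tifffile.TiffFile(path) as tif:
        grid = tif.asarray()
        desc = tif.pages[0].description
    meta = json.loads(desc) if desc else {}
    cellsize = float(meta.get("pixel_size", 1.0))
    nodata = float(meta.get("nodata", -9999))
    origin = tuple(meta.get("origin", (0.0, 0.0)))
    codebook = meta.get("codebook")
    if codebook is not None:
        codebook = {int(k): v for k, v in codebook.items()}
    return grid, cellsize, nodata, origin, codebook


# ---------------------------------------------------------------------------
# Public API
# ---------------------------------------------------------------------------

def read_landuse_raster(
    path: str | Path,
    dialect: str = "ascii_grid",
    codebook: Mapping[int, str] | None = None,
) -> LandUseRaster:
    """Read a categorical land-use raster.

    ``codebook`` defaults to the five-class :data:`DEFAULT_CODEBOOK` (for the
    ASCII dialect) or the codebook embedded in the file (TIFF dialect).
    Codes present in the grid but absent from the codebook raise ``ValueError``
    naming the offending codes.
    """
    path = Path(path)
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {_DIALECTS}")
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "ascii_grid":
        grid, cellsize, nodata, origin = _read_ascii_grid(path)
        embedded = None
    else:
        grid, cellsize, nodata, origin, embedded = _read_tiff(path)
    igrid = np.asarray(grid)
    if not np.issubdtype(igrid.dtype, np.integer):
        rounded = np.rint(igrid)
        if not np.allclose(igrid, rounded, atol=1e-9):
            raise ValueError(f"{path}: raster band is not integer-valued")
        igrid = rounded.astype(np.int64)
    cb = dict(codebook) if codebook is not None else (embedded or dict(DEFAULT_CODEBOOK))
    return LandUseRaster(
        codes=igrid,
        pixel_size=cellsize,
        nodata_code=int(nodata),
        codebook=cb,
        origin=(float(origin[0]), float(origin[1])),
    )


def write_raster(
    raster: "LandUseRaster | np.ndarray",
    path: str | Path,
    dialect: str = "ascii_grid",
    *,
    pixel_size: float | None = None,
    nodata: float = -9999.0,
    origin: tuple[float, float] = (0.0, 0.0),
) -> Path:
    """Write an integer land-use raster or a real-valued grid.

    Integer rasters round-trip bit-faithfully; real-valued grids (e.g. a
    per-cell ERI surface) are written with 6 decimals in the ASCII dialect.
    """
    path = Path(path)
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {_DIALECTS}")
    if isinstance(raster, LandUseRaster):
        grid = raster.codes
        cellsize = raster.pixel_size
        nodata = raster.nodata_code
        origin = raster.origin
        codebook: Mapping[int, str] | None = raster.codebook
        integer = True
    else:
        grid = np.asarray(raster)
        if grid.ndim != 2 or grid.size == 0:
            raise ValueError("grid must be a non-empty 2-D array")
        if pixel_size is None:
            raise ValueError("pixel_size is required when writing a bare array")
        cellsize = pixel_size
        codebook = None
        integer = bool(np.issubdtype(grid.dtype, np.integer))
    if dialect == "ascii_grid":
        _write_ascii_grid(grid, path, cellsize, nodata, origin, integer)
    else:
        _write_tiff(grid, path, cellsize, nodata, origin, codebook)
    return path


def write_report(tables: Mapping[str, pd.DataFrame], out_dir: str | Path) -> list[Path]:
    """Write named tables as one CSV each under ``out_dir``.

    Returns the written paths. Index is kept when it is named (e.g. class
    names on a transfer matrix); numbers are written at full precision.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if not tables:
        raise ValueError("no tables to write")
    written = []
    for name, table in tables.items():
        if table is None or len(table) == 0:
            raise ValueError(f"table {name!r} is empty")
        p = out_dir / f"{name}.csv"
        keep_index = table.index.name is not None or not isinstance(
            table.index, pd.RangeIndex
        )
        table.to_csv(p, index=keep_index)
        written.append(p)
    return written


def risk_cells_to_geojson(
    cell_table: pd.DataFrame, cell_side: float, path: str | Path
) -> Path:
    """Export risk-cell polygons (with attributes) as GeoJSON.

    ``cell_table`` needs columns ``centroid_x``/``centroid_y`` (meters); every
    other column is carried over as a feature property.
    """
    half = cell_side / 2.0
    feats = []
    attr_cols = [c for c in cell_table.columns if c not in ("centroid_x", "centroid_y")]
    for _, row in cell_table.iterrows():
        cx, cy = float(row["centroid_x"]), float(row["centroid_y"])
        ring = [
            [cx - half, cy - half],
            [cx + half, cy - half],
            [cx + half, cy + half],
            [cx - half, cy + half],
            [cx - half, cy - half],
        ]
        props = {}
        for c in attr_cols:
            v = row[c]
            props[c] = v.item() if hasattr(v, "item") else v
        feats.append(
            {
                "type": "Feature",
                "geometry": {"type": "Polygon", "coordinates": [ring]},
                "properties": props,
            }
        )
    path = Path(path)
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)
    return path
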