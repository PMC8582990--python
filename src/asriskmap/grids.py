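"""Regular prediction grids and the file formats around them.

The map products live on a regular cell-center grid (default 1 km x 1 km):
estimates are computed at (xll + (j+0.5)*cell, yll + (i+0.5)*cell) with row
index i increasing northward in memory.  Supported on-disk formats are all
plain text:

* wells CSV (``well_id,x,y,conc_ugL,censored``),
* ESRI ASCII grid per layer (NODATA -9999; rows written north-to-south as
  the dialect requires),
* long-format grid CSV (``x,y`` plus one column per layer),
* GeoJSON polygons of contiguous same-class cells (zone maps).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .synthetic import WELL_COLUMNS, validate_wells

NODATA = -9999.0


@dataclass(frozen=True)
class GridSpec:
    """Regular grid geometry (planar meters, y increasing northward)."""

    xll: float
    yll: float
    cell_size: float = 1000.0
    ncols: int = 1
    nrows: int = 1
    mask: object | None = field(default=None, compare=False)  # shapely polygon

    def __post_init__(self):
        if self.cell_size <= 0:
            raise ValueError("cell_size must be > 0")
        if self.ncols < 1 or self.nrows < 1:
            raise ValueError("grid needs at least one cell")

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(X, Y) arrays of shape (nrows, ncols); row 0 is the southernmost."""
        xs = self.xll + (np.arange(self.ncols) + 0.5) * self.cell_size
        ys = self.yll + (np.arange(self.nrows) + 0.5) * self.cell_size
        return np.meshgrid(xs, ys)

    def mask_array(self) -> np.ndarray:
        """Boolean (nrows, ncols) array: True where the cell center is inside
        the mask polygon (all True without a mask)."""
        if self.mask is None:
            return np.ones((self.nrows, self.ncols), bool)
        from shapely.geometry import Point

        cx, cy = self.cell_centers()
        inside = np.array(
            [self.mask.covers(Point(x, y)) for x, y in zip(cx.ravel(), cy.ravel())]
        )
        return inside.reshape(self.nrows, self.ncols)


def make_grid(wells_or_extent, cell_size: float = 1000.0, padding: float = 0.0,
              mask=None) -> GridSpec:
    """Smallest grid of ``cell_size`` cells covering the (padded) extent.

    ``wells_or_extent`` is either a well DataFrame (bounding box of its
    coordinates) or an (xmin, ymin, xmax, ymax) tuple.  Cell counts follow
    the ceiling rule, so the grid may overshoot the extent by less than one
    cell on the far edges.
    """
    if isinstance(wells_or_extent, pd.DataFrame):
        w = wells_or_extent
        xmin, ymin = float(w["x"].min()), float(w["y"].min())
        xmax, ymax = float(w["x"].max()), float(w["y"].max())
    else:
        xmin, ymin, xmax, ymax = map(float, wells_or_extent)
    xmin -= padding
    ymin -= padding
    xmax += padding
    ymax += padding
    width, height = xmax - xmin, ymax - ymin
    if width <= 0 or height <= 0:
        raise ValueError("extent must have positive width and height (add padding?)")
    ncols = max(1, math.ceil(width / cell_size - 1e-9))
    nrows = max(1, math.ceil(height / cell_size - 1e-9))
    return GridSpec(xll=xmin, yll=ymin, cell_size=cell_size,
                    ncols=ncols, nrows=nrows, mask=mask)


class ConcentrationGrid:
    """A GridSpec plus named per-cell layers (2D float or object arrays).

    Cells outside the mask polygon are NaN in every numeric layer.
    """

    def __init__(self, spec: GridSpec):
        self.spec = spec
        self.layers: dict[str, np.ndarray] = {}
        self._mask = spec.mask_array()

    def add_layer(self, name: str, values: np.ndarray) -> None:
        arr = np.asarray(values)
        if arr.shape != (self.spec.nrows, self.spec.ncols):
            raise ValueError(
                f"layer {name!r} shape {arr.shape} does not match grid "
                f"({self.spec.nrows}, {self.spec.ncols})"
            )
        if arr.dtype.kind == "f":
            arr = np.where(self._mask, arr, np.nan)
        self.layers[name] = arr

    def __getitem__(self, name: str) -> np.ndarray:
        return self.layers[name]

    def to_frame(self) -> pd.DataFrame:
        cx, cy = self.spec.cell_centers()
        data = {"x": cx.ravel(), "y": cy.ravel()}
        for name, arr in self.layers.items():
            data[name] = arr.ravel()
        return pd.DataFrame(data)

    def plot(self, layer: str = "conc_ugL", ax=None, **imshow_kw):
        """Quick-look map of one layer (matplotlib, row 0 plotted south)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        sp = self.spec
        extent = (sp.xll, sp.xll + sp.ncols * sp.cell_size,
                  sp.yll, sp.yll + sp.nrows * sp.cell_size)
        im = ax.imshow(np.asarray(self.layers[layer], float), origin="lower",
                       extent=extent, **imshow_kw)
        ax.set_xlabel("x (m)")
        ax.set_ylabel("y (m)")
        ax.set_title(layer)
        plt.colorbar(im, ax=ax)
        return ax


# ---------------------------------------------------------------------------
# wells CSV

def write_wells(wells: pd.DataFrame, path) -> None:
    validate_wells(wells)[WELL_COLUMNS].to_csv(path, index=False)


def read_wells(path) -> pd.DataFrame:
    """Read a wells CSV; malformed rows raise with the offending line number."""
    try:
        df = pd.read_csv(
            path,
            dtype={"well_id": str, "x": float, "y": float, "conc_ugL": float,
                   "censored": bool},
        )
    except (ValueError, pd.errors.ParserError) as exc:
        raise ValueError(f"malformed wells CSV {path}: {exc}") from exc
    missing = [c for c in WELL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"wells CSV {path} missing columns {missing}")
    bad = df.index[df["conc_ugL"] <= 0]
    if len(bad):
        raise ValueError(
            f"wells CSV {path}: non-positive concentration at line {bad[0] + 2}"
        )
    return df[WELL_COLUMNS]


# ---------------------------------------------------------------------------
# ESRI ASCII grid

def write_grid_ascii(grid: ConcentrationGrid, layer: str, path) -> None:
    sp = grid.spec
    arr = np.asarray(grid.layers[layer], float)
    out = np.where(np.isfinite(arr), arr, NODATA)
    with open(path, "w") as fh:
        fh.write(f"ncols {sp.ncols}\n")
        fh.write(f"nrows {sp.nrows}\n")
        fh.write(f"xllcorner {sp.xll:.6f}\n")
        fh.write(f"yllcorner {sp.yll:.6f}\n")
        fh.write(f"cellsize {sp.cell_size:.6f}\n")
        fh.write(f"NODATA_value {NODATA:g}\n")
        # dialect stores the top (northern) row first
        for row in out[::-1]:
            fh.write(" ".join(f"{v:.10g}" for v in row) + "\n")


def read_grid_ascii(path) -> tuple[GridSpec, np.ndarray]:
    """Read an ESRI ASCII grid; returns (GridSpec, array with NaN for NODATA,
    row 0 southernmost)."""
    header: dict[str, float] = {}
    rows: list[np.ndarray] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            if len(header) < 6 and not _is_number(parts[0]):
                if len(parts) != 2 or not _is_number(parts[1]):
                    raise ValueError(f"{path}:{lineno}: malformed header line {line!r}")
                header[parts[0].lower()] = float(parts[1])
            else:
                try:
                    rows.append(np.array(parts, dtype=float))
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: malformed data row") from exc
    required = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize")
    missing = [k for k in required if k not in header]
    if missing:
        raise ValueError(f"{path}: header missing {missing}")
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    if len(rows) != nrows or any(len(r) != ncols for r in rows):
        raise ValueError(f"{path}: data does not match {nrows} x {ncols} header")
    arr = np.vstack(rows)[::-1]
    nodata = header.get("nodata_value", NODATA)
    arr = np.where(arr == nodata, np.nan, arr)
    spec = GridSpec(header["xllcorner"], header["yllcorner"], header["cellsize"],
                    ncols, nrows)
    return spec, arr


def _is_number(tok: str) -> bool:
    try:
        float(tok)
        return True
    except ValueError:
        return False


def write_grid_csv(grid: ConcentrationGrid, path) -> None:
    grid.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# GeoJSON zones

def write_zones(grid: ConcentrationGrid, layer: str, path) -> None:
    """Dissolve contiguous same-class cells of a classification layer into
    polygons and write a GeoJSON FeatureCollection (one feature per class
    value; multi-part where a class is spatially disconnected)."""
    from shapely.geometry import box, mapping
    from shapely.ops import unary_union

    sp = grid.spec
    arr = grid.layers[layer]
    features = []
    flat = arr.ravel()
    valid = ~pd.isna(flat)
    if arr.dtype.kind == "f":
        valid &= np.isfinite(flat.astype(float))
    classes = sorted({v for v in flat[valid].tolist() if v != "" and v != 0})
    for value in classes:
        cells = []
        for i in range(sp.nrows):
            for j in range(sp.ncols):
                if arr[i, j] == value:
                    x0 = sp.xll + j * sp.cell_size
                    y0 = sp.yll + i * sp.cell_size
                    cells.append(box(x0, y0, x0 + sp.cell_size, y0 + sp.cell_size))
        if not cells:
            continue
        geom = unary_union(cells)
        features.append(
            {
                "type": "Feature",
                "properties": {"layer": layer, "class": value},
                "geometry": mapping(geom),
            }
        )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)
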