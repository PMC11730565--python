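"""Single-band concentration rasters and point sampling.

A :class:`RasterGrid` is a row-major, north-to-south 2-D grid of square
cells with a top-left origin, a nodata sentinel and a CRS tag.  Grids are
stored in a plain-text format (header of ncols/nrows/origin/cellsize/nodata/
crs followed by rows of values, northernmost first).

Point sampling is nearest-cell: each site receives the value of the cell
containing it under the half-open convention [left, right) × (top, bottom],
with an optional k×k neighbourhood mean.  No interpolation is applied —
interpolated concentration maps are already smooth products, and the goal is
to read them exactly as a GIS point-sampling tool would.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np

from .core import SampleTable, SoilRiskError

logger = logging.getLogger("soilrisk")

__all__ = ["RasterGrid", "locate_cell", "sample_raster_at_points", "read_grid", "write_grid"]


@dataclass
class RasterGrid:
    """Single-band grid: values[0, 0] is the north-west cell."""

    values: np.ndarray
    origin_x: float
    origin_y: float  # top (north) edge of the top row
    cell_size: float
    nodata: float = -9999.0
    crs_tag: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise SoilRiskError("raster values must be a 2-D array")
        if not self.cell_size > 0:
            raise SoilRiskError(f"cell_size must be > 0, got {self.cell_size}")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def extent(self) -> tuple[float, float]:
        """(width, height) in metres."""
        return (self.n_cols * self.cell_size, self.n_rows * self.cell_size)

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Meshgrid (X, Y) of cell-centre coordinates."""
        xs = self.origin_x + (np.arange(self.n_cols) + 0.5) * self.cell_size
        ys = self.origin_y - (np.arange(self.n_rows) + 0.5) * self.cell_size
        return np.meshgrid(xs, ys)

    def is_nodata(self, value: float) -> bool:
        return bool(np.isnan(value)) or value == self.nodata


def locate_cell(raster: RasterGrid, x: float, y: float) -> tuple[int, int] | None:
    """(row, col) of the cell containing (x, y), or None if outside.

    Cells are half-open: a point on the left/top edge of a cell belongs to
    it; points on the right/bottom edge of the whole extent are outside.
    """
    col = int(np.floor((x - raster.origin_x) / raster.cell_size))
    row = int(np.floor((raster.origin_y - y) / raster.cell_size))
    if 0 <= row < raster.n_rows and 0 <= col < raster.n_cols:
        return (row, col)
    return None


def _cell_value(raster: RasterGrid, row: int, col: int, window: int) -> float:
    if window <= 1:
        v = raster.values[row, col]
        return np.nan if raster.is_nodata(v) else float(v)
    h = window // 2
    block = raster.values[max(0, row - h): row + h + 1, max(0, col - h): col + h + 1]
    valid = block[~(np.isnan(block) | (block == raster.nodata))]
    return float(valid.mean()) if valid.size else np.nan


def sample_raster_at_points(
    rasters: Mapping[str, RasterGrid],
    points: SampleTable,
    window: int = 1,
    source_tag: str = "raster",
) -> tuple[SampleTable, dict]:
    """Read each element raster at every site location.

    Returns a new SampleTable (same site ids and coordinates) whose
    concentrations come from the containing raster cell, plus an extraction
    report counting outside-extent and nodata lookups per element.  ``window``
    (odd) requests a window×window mean around the containing cell.

    All rasters must share the points' CRS tag; a missing raster for a
    requested element is fatal.
    """
    if not rasters:
        raise SoilRiskError("no rasters supplied")
    if window < 1 or window % 2 == 0:
        raise SoilRiskError(f"window must be a positive odd integer, got {window}")
    for el, r in rasters.items():
        if r.crs_tag != points.crs_tag:
            raise SoilRiskError(
                f"CRS mismatch for {el}: raster {r.crs_tag!r} vs points {points.crs_tag!r}"
            )
    xs = points.data["x"].to_numpy(dtype=float)
    ys = points.data["y"].to_numpy(dtype=float)
    out = points.data[["x", "y"]].copy()
    report: dict = {"n_sites": len(points), "window": window, "elements": {}}
    for el, raster in rasters.items():
        vals = np.full(len(points), np.nan)
        n_outside = n_nodata = 0
        for i, (x, y) in enumerate(zip(xs, ys)):
            loc = locate_cell(raster, x, y)
            if loc is None:
                n_outside += 1
                continue
            v = _cell_value(raster, *loc, window)
            if np.isnan(v):
                n_nodata += 1
            else:
                vals[i] = v
        out[el] = vals
        report["elements"][el] = {"outside": n_outside, "nodata": n_nodata}
        if n_outside or n_nodata:
            logger.info("extraction %s: %d outside extent, %d nodata", el, n_outside, n_nodata)
    return SampleTable(out, source_tag=source_tag, crs_tag=points.crs_tag), report


# ---------------------------------------------------------------------------
# Plain-text grid format
# ---------------------------------------------------------------------------

def write_grid(raster: RasterGrid, path: str | Path) -> None:
    """Write a raster as a plain-text grid (header + rows, north first).

    NaN cells are written as the nodata sentinel.
    """
    path = Path(path)
    vals = np.where(np.isnan(raster.values), raster.nodata, raster.values)
    with open(path, "w") as fh:
        fh.write(f"ncols {raster.n_cols}\n")
        fh.write(f"nrows {raster.n_rows}\n")
        fh.write(f"xorigin {raster.origin_x!r}\n")
        fh.write(f"yorigin {raster.origin_y!r}\n")
        fh.write(f"cellsize {raster.cell_size!r}\n")
        fh.write(f"nodata_value {raster.nodata!r}\n")
        fh.write(f"crs {raster.crs_tag}\n")
        np.savetxt(fh, vals, fmt="%.10g")


def read_grid(path: str | Path) -> RasterGrid:
    """Read a plain-text grid written by :func:`write_grid`."""
    path = Path(path)
    header: dict[str, str] = {}
    with open(path) as fh:
        for _ in range(7):
            line = fh.readline()
            key, _, value = line.partition(" ")
            header[key.strip()] = value.strip()
        try:
            ncols = int(header["ncols"])
            nrows = int(header["nrows"])
            raster = RasterGrid(
                values=np.loadtxt(fh, ndmin=2),
                origin_x=float(header["xorigin"]),
                origin_y=float(header["yorigin"]),
                cell_size=float(header["cellsize"]),
                nodata=float(header["nodata_value"]),
                crs_tag=header.get("crs", ""),
            )
        except (KeyError, ValueError) as exc:
            raise SoilRiskError(f"{path}: malformed grid header ({exc})") from exc
    if raster.values.shape != (nrows, ncols):
        raise SoilRiskError(
            f"{path}: grid shape {raster.values.shape} does not match header ({nrows}, {ncols})"
        )
    return raster
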