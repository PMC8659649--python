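"""Planar raster grid geometry and plain-text raster I/O.

Coordinates are projected metres.  The grid origin sits at the north-west
corner; rows increase southwards and columns eastwards (raster convention).
A cell (r, c) covers the half-open square

    [x0 + c*cell, x0 + (c+1)*cell)  x  (y0 - (r+1)*cell, y0 - r*cell]

so a point on a shared edge belongs to the cell to its south-east, which
makes per-pixel assignment unambiguous.

Rasters are written as ESRI ASCII grids (``.asc``): a six-line text header
(ncols, nrows, xllcorner, yllcorner, cellsize, NODATA_value) followed by
row-major values, north row first.  The format carries the full grid
geometry, so layers round-trip without resampling.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import DataError

NODATA = -9999.0


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a regular raster grid in projected metres."""

    x0: float  # west edge (x of the north-west corner)
    y0: float  # north edge (y of the north-west corner)
    cell: float  # cell size, metres
    nrows: int
    ncols: int
    crs: str = "local-metre"

    def __post_init__(self) -> None:
        if self.cell <= 0:
            raise DataError(f"cell size must be positive, got {self.cell}")
        if self.nrows < 1 or self.ncols < 1:
            raise DataError("grid must have at least one row and column")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.nrows, self.ncols)

    @property
    def n_cells(self) -> int:
        return self.nrows * self.ncols

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, xmax, ymin, ymax) of the grid footprint."""
        return (
            self.x0,
            self.x0 + self.ncols * self.cell,
            self.y0 - self.nrows * self.cell,
            self.y0,
        )

    def cell_of(self, x, y):
        """Map point coordinates to (row, col) indices.

        Vectorized; raises :class:`DataError` if any point falls outside the
        grid footprint.
        """
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        tx = (x - self.x0) / self.cell
        ty = (self.y0 - y) / self.cell
        col = np.floor(tx).astype(int)
        # floor encodes (y - cell, y]: a point on a cell's bottom edge falls
        # in the row to the south, the north edge of the grid in row 0.
        row = np.floor(ty).astype(int)
        bad = (col < 0) | (col >= self.ncols) | (row < 0) | (row >= self.nrows)
        if np.any(bad):
            idx = np.argwhere(np.atleast_1d(bad)).ravel()[:5]
            raise DataError(f"point(s) outside grid footprint at indices {idx.tolist()}")
        if x.ndim == 0:
            return int(row), int(col)
        return row, col

    def cell_center(self, row, col):
        """Centre coordinates (x, y) of cell(s) (row, col)."""
        row = np.asarray(row)
        col = np.asarray(col)
        x = self.x0 + (col + 0.5) * self.cell
        y = self.y0 - (row + 0.5) * self.cell
        if row.ndim == 0:
            return float(x), float(y)
        return x, y

    def center_mesh(self) -> tuple[np.ndarray, np.ndarray]:
        """Full (nrows, ncols) meshes of cell-centre x and y coordinates."""
        rows, cols = np.meshgrid(
            np.arange(self.nrows), np.arange(self.ncols), indexing="ij"
        )
        return self.cell_center(rows, cols)

    def flat_index(self, row, col):
        return np.asarray(row) * self.ncols + np.asarray(col)


def write_ascii_grid(path: str | Path, grid: GridSpec, values: np.ndarray) -> None:
    """Write a 2-D layer as an ESRI ASCII grid; NaN becomes NODATA."""
    values = np.asarray(values, dtype=float)
    if values.shape != grid.shape:
        raise DataError(f"layer shape {values.shape} != grid shape {grid.shape}")
    out = np.where(np.isnan(values), NODATA, values)
    header = (
        f"ncols {grid.ncols}\n"
        f"nrows {grid.nrows}\n"
        f"xllcorner {grid.x0!r}\n"
        f"yllcorner {grid.y0 - grid.nrows * grid.cell!r}\n"
        f"cellsize {grid.cell!r}\n"
        f"NODATA_value {NODATA!r}\n"
    )
    path = Path(path)
    with path.open("w") as fh:
        fh.write(header)
        for row in out:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")


def read_ascii_grid(path: str | Path, crs: str = "local-metre") -> tuple[GridSpec, np.ndarray]:
    """Read an ESRI ASCII grid; NODATA becomes NaN."""
    path = Path(path)
    with path.open() as fh:
        header: dict[str, float] = {}
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        values = np.loadtxt(fh)
    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    values = values.reshape(nrows, ncols)
    cell = header["cellsize"]
    grid = GridSpec(
        x0=header["xllcorner"],
        y0=header["yllcorner"] + nrows * cell,
        cell=cell,
        nrows=nrows,
        ncols=ncols,
        crs=crs,
    )
    nodata = header.get("nodata_value", NODATA)
    values = np.where(values == nodata, np.nan, values)
    return grid, values
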