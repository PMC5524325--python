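"""Raster grid geometry and plain-text raster I/O.

All rasters in this package live on a regular grid in projected map
coordinates (meters), row-major from the north-west corner: row 0 is the
northernmost row, column 0 the westernmost column, x grows east and y grows
north.  External raster exchange uses the ESRI ASCII grid format (``.asc``),
a plain-text header-plus-matrix format readable by every desktop GIS.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["GridGeometry", "read_ascii_grid", "write_ascii_grid"]

NODATA_INT = -1
NODATA_FLOAT = -9999.0


@dataclass(frozen=True)
class GridGeometry:
    """Geometry of a regular raster grid.

    Parameters
    ----------
    origin_x, origin_y:
        Map coordinates of the north-west corner of the grid (the outer
        corner of cell ``[0, 0]``).
    cell_size:
        Cell edge length in meters (> 0, square cells).
    rows, cols:
        Grid shape.
    """

    origin_x: float
    origin_y: float
    cell_size: float
    rows: int
    cols: int

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError("cell_size must be > 0")
        if self.rows < 1 or self.cols < 1:
            raise ValueError("grid must have at least one row and column")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.rows, self.cols)

    @property
    def width(self) -> float:
        return self.cols * self.cell_size

    @property
    def height(self) -> float:
        return self.rows * self.cell_size

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the grid extent."""
        return (
            self.origin_x,
            self.origin_y - self.height,
            self.origin_x + self.width,
            self.origin_y,
        )

    @property
    def cell_area_ha(self) -> float:
        """Area of one cell in hectares (500-m cells -> 25 ha)."""
        return self.cell_size * self.cell_size / 10_000.0

    def x_centers(self) -> np.ndarray:
        return self.origin_x + (np.arange(self.cols) + 0.5) * self.cell_size

    def y_centers(self) -> np.ndarray:
        return self.origin_y - (np.arange(self.rows) + 0.5) * self.cell_size

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        return (
            self.origin_x + (col + 0.5) * self.cell_size,
            self.origin_y - (row + 0.5) * self.cell_size,
        )

    def index_of(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        """Row/col indices of the cells containing map points (vectorized)."""
        col = np.floor((np.asarray(x) - self.origin_x) / self.cell_size).astype(int)
        row = np.floor((self.origin_y - np.asarray(y)) / self.cell_size).astype(int)
        return row, col

    def contains(self, x, y) -> np.ndarray:
        xmin, ymin, xmax, ymax = self.bounds
        x = np.asarray(x)
        y = np.asarray(y)
        return (x >= xmin) & (x < xmax) & (y > ymin) & (y <= ymax)

    def coarsen(self, grain: float) -> "GridGeometry":
        """A coarser grid with cell size ``grain`` covering the same origin.

        ``grain`` must be a positive integer multiple of the cell size.
        """
        ratio = grain / self.cell_size
        if grain <= 0 or abs(ratio - round(ratio)) > 1e-9:
            raise ValueError(
                f"grain {grain} is not an integer multiple of cell size {self.cell_size}"
            )
        ratio = int(round(ratio))
        return GridGeometry(
            origin_x=self.origin_x,
            origin_y=self.origin_y,
            cell_size=float(grain),
            rows=self.rows // ratio,
            cols=self.cols // ratio,
        )


def write_ascii_grid(path, data: np.ndarray, geometry: GridGeometry, nodata=None) -> None:
    """Write a 2-D array as an ESRI ASCII grid (plain text)."""
    data = np.asarray(data)
    if data.shape != geometry.shape:
        raise ValueError("data shape does not match geometry")
    if nodata is None:
        nodata = NODATA_INT if np.issubdtype(data.dtype, np.integer) else NODATA_FLOAT
    xmin, ymin, _, _ = geometry.bounds
    fmt = "%d" if np.issubdtype(data.dtype, np.integer) else "%.6g"
    header = (
        f"ncols {geometry.cols}\n"
        f"nrows {geometry.rows}\n"
        f"xllcorner {xmin:.6f}\n"
        f"yllcorner {ymin:.6f}\n"
        f"cellsize {geometry.cell_size:.6f}\n"
        f"NODATA_value {nodata}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, data, fmt=fmt)


def read_ascii_grid(path) -> tuple[np.ndarray, GridGeometry, float]:
    """Read an ESRI ASCII grid; returns (data, geometry, nodata value)."""
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, value = fh.readline().split()
            header[key.lower()] = float(value)
        data = np.loadtxt(fh)
    rows = int(header["nrows"])
    cols = int(header["ncols"])
    cell = header["cellsize"]
    geometry = GridGeometry(
        origin_x=header["xllcorner"],
        origin_y=header["yllcorner"] + rows * cell,
        cell_size=cell,
        rows=rows,
        cols=cols,
    )
    return data.reshape(rows, cols), geometry, header.get("nodata_value", NODATA_FLOAT)
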