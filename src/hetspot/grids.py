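"""Shared raster grid primitives.

All analysis surfaces (expected cases, densities, p-value grids, hotspot
masks) live on one common grid: north-up, cell-center registered, in a
projected coordinate system with units of meters.  Internally ``values`` is
indexed ``[row, col]`` with row 0 at the *south* edge, so that
``y = y0 + (row + 0.5) * cell_size`` increases with the row index; writers
flip to the top-down order the ESRI ASCII format expects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["GridSpec", "Surface"]


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a raster grid: origin is the south-west corner."""

    x0: float
    y0: float
    ncols: int
    nrows: int
    cell_size: float

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.ncols < 1 or self.nrows < 1:
            raise ValueError("grid must have at least one cell")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.nrows, self.ncols)

    @property
    def n_cells(self) -> int:
        return self.nrows * self.ncols

    @property
    def cell_area(self) -> float:
        return self.cell_size * self.cell_size

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax)."""
        return (
            self.x0,
            self.y0,
            self.x0 + self.ncols * self.cell_size,
            self.y0 + self.nrows * self.cell_size,
        )

    def x_centers(self) -> np.ndarray:
        return self.x0 + (np.arange(self.ncols) + 0.5) * self.cell_size

    def y_centers(self) -> np.ndarray:
        return self.y0 + (np.arange(self.nrows) + 0.5) * self.cell_size

    def center_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Meshgrid arrays (X, Y) of cell-center coordinates, shape (nrows, ncols)."""
        return np.meshgrid(self.x_centers(), self.y_centers())

    def index_of(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        """(row, col) of the cell containing each (x, y); no bounds check."""
        col = np.floor((np.asarray(x) - self.x0) / self.cell_size).astype(int)
        row = np.floor((np.asarray(y) - self.y0) / self.cell_size).astype(int)
        return row, col

    def contains(self, x, y) -> np.ndarray:
        xmin, ymin, xmax, ymax = self.extent
        x = np.asarray(x)
        y = np.asarray(y)
        return (x >= xmin) & (x < xmax) & (y >= ymin) & (y < ymax)

    @staticmethod
    def from_extent(extent, cell_size: float) -> "GridSpec":
        xmin, ymin, xmax, ymax = extent
        if xmax <= xmin or ymax <= ymin:
            raise ValueError("degenerate extent")
        ncols = int(np.ceil((xmax - xmin) / cell_size))
        nrows = int(np.ceil((ymax - ymin) / cell_size))
        return GridSpec(xmin, ymin, ncols, nrows, cell_size)


@dataclass
class Surface:
    """A scalar field on a :class:`GridSpec`; NaN marks undefined cells."""

    grid: GridSpec
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"values shape {self.values.shape} != grid shape {self.grid.shape}"
            )

    @staticmethod
    def zeros(grid: GridSpec) -> "Surface":
        return Surface(grid, np.zeros(grid.shape))

    @staticmethod
    def full(grid: GridSpec, value: float) -> "Surface":
        return Surface(grid, np.full(grid.shape, float(value)))

    def copy(self) -> "Surface":
        return Surface(self.grid, self.values.copy())

    def sum(self) -> float:
        return float(np.nansum(self.values))

    def same_grid(self, other: "Surface") -> bool:
        return self.grid == other.grid

    def require_same_grid(self, other: "Surface") -> None:
        if not self.same_grid(other):
            raise ValueError("surfaces are on different grids")

    def value_at(self, x: float, y: float) -> float:
        row, col = self.grid.index_of(x, y)
        return float(self.values[row, col])

    # ---- ESRI ASCII grid IO (text raster; nodata encodes NaN) ----

    def write_ascii(self, path, nodata: float = -9999.0) -> None:
        g = self.grid
        vals = np.where(np.isnan(self.values), nodata, self.values)
        header = (
            f"ncols {g.ncols}\n"
            f"nrows {g.nrows}\n"
            f"xllcorner {g.x0!r}\n"
            f"yllcorner {g.y0!r}\n"
            f"cellsize {g.cell_size!r}\n"
            f"NODATA_value {nodata!r}\n"
        )
        body = "\n".join(
            " ".join(repr(float(v)) for v in row) for row in vals[::-1]
        )
        Path(path).write_text(header + body + "\n")

    @staticmethod
    def read_ascii(path) -> "Surface":
        lines = Path(path).read_text().splitlines()
        hdr = {}
        i = 0
        while i < len(lines):
            parts = lines[i].split()
            if len(parts) == 2 and parts[0].lower() in {
                "ncols", "nrows", "xllcorner", "yllcorner", "cellsize",
                "nodata_value",
            }:
                hdr[parts[0].lower()] = parts[1]
                i += 1
            else:
                break
        grid = GridSpec(
            float(hdr["xllcorner"]),
            float(hdr["yllcorner"]),
            int(hdr["ncols"]),
            int(hdr["nrows"]),
            float(hdr["cellsize"]),
        )
        data = np.loadtxt(lines[i:], ndmin=2)[::-1]
        if "nodata_value" in hdr:
            nodata = float(hdr["nodata_value"])
            data = np.where(data == nodata, np.nan, data)
        return Surface(grid, data)
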