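"""Planar raster container and plain-text (ESRI ASCII grid) I/O.

All layers in this package live on a regular north-up grid in projected
metric coordinates.  A :class:`Raster` is a float array plus the grid
geometry (top-left corner origin, square cell size); nodata is carried as
NaN in memory and as an explicit ``NODATA_value`` on disk.  Pixel indexing
is row-major from the top-left with half-open cell extents; coordinates
returned by :meth:`Raster.cell_center` are cell centers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["Raster", "GridMismatchError"]


class GridMismatchError(ValueError):
    """Two rasters do not share the same grid geometry."""


@dataclass
class Raster:
    """A single-band raster on a square-celled, axis-aligned grid.

    Parameters
    ----------
    data
        2-D float array, row 0 at the top (largest y). NaN marks nodata.
    cell_size
        Cell edge length in meters.
    origin
        (x, y) of the *top-left corner* of the grid.
    """

    data: np.ndarray
    cell_size: float = 30.0
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("raster data must be 2-D")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    # ------------------------------------------------------------------ geometry
    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    @property
    def valid(self) -> np.ndarray:
        """Boolean mask of non-nodata cells."""
        return ~np.isnan(self.data)

    def same_grid(self, other: "Raster") -> bool:
        return (
            self.shape == other.shape
            and np.isclose(self.cell_size, other.cell_size)
            and np.allclose(self.origin, other.origin)
        )

    def require_same_grid(self, other: "Raster") -> None:
        if not self.same_grid(other):
            raise GridMismatchError(
                f"grid mismatch: {self.shape}/{self.cell_size}/{self.origin} vs "
                f"{other.shape}/{other.cell_size}/{other.origin}"
            )

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        x0, y0 = self.origin
        return (x0 + (col + 0.5) * self.cell_size, y0 - (row + 0.5) * self.cell_size)

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Arrays (X, Y) of cell-center coordinates, same shape as data."""
        nrow, ncol = self.shape
        x0, y0 = self.origin
        xs = x0 + (np.arange(ncol) + 0.5) * self.cell_size
        ys = y0 - (np.arange(nrow) + 0.5) * self.cell_size
        return np.meshgrid(xs, ys)

    def index_of(self, x: float, y: float) -> tuple[int, int]:
        """Row/col of the cell containing point (x, y); may be out of bounds."""
        x0, y0 = self.origin
        col = int(np.floor((x - x0) / self.cell_size))
        row = int(np.floor((y0 - y) / self.cell_size))
        return row, col

    def contains(self, x: float, y: float) -> bool:
        row, col = self.index_of(x, y)
        nrow, ncol = self.shape
        return 0 <= row < nrow and 0 <= col < ncol

    def like(self, data: np.ndarray) -> "Raster":
        """New raster with the same geometry carrying ``data``."""
        if data.shape != self.shape:
            raise ValueError("data shape does not match grid")
        return Raster(np.asarray(data, dtype=float), self.cell_size, self.origin)

    def copy(self) -> "Raster":
        return Raster(self.data.copy(), self.cell_size, self.origin)

    # ------------------------------------------------------------------ I/O
    def write_ascii(self, path: str | Path, nodata: float = -9999.0) -> None:
        """Write as ESRI ASCII grid (plain text)."""
        nrow, ncol = self.shape
        x0, y0 = self.origin
        yll = y0 - nrow * self.cell_size
        out = np.where(np.isnan(self.data), nodata, self.data)
        header = (
            f"ncols {ncol}\nnrows {nrow}\n"
            f"xllcorner {x0}\nyllcorner {yll}\n"
            f"cellsize {self.cell_size}\nNODATA_value {nodata}\n"
        )
        with open(path, "w") as fh:
            fh.write(header)
            np.savetxt(fh, out, fmt="%.8g")

    @classmethod
    def read_ascii(cls, path: str | Path) -> "Raster":
        header: dict[str, float] = {}
        with open(path) as fh:
            for _ in range(6):
                key, val = fh.readline().split()
                header[key.lower()] = float(val)
            data = np.loadtxt(fh)
        data = np.atleast_2d(data)
        nodata = header.get("nodata_value", -9999.0)
        data[data == nodata] = np.nan
        cell = header["cellsize"]
        x0 = header["xllcorner"]
        y0 = header["yllcorner"] + header["nrows"] * cell
        return cls(data, cell, (x0, y0))


@dataclass
class CovariateStack:
    """Named co-registered raster layers sharing one grid and nodata mask."""

    layers: dict[str, Raster]
    aux: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.layers:
            raise ValueError("empty stack")
        first = next(iter(self.layers.values()))
        for name, r in self.layers.items():
            if not first.same_grid(r):
                raise GridMismatchError(f"layer {name!r} not on the common grid")

    @property
    def grid(self) -> Raster:
        return next(iter(self.layers.values()))

    @property
    def names(self) -> list[str]:
        return list(self.layers)

    def __getitem__(self, name: str) -> Raster:
        return self.layers[name]

    def __contains__(self, name: str) -> bool:
        return name in self.layers

    def subset(self, names: list[str]) -> "CovariateStack":
        return CovariateStack({n: self.layers[n] for n in names}, aux=self.aux)

    def valid_mask(self) -> np.ndarray:
        mask = np.ones(self.grid.shape, dtype=bool)
        for r in self.layers.values():
            mask &= r.valid
        return mask

    def values_at(self, x: np.ndarray, y: np.ndarray, names: list[str] | None = None) -> np.ndarray:
        """Covariate matrix (n points x n layers) sampled at point coordinates.

        Points outside the grid get NaN rows.
        """
        names = names or self.names
        g = self.grid
        x = np.atleast_1d(np.asarray(x, float))
        y = np.atleast_1d(np.asarray(y, float))
        x0, y0 = g.origin
        col = np.floor((x - x0) / g.cell_size).astype(int)
        row = np.floor((y0 - y) / g.cell_size).astype(int)
        nrow, ncol = g.shape
        inside = (row >= 0) & (row < nrow) & (col >= 0) & (col < ncol)
        out = np.full((x.size, len(names)), np.nan)
        for k, name in enumerate(names):
            out[inside, k] = self.layers[name].data[row[inside], col[inside]]
        return out

    def write_dir(self, directory: str | Path) -> list[Path]:
        """One .asc per layer, named <layer>.asc."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = []
        for name, r in self.layers.items():
            p = directory / f"{name}.asc"
            r.write_ascii(p)
            paths.append(p)
        return paths

    @classmethod
    def read_dir(cls, directory: str | Path, names: list[str]) -> "CovariateStack":
        directory = Path(directory)
        return cls({n: Raster.read_ascii(directory / f"{n}.asc") for n in names})
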