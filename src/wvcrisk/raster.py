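"""Gridded covariate layers.

A :class:`CovariateRaster` is a named single-band grid in a projected
coordinate system (metres).  Cells are half-open rectangles
``[x, x + cell) x [y, y + cell)`` so every point belongs to exactly one
cell.  Values are stored north-up: row 0 of the array is the top
(largest y) row, matching the ESRI ASCII grid layout used on disk.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = ["CovariateRaster", "RasterBoundsError", "read_ascii_grid", "write_ascii_grid"]

_NODATA = -9999.0


class RasterBoundsError(ValueError):
    """Point falls outside the raster extent."""


@dataclass
class CovariateRaster:
    """A named gridded environmental or anthropogenic layer.

    Parameters
    ----------
    name : str
        Layer name (e.g. ``"ELEV"``).
    values : ndarray of shape (n_rows, n_cols)
        Cell values, row 0 at the top (north).  Missing cells are NaN.
    origin : (float, float)
        Lower-left corner ``(x, y)`` in projected metres.
    cell_size : float
        Cell edge length in metres.
    """

    name: str
    values: np.ndarray
    origin: tuple[float, float]
    cell_size: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("raster values must be 2-D")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the full extent."""
        x0, y0 = self.origin
        return (x0, y0, x0 + self.n_cols * self.cell_size, y0 + self.n_rows * self.cell_size)

    def cell_index(self, x: float, y: float) -> tuple[int, int]:
        """(row, col) of the half-open cell containing the point.

        Cells are half-open internally; the outer top/right boundary is
        closed, so points exactly on it belong to the last row/column.
        """
        x0, y0 = self.origin
        xmin, ymin, xmax, ymax = self.bounds
        if not (xmin <= x <= xmax and ymin <= y <= ymax):
            raise RasterBoundsError(
                f"point ({x}, {y}) outside raster '{self.name}' extent {self.bounds}"
            )
        col = min(int(np.floor((x - x0) / self.cell_size)), self.n_cols - 1)
        row_from_bottom = min(int(np.floor((y - y0) / self.cell_size)), self.n_rows - 1)
        return self.n_rows - 1 - row_from_bottom, col

    def sample(self, x: float, y: float) -> float:
        """Value of the cell containing (x, y); nearest-cell, no interpolation.

        Returns NaN for a no-data cell; raises :class:`RasterBoundsError`
        outside the extent.
        """
        r, c = self.cell_index(x, y)
        return float(self.values[r, c])

    def sample_points(self, xs: np.ndarray, ys: np.ndarray) -> np.ndarray:
        """Vectorised :meth:`sample` over coordinate arrays."""
        xs = np.asarray(xs, dtype=float)
        ys = np.asarray(ys, dtype=float)
        x0, y0 = self.origin
        xmin, ymin, xmax, ymax = self.bounds
        inside = (xs >= xmin) & (xs <= xmax) & (ys >= ymin) & (ys <= ymax)
        if not inside.all():
            bad = np.flatnonzero(~inside)[:5]
            raise RasterBoundsError(
                f"{(~inside).sum()} point(s) outside raster '{self.name}', "
                f"first offending indices {bad.tolist()}"
            )
        cols = np.minimum(np.floor((xs - x0) / self.cell_size).astype(int), self.n_cols - 1)
        rows = self.n_rows - 1 - np.minimum(
            np.floor((ys - y0) / self.cell_size).astype(int), self.n_rows - 1
        )
        return self.values[rows, cols]


def write_ascii_grid(raster: CovariateRaster, path: str | Path) -> None:
    """Write a raster as an ESRI ASCII grid (.asc)."""
    path = Path(path)
    vals = np.where(np.isnan(raster.values), _NODATA, raster.values)
    header = (
        f"NCOLS {raster.n_cols}\n"
        f"NROWS {raster.n_rows}\n"
        f"XLLCORNER {raster.origin[0]!r}\n"
        f"YLLCORNER {raster.origin[1]!r}\n"
        f"CELLSIZE {raster.cell_size!r}\n"
        f"NODATA_value {_NODATA}\n"
    )
    with path.open("w") as fh:
        fh.write(header)
        np.savetxt(fh, vals, fmt="%.10g")


def read_ascii_grid(path: str | Path, name: str | None = None) -> CovariateRaster:
    """Read an ESRI ASCII grid written by :func:`write_ascii_grid`."""
    path = Path(path)
    meta: dict[str, float] = {}
    with path.open() as fh:
        lines = fh.readlines()
    n_header = 0
    for line in lines:
        parts = line.split()
        if len(parts) == 2 and parts[0].upper() in {
            "NCOLS", "NROWS", "XLLCORNER", "YLLCORNER", "CELLSIZE", "NODATA_VALUE",
        }:
            meta[parts[0].upper()] = float(parts[1])
            n_header += 1
        else:
            break
    values = np.loadtxt(lines[n_header:], dtype=float)
    values = np.atleast_2d(values)
    nodata = meta.get("NODATA_VALUE", _NODATA)
    values = np.where(values == nodata, np.nan, values)
    return CovariateRaster(
        name=name or path.stem,
        values=values,
        origin=(meta["XLLCORNER"], meta["YLLCORNER"]),
        cell_size=meta["CELLSIZE"],
    )
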