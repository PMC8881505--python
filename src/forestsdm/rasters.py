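"""Minimal ESRI ASCII grid raster container.

The pipeline exchanges climate and landcover layers as plain-text ``.asc``
grids (ncols/nrows/xllcorner/yllcorner/cellsize header followed by rows from
the top of the map down). Coordinates are planar metres throughout; cell (0,0)
of the array is the *top-left* map cell, matching the on-disk row order.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = ["Raster", "read_ascii_grid", "write_ascii_grid"]

_HEADER_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize")


@dataclass
class Raster:
    """A single-band raster on a regular grid in projected metre coordinates."""

    values: np.ndarray  # shape (nrows, ncols), row 0 = northernmost
    xll: float  # x of the lower-left corner (m)
    yll: float  # y of the lower-left corner (m)
    cellsize: float  # cell edge length (m)
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("raster values must be a 2-D array")
        if self.cellsize <= 0:
            raise ValueError("cellsize must be positive")

    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, xmax, ymin, ymax) of the covered area."""
        return (
            self.xll,
            self.xll + self.ncols * self.cellsize,
            self.yll,
            self.yll + self.nrows * self.cellsize,
        )

    def cell_index(self, x, y):
        """Row/column of the cell containing each point (nearest-cell lookup).

        Returns integer arrays (row, col); points outside the extent get -1.
        """
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        col = np.floor((x - self.xll) / self.cellsize).astype(int)
        row_from_bottom = np.floor((y - self.yll) / self.cellsize).astype(int)
        row = self.nrows - 1 - row_from_bottom
        inside = (col >= 0) & (col < self.ncols) & (row >= 0) & (row < self.nrows)
        return np.where(inside, row, -1), np.where(inside, col, -1)

    def extract(self, x, y) -> np.ndarray:
        """Nearest-cell values at the given points; NaN outside the extent."""
        row, col = self.cell_index(x, y)
        out = np.full(np.shape(row), np.nan, dtype=float)
        inside = row >= 0
        out[inside] = self.values[row[inside], col[inside]]
        out[np.isclose(out, self.nodata)] = np.nan
        return out

    def cell_centres(self) -> tuple[np.ndarray, np.ndarray]:
        """Meshgrid (x, y) of all cell centres, same shape as ``values``."""
        xs = self.xll + (np.arange(self.ncols) + 0.5) * self.cellsize
        ys_top_down = self.yll + (self.nrows - np.arange(self.nrows) - 0.5) * self.cellsize
        return np.meshgrid(xs, ys_top_down)


def read_ascii_grid(path: str | Path) -> Raster:
    path = Path(path)
    header: dict[str, float] = {}
    with path.open() as fh:
        pos = fh.tell()
        for _ in range(6):
            pos = fh.tell()
            line = fh.readline()
            parts = line.split()
            if len(parts) == 2 and parts[0].lower() in _HEADER_KEYS + ("nodata_value",):
                header[parts[0].lower()] = float(parts[1])
            else:
                fh.seek(pos)
                break
        body = np.loadtxt(fh)
    for key in _HEADER_KEYS:
        if key not in header:
            raise ValueError(f"{path}: missing ASCII grid header field {key!r}")
    values = np.atleast_2d(body).reshape(int(header["nrows"]), int(header["ncols"]))
    return Raster(
        values=values,
        xll=header["xllcorner"],
        yll=header["yllcorner"],
        cellsize=header["cellsize"],
        nodata=header.get("nodata_value", -9999.0),
    )


def write_ascii_grid(raster: Raster, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"ncols {raster.ncols}\n")
        fh.write(f"nrows {raster.nrows}\n")
        fh.write(f"xllcorner {raster.xll:.6f}\n")
        fh.write(f"yllcorner {raster.yll:.6f}\n")
        fh.write(f"cellsize {raster.cellsize:.6f}\n")
        fh.write(f"NODATA_value {raster.nodata:g}\n")
        np.savetxt(fh, np.where(np.isnan(raster.values), raster.nodata, raster.values), fmt="%.6g")
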