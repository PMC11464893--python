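"""In-memory multi-band raster container with simple affine georeferencing.

A :class:`LandscapeStack` holds named 2-D float bands on a shared north-up
grid (square pixels), plus named point-feature sets (leks, springs, stream
vertices).  World coordinates follow GIS convention: the origin is the
upper-left corner of the grid, x increases east, y increases north (so row
index increases as y decreases).

Rasters are serialized as ESRI ASCII grids (plain text), one file per band,
and feature sets as CSV point tables.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["LandscapeStack", "read_ascii_grid", "write_ascii_grid"]


@dataclass
class LandscapeStack:
    """Named multi-band raster stack on a shared grid.

    Parameters
    ----------
    bands
        Mapping from band name to 2-D float array.  Temporally varying
        covariates use one band per year, named ``"<name>@<year>"``.
    pixel_size
        Edge length of a (square) pixel in metres.
    origin
        ``(x, y)`` world coordinates of the upper-left corner of the grid.
    features
        Mapping from feature-set name (e.g. ``"leks"``) to an ``(n, 2)``
        array of ``(x, y)`` world coordinates.
    """

    bands: dict[str, np.ndarray]
    pixel_size: float = 30.0
    origin: tuple[float, float] = (0.0, 0.0)
    features: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        shapes = {b.shape for b in self.bands.values()}
        if len(shapes) > 1:
            raise ValueError(f"bands have inconsistent shapes: {shapes}")

    # -- grid geometry ---------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.bands.values())).shape

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the grid in world coordinates."""
        nr, nc = self.shape
        x0, y0 = self.origin
        return (x0, y0 - nr * self.pixel_size, x0 + nc * self.pixel_size, y0)

    def xy_to_rowcol(self, x, y):
        """Map world coordinates to (row, col) pixel indices (no bounds check)."""
        x0, y0 = self.origin
        col = np.floor((np.asarray(x) - x0) / self.pixel_size).astype(int)
        row = np.floor((y0 - np.asarray(y)) / self.pixel_size).astype(int)
        return row, col

    def rowcol_to_xy(self, row, col):
        """World coordinates of pixel centers."""
        x0, y0 = self.origin
        x = x0 + (np.asarray(col) + 0.5) * self.pixel_size
        y = y0 - (np.asarray(row) + 0.5) * self.pixel_size
        return x, y

    def contains(self, x, y) -> np.ndarray:
        xmin, ymin, xmax, ymax = self.extent
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return (x >= xmin) & (x < xmax) & (y > ymin) & (y <= ymax)

    # -- band access -----------------------------------------------------
    def band(self, name: str, year: int | None = None) -> np.ndarray:
        """Return a band, resolving temporal bands by year when present."""
        if year is not None and f"{name}@{year}" in self.bands:
            return self.bands[f"{name}@{year}"]
        if name in self.bands:
            return self.bands[name]
        raise KeyError(f"band {name!r} (year={year}) not in stack")

    def band_names(self) -> list[str]:
        return list(self.bands)

    def extract(self, name: str, x, y, year: int | None = None) -> np.ndarray:
        """Sample a band at world coordinates (nearest pixel)."""
        arr = self.band(name, year=year)
        row, col = self.xy_to_rowcol(x, y)
        inside = (row >= 0) & (row < arr.shape[0]) & (col >= 0) & (col < arr.shape[1])
        if not np.all(inside):
            raise ValueError("extraction coordinates fall outside the raster")
        return arr[row, col]

    # -- I/O ---------------------------------------------------------------
    def write(self, directory: str) -> None:
        """Write one ASCII grid per band and one CSV per feature set."""
        os.makedirs(directory, exist_ok=True)
        for name, arr in self.bands.items():
            fname = name.replace("@", "_yr") + ".asc"
            write_ascii_grid(os.path.join(directory, fname), arr, self.pixel_size, self.origin)
        for name, pts in self.features.items():
            pd.DataFrame(pts, columns=["x", "y"]).to_csv(
                os.path.join(directory, f"{name}.csv"), index=False
            )


def write_ascii_grid(path: str, arr: np.ndarray, pixel_size: float,
                     origin: tuple[float, float], nodata: float = -9999.0) -> None:
    nr, nc = arr.shape
    x0, y0 = origin
    out = np.where(np.isfinite(arr), arr, nodata)
    header = (
        f"ncols {nc}\nnrows {nr}\nxllcorner {x0}\nyllcorner {y0 - nr * pixel_size}\n"
        f"cellsize {pixel_size}\nNODATA_value {nodata}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, out, fmt="%.8g")


def read_ascii_grid(path: str) -> tuple[np.ndarray, float, tuple[float, float]]:
    """Read an ESRI ASCII grid; returns (array, pixel_size, upper-left origin)."""
    meta: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            meta[key.lower()] = float(val)
        arr = np.loadtxt(fh)
    arr = arr.reshape(int(meta["nrows"]), int(meta["ncols"]))
    nodata = meta.get("nodata_value")
    if nodata is not None:
        arr = np.where(arr == nodata, np.nan, arr)
    origin = (meta["xllcorner"], meta["yllcorner"] + meta["nrows"] * meta["cellsize"])
    return arr, meta["cellsize"], origin
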