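"""Canopy height model (CHM) raster container and text/TIFF I/O.

A CHM is a gridded surface of vegetation height (m) over a plot, here always
in plot-local coordinates with the origin at the south-west corner.  Rows run
north to south (row 0 is the northern edge), columns west to east, so the
array renders the right way up with ``plt.imshow``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["CHMRaster"]


@dataclass
class CHMRaster:
    """A single-band canopy height raster.

    Parameters
    ----------
    values
        2-D array of heights in metres, shape ``(nrows, ncols)``, row 0 at
        the northern edge.  Negative values are clamped to zero on
        construction and counted in :attr:`n_clamped`.
    resolution
        Pixel size in metres (square pixels, pixel-is-area).
    origin
        ``(x, y)`` of the south-west corner in metres.
    """

    values: np.ndarray
    resolution: float = 0.1
    origin: tuple[float, float] = (0.0, 0.0)
    n_clamped: int = field(default=0, compare=False)

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise ValueError(f"resolution must be > 0, got {self.resolution}")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("CHM values must be a 2-D array")
        neg = self.values < 0
        if neg.any():
            self.n_clamped = int(neg.sum())
            self.values = np.where(neg, 0.0, self.values)

    # -- geometry ----------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def extent(self) -> tuple[float, float]:
        """(width, height) of the raster footprint in metres."""
        nr, nc = self.shape
        return nc * self.resolution, nr * self.resolution

    def pixel_to_world(self, row, col) -> tuple[np.ndarray, np.ndarray]:
        """Centre coordinates (x, y) in metres of pixel ``(row, col)``."""
        nr, _ = self.shape
        x = self.origin[0] + (np.asarray(col) + 0.5) * self.resolution
        y = self.origin[1] + (nr - np.asarray(row) - 0.5) * self.resolution
        return x, y

    def world_to_pixel(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        """Pixel indices (row, col) containing world point ``(x, y)``."""
        nr, nc = self.shape
        col = np.floor((np.asarray(x) - self.origin[0]) / self.resolution).astype(int)
        row = nr - 1 - np.floor((np.asarray(y) - self.origin[1]) / self.resolution).astype(int)
        return np.clip(row, 0, nr - 1), np.clip(col, 0, nc - 1)

    # -- I/O ---------------------------------------------------------------
    def to_ascii(self, path) -> None:
        """Write as an ESRI ASCII grid (.asc)."""
        nr, nc = self.shape
        header = (
            f"ncols {nc}\nnrows {nr}\n"
            f"xllcorner {self.origin[0]:.6f}\nyllcorner {self.origin[1]:.6f}\n"
            f"cellsize {self.resolution:.6f}\nNODATA_value -9999\n"
        )
        with open(path, "w") as fh:
            fh.write(header)
            np.savetxt(fh, self.values, fmt="%.4f")

    @classmethod
    def from_ascii(cls, path) -> "CHMRaster":
        """Read an ESRI ASCII grid; negative heights are clamped to 0."""
        meta = {}
        with open(path) as fh:
            lines = fh.readlines()
        n_header = 0
        for line in lines:
            parts = line.split()
            if len(parts) == 2 and parts[0].lower() in {
                "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"
            }:
                meta[parts[0].lower()] = float(parts[1])
                n_header += 1
            else:
                break
        values = np.loadtxt(lines[n_header:])
        values = np.atleast_2d(values)
        nodata = meta.get("nodata_value")
        if nodata is not None:
            values = np.where(values == nodata, 0.0, values)
        raster = cls(
            values=values,
            resolution=meta.get("cellsize", 0.1),
            origin=(meta.get("xllcorner", 0.0), meta.get("yllcorner", 0.0)),
        )
        if raster.n_clamped:
            warnings.warn(f"clamped {raster.n_clamped} negative CHM pixels to 0")
        return raster

    def to_tiff(self, path) -> None:
        """Write as a single-band float32 TIFF (tifffile backend).

        Plot-local georeferencing (resolution, origin) is stored as JSON in
        the ImageDescription tag; no CRS is attached.
        """
        import tifffile

        desc = json.dumps({"resolution": self.resolution, "origin": list(self.origin)})
        tifffile.imwrite(path, self.values.astype(np.float32), description=desc)

    @classmethod
    def from_tiff(cls, path) -> "CHMRaster":
        import tifffile

        with tifffile.TiffFile(path) as tif:
            values = tif.asarray()
            desc = tif.pages[0].description or "{}"
        try:
            meta = json.loads(desc)
        except json.JSONDecodeError:
            meta = {}
        return cls(
            values=np.asarray(values, dtype=float),
            resolution=float(meta.get("resolution", 0.1)),
            origin=tuple(meta.get("origin", (0.0, 0.0))),
        )

    @classmethod
    def read(cls, path) -> "CHMRaster":
        path = Path(path)
        if path.suffix.lower() in {".tif", ".tiff"}:
            return cls.from_tiff(path)
        return cls.from_ascii(path)

    def write(self, path) -> None:
        path = Path(path)
        if path.suffix.lower() in {".tif", ".tiff"}:
            self.to_tiff(path)
        else:
            self.to_ascii(path)
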