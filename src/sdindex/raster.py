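"""Minimal single-band raster container with an affine georeferencing model.

The affine transform follows the usual north-up GIS convention
``x = c + a*col``, ``y = f + e*row`` with ``a > 0`` (cell width) and
``e < 0`` (negative cell height); rotation terms are not supported.
Coordinates refer to cell *edges* at the grid origin (upper-left corner of
cell (0, 0)), cell centroids sit half a cell in.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np

from .errors import InputError
from .projection import VALID_CRS


@dataclass
class Raster:
    values: np.ndarray
    transform: Tuple[float, float, float, float, float, float]  # (a, b, c, d, e, f)
    crs: str
    nodata: Optional[float] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise InputError(f"raster must be single-band 2-D, got shape {self.values.shape}")
        a, b, c, d, e, f = self.transform
        if b != 0.0 or d != 0.0:
            raise InputError("rotated rasters are not supported")
        if a <= 0 or e >= 0:
            raise InputError("expected north-up transform (a > 0, e < 0)")
        if self.crs not in VALID_CRS:
            raise InputError(f"unknown raster crs {self.crs!r}")

    # -- geometry of the grid -------------------------------------------------

    @property
    def height(self) -> int:
        return self.values.shape[0]

    @property
    def width(self) -> int:
        return self.values.shape[1]

    @property
    def bounds(self) -> Tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the full grid footprint."""
        a, _, c, _, e, f = self.transform
        return (c, f + e * self.height, c + a * self.width, f)

    def cell_centroids(self) -> Tuple[np.ndarray, np.ndarray]:
        """Arrays (xs[width], ys[height]) of cell-centroid coordinates."""
        a, _, c, _, e, f = self.transform
        xs = c + a * (np.arange(self.width) + 0.5)
        ys = f + e * (np.arange(self.height) + 0.5)
        return xs, ys

    def cell_bounds(self, row: int, col: int) -> Tuple[float, float, float, float]:
        a, _, c, _, e, f = self.transform
        x0 = c + a * col
        y1 = f + e * row
        return (x0, y1 + e, x0 + a, y1)

    def index(self, x: float, y: float) -> Tuple[int, int]:
        """(row, col) of the cell containing point (x, y); may be out of range."""
        a, _, c, _, e, f = self.transform
        return int(np.floor((y - f) / e)), int(np.floor((x - c) / a))

    # -- values ---------------------------------------------------------------

    def mask(self) -> np.ndarray:
        """Boolean array, True where the cell holds valid data."""
        if self.nodata is None:
            return np.ones(self.values.shape, dtype=bool)
        if np.issubdtype(self.values.dtype, np.floating) and np.isnan(self.nodata):
            return ~np.isnan(self.values)
        return self.values != self.nodata

    def aligned_with(self, other: "Raster") -> bool:
        return (
            self.values.shape == other.values.shape
            and np.allclose(self.transform, other.transform)
            and self.crs == other.crs
        )


def full_like(template: Raster, fill: float, dtype=np.float64) -> Raster:
    return Raster(
        np.full(template.values.shape, fill, dtype=dtype),
        template.transform,
        template.crs,
        template.nodata,
    )
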