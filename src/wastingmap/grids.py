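"""A minimal planar raster container used across the pipeline.

Pixels are square cells of side ``resolution`` km; ``values`` is stored
(ny, nx) row-major with row 0 at the smallest y.  Pixel centers are at
origin + resolution * (index + 0.5).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class Grid:
    x0: float  # lower-left corner (not center) of the grid, km
    y0: float
    resolution: float
    values: np.ndarray  # (ny, nx)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")

    @property
    def ny(self) -> int:
        return self.values.shape[0]

    @property
    def nx(self) -> int:
        return self.values.shape[1]

    def x_centers(self) -> np.ndarray:
        return self.x0 + self.resolution * (np.arange(self.nx) + 0.5)

    def y_centers(self) -> np.ndarray:
        return self.y0 + self.resolution * (np.arange(self.ny) + 0.5)

    def centers(self):
        """Flattened (x, y) pixel-center coordinates, row-major."""
        X, Y = np.meshgrid(self.x_centers(), self.y_centers())
        return X.ravel(), Y.ravel()

    def same_geometry(self, other: "Grid", tol: float = 1e-9) -> bool:
        return (
            self.values.shape == other.values.shape
            and abs(self.x0 - other.x0) <= tol
            and abs(self.y0 - other.y0) <= tol
            and abs(self.resolution - other.resolution) <= tol
        )

    def with_values(self, values: np.ndarray) -> "Grid":
        values = np.asarray(values, dtype=float)
        if values.shape != self.values.shape:
            raise ValueError("replacement values must keep the grid shape")
        return Grid(self.x0, self.y0, self.resolution, values)

    def interp(self, x, y) -> np.ndarray:
        """Bilinear interpolation at planar points, clamped to the grid."""
        from scipy.interpolate import RegularGridInterpolator

        f = RegularGridInterpolator(
            (self.y_centers(), self.x_centers()),
            self.values,
            bounds_error=False,
            fill_value=None,
        )
        return f(np.column_stack([np.atleast_1d(y), np.atleast_1d(x)]))
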