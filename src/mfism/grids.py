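"""Square sampling grids shared by the design and optics layers.

Physical coordinates are in micrometres, origin at the grid centre,
x increasing with column index (rightward) and y decreasing with row
index (row 0 carries the maximal y).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Grid"]


@dataclass(frozen=True)
class Grid:
    """A square, uniformly sampled plane.

    Parameters
    ----------
    n : int
        Samples per side.
    step : float
        Sampling step in μm; samples sit at pixel centres.
    """

    n: int
    step: float

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("grid needs at least one sample per side")
        if self.step <= 0:
            raise ValueError("sampling step must be positive")

    @property
    def extent(self) -> float:
        """Physical side length in μm."""
        return self.n * self.step

    @property
    def x(self) -> np.ndarray:
        """Column coordinates (μm), centred."""
        return (np.arange(self.n) - (self.n - 1) / 2.0) * self.step

    @property
    def y(self) -> np.ndarray:
        """Row coordinates (μm); row 0 has maximal y."""
        return ((self.n - 1) / 2.0 - np.arange(self.n)) * self.step

    def meshgrid(self, dtype=np.float64) -> tuple[np.ndarray, np.ndarray]:
        X, Y = np.meshgrid(self.x.astype(dtype), self.y.astype(dtype))
        return X, Y

    def aperture_mask(self, diameter: float) -> np.ndarray:
        """Boolean mask of a centred circular aperture of the given diameter (μm)."""
        X, Y = self.meshgrid(np.float32)
        return (X * X + Y * Y) <= (diameter / 2.0) ** 2

    def rowcol_to_xy(self, row, col) -> tuple[np.ndarray, np.ndarray]:
        row = np.asarray(row, dtype=float)
        col = np.asarray(col, dtype=float)
        x = (col - (self.n - 1) / 2.0) * self.step
        y = ((self.n - 1) / 2.0 - row) * self.step
        return x, y

    def xy_to_rowcol(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        col = x / self.step + (self.n - 1) / 2.0
        row = (self.n - 1) / 2.0 - y / self.step
        return row, col

    @classmethod
    def for_aperture(cls, diameter: float, step: float, margin: float = 0.0) -> "Grid":
        """Smallest even-sized grid covering ``diameter + 2*margin``."""
        n = int(np.ceil((diameter + 2.0 * margin) / step))
        n += n % 2
        return cls(n=n, step=step)
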