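"""Geometry of the 2-D monitoring problem.

The computation domain is a square grid of equal cells centered at the
origin; cell (row, col) = (0, 0) is the top-left cell, x grows with the
column index and y decreases with the row index.  Antennas sit on a circle
around the domain; measurements are repeated on a linearly spaced frequency
grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GridSpec", "AntennaArray", "FrequencyGrid"]


@dataclass(frozen=True)
class GridSpec:
    """Square pixel grid over the computation domain.

    Parameters
    ----------
    n_cells_per_axis:
        Number of cells along each axis (default 50).
    cell_size:
        Cell edge length in meters (default 2 mm).
    """

    n_cells_per_axis: int = 50
    cell_size: float = 0.002

    def __post_init__(self) -> None:
        if self.n_cells_per_axis < 1:
            raise ValueError("n_cells_per_axis must be >= 1")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    @property
    def extent(self) -> float:
        """Domain edge length in meters."""
        return self.n_cells_per_axis * self.cell_size

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_cells_per_axis, self.n_cells_per_axis)

    @property
    def n_cells(self) -> int:
        return self.n_cells_per_axis ** 2

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-cell center coordinates ``(x, y)`` in meters, each (n, n).

        Cell (0, 0) is the top-left cell: x = -extent/2 + h/2 + h*col,
        y = +extent/2 - h/2 - h*row.
        """
        n, h = self.n_cells_per_axis, self.cell_size
        half = self.extent / 2.0
        cols = -half + h / 2.0 + h * np.arange(n)
        rows = half - h / 2.0 - h * np.arange(n)
        x = np.broadcast_to(cols[None, :], (n, n)).copy()
        y = np.broadcast_to(rows[:, None], (n, n)).copy()
        return x, y

    def cell_centers_flat(self) -> np.ndarray:
        """(n_cells, 2) array of (x, y) centers in row-major order."""
        x, y = self.cell_centers()
        return np.column_stack([x.ravel(), y.ravel()])


@dataclass(frozen=True)
class AntennaArray:
    """Equally spaced transmit/receive antennas on a circle.

    Antenna 0 sits on the positive x-axis; ordering is counter-clockwise.
    """

    n_antennas: int = 16
    radius: float = 0.075

    def __post_init__(self) -> None:
        if self.n_antennas < 1:
            raise ValueError("n_antennas must be >= 1")
        if self.radius <= 0:
            raise ValueError("radius must be positive")

    @property
    def angles(self) -> np.ndarray:
        return 2.0 * np.pi * np.arange(self.n_antennas) / self.n_antennas

    @property
    def positions(self) -> np.ndarray:
        """(n_antennas, 2) array of (x, y) positions in meters."""
        a = self.angles
        return self.radius * np.column_stack([np.cos(a), np.sin(a)])


@dataclass(frozen=True)
class FrequencyGrid:
    """Linearly spaced measurement frequencies, default 16 points 0.5-2 GHz."""

    f_min: float = 0.5e9
    f_max: float = 2.0e9
    n_frequencies: int = 16
    frequencies: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.n_frequencies < 1:
            raise ValueError("n_frequencies must be >= 1")
        if self.f_min <= 0 or self.f_max < self.f_min:
            raise ValueError("need 0 < f_min <= f_max")
        if self.n_frequencies == 1 and self.f_max != self.f_min:
            raise ValueError("single frequency requires f_min == f_max")
        freqs = np.linspace(self.f_min, self.f_max, self.n_frequencies)
        object.__setattr__(self, "frequencies", freqs)

    @property
    def angular_frequencies(self) -> np.ndarray:
        return 2.0 * np.pi * self.frequencies

    def __len__(self) -> int:
        return self.n_frequencies

    def index_of(self, f: float) -> int:
        """Index of frequency ``f`` on the grid (exact within rounding)."""
        i = int(np.argmin(np.abs(self.frequencies - f)))
        if not np.isclose(self.frequencies[i], f, rtol=1e-9, atol=0.0):
            raise ValueError(f"frequency {f} Hz is not on the grid")
        return i
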