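"""Regular 2D grids for tissue sheets.

All fields in this package live on a :class:`GridSpec`: a regular square-spaced
grid of nodes at cell centres, ``x_i = (i + 1/2) dx``, ``y_j = (j + 1/2) dx``.
Arrays are indexed ``[j, i]`` (row = y, column = x), matching image conventions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GridSpec", "DEFAULT_SHEET"]


@dataclass(frozen=True)
class GridSpec:
    """Regular grid of ``nx`` x ``ny`` nodes with spacing ``dx`` (mm).

    Nodes sit at cell centres, so the physical extent is exactly
    ``nx * dx`` by ``ny * dx`` mm.
    """

    nx: int
    ny: int
    dx: float = 0.25

    def __post_init__(self) -> None:
        if self.dx <= 0:
            raise ValueError(f"dx must be positive, got {self.dx}")
        if self.nx < 2 or self.ny < 2:
            raise ValueError(f"grid needs at least 2x2 nodes, got {self.nx}x{self.ny}")

    @property
    def width(self) -> float:
        """Physical width in mm."""
        return self.nx * self.dx

    @property
    def height(self) -> float:
        """Physical height in mm."""
        return self.ny * self.dx

    @property
    def shape(self) -> tuple[int, int]:
        """Array shape ``(ny, nx)``."""
        return (self.ny, self.nx)

    @property
    def n_nodes(self) -> int:
        return self.nx * self.ny

    def x_coords(self) -> np.ndarray:
        """Node x coordinates (mm), length nx."""
        return (np.arange(self.nx) + 0.5) * self.dx

    def y_coords(self) -> np.ndarray:
        """Node y coordinates (mm), length ny."""
        return (np.arange(self.ny) + 0.5) * self.dx

    def meshgrid(self) -> tuple[np.ndarray, np.ndarray]:
        """(X, Y) coordinate arrays of shape ``(ny, nx)``."""
        return np.meshgrid(self.x_coords(), self.y_coords())

    def distance_to(self, point: tuple[float, float]) -> np.ndarray:
        """Euclidean distance (mm) from every node to ``point = (x, y)``."""
        x, y = self.meshgrid()
        return np.hypot(x - point[0], y - point[1])

    @classmethod
    def from_extent(cls, width: float, height: float, dx: float = 0.25) -> "GridSpec":
        """Grid covering ``width`` x ``height`` mm with spacing ``dx``."""
        nx = int(round(width / dx))
        ny = int(round(height / dx))
        grid = cls(nx=nx, ny=ny, dx=dx)
        if abs(grid.width - width) > dx or abs(grid.height - height) > dx:
            raise ValueError(
                f"extent {width}x{height} mm is not commensurate with dx={dx}"
            )
        return grid


#: The 10 x 10 cm ventricular sheet at 0.25 mm spacing (400 x 400 nodes).
DEFAULT_SHEET = GridSpec(nx=400, ny=400, dx=0.25)
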