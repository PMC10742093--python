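"""Dynamic 2-D odor concentration field (stigmergic predator trace).

The predator deposits a radially symmetric Gaussian bump of spatial scale
``phi_w`` at its position each step; the field then diffuses (explicit
4-neighbour scheme) and evaporates (multiplicative decay), leaving the decaying
trails prey respond to.  Prey read the field through two sensors placed
symmetrically at the agent base, perpendicular to the heading.

Coordinates: the arena is the axis-aligned square ``[-L/2, L/2]^2``; grid cell
``(i, j)`` (row i = y index, column j = x index) has its center at
``origin + (j + 0.5, i + 0.5) * cell_size``.
"""

from __future__ import annotations

import math
from typing import Tuple

import numpy as np

__all__ = ["OdorField", "sensor_positions"]


class OdorField:
    """Non-negative concentration grid covering the full arena."""

    def __init__(self, arena_length: float, cell_size: float = 1.0):
        if arena_length <= 0 or cell_size <= 0:
            raise ValueError("arena_length and cell_size must be positive")
        self.arena_length = float(arena_length)
        self.cell_size = float(cell_size)
        n = int(math.ceil(arena_length / cell_size))
        self.n_cells = n
        self.origin = np.array([-arena_length / 2.0, -arena_length / 2.0])
        self.grid = np.zeros((n, n), dtype=float)
        # cell-center coordinate vectors (shared by x and y: square arena)
        self._centers = self.origin[0] + (np.arange(n) + 0.5) * self.cell_size

    # -- queries --------------------------------------------------------------

    def _inside(self, pos) -> bool:
        h = self.arena_length / 2.0
        return -h <= pos[0] <= h and -h <= pos[1] <= h

    def total_mass(self) -> float:
        return float(self.grid.sum())

    def peak(self) -> float:
        return float(self.grid.max())

    def save_csv(self, path) -> None:
        """Export the concentration grid as a dense CSV matrix (row = y index)."""
        np.savetxt(path, self.grid, delimiter=",", fmt="%.17g")

    def sample(self, pos) -> float:
        """Bilinearly interpolated concentration at a world position.

        Positions outside the arena read 0 (the odor is arena-confined); a
        query exactly at a cell center returns that cell's stored value.
        """
        if not self._inside(pos):
            return 0.0
        n = self.n_cells
        # continuous index of the query in cell-center coordinates
        fx = (pos[0] - self.origin[0]) / self.cell_size - 0.5
        fy = (pos[1] - self.origin[1]) / self.cell_size - 0.5
        j0 = int(np.clip(math.floor(fx), 0, n - 1))
        i0 = int(np.clip(math.floor(fy), 0, n - 1))
        j1 = min(j0 + 1, n - 1)
        i1 = min(i0 + 1, n - 1)
        tx = np.clip(fx - j0, 0.0, 1.0)
        ty = np.clip(fy - i0, 0.0, 1.0)
        g = self.grid
        return float(
            g[i0, j0] * (1 - tx) * (1 - ty)
            + g[i0, j1] * tx * (1 - ty)
            + g[i1, j0] * (1 - tx) * ty
            + g[i1, j1] * tx * ty
        )

    # -- dynamics -------------------------------------------------------------

    def inject(self, source_pos, phi_w: float, amplitude: float) -> None:
        """Add a Gaussian bump ``amplitude * exp(-d^2 / (2 (phi_w/2)^2))``.

        ``phi_w`` is the injection *width*: the Gaussian scale is ``phi_w / 2``
        so that ~95% of the deposited mass falls within a disc of diameter
        ``2 * phi_w`` around the source.
        """
        if phi_w <= 0 or amplitude <= 0:
            raise ValueError("phi_w and amplitude must be positive")
        if not self._inside(source_pos):
            raise ValueError(f"odor source {tuple(source_pos)} outside arena")
        sigma = phi_w / 2.0
        dx = self._centers - source_pos[0]          # (n,) along columns
        dy = self._centers - source_pos[1]          # (n,) along rows
        # truncate beyond 4 sigma: contribution < 3.4e-4 * amplitude per cell
        cut = 4.0 * sigma
        jm = (np.abs(dx) <= cut).nonzero()[0]
        im = (np.abs(dy) <= cut).nonzero()[0]
        if len(im) == 0 or len(jm) == 0:  # pragma: no cover - cut >= cell always
            return
        bump = np.exp(
            -(dy[im, None] ** 2 + dx[None, jm] ** 2) / (2.0 * sigma**2)
        )
        self.grid[np.ix_(im, jm)] += amplitude * bump

    def evolve(self, evaporation: float, diffusion: float) -> None:
        """One explicit diffusion step followed by multiplicative evaporation.

        Diffusion mixes each cell with its 4-neighbourhood under reflecting
        (zero-flux) boundaries, conserving total mass; the subsequent
        ``*(1 - evaporation)`` strictly decreases it.  Stability requires the
        diffusion coefficient to be at most 0.25.
        """
        if not 0.0 < evaporation < 1.0:
            raise ValueError("evaporation must lie strictly in (0, 1)")
        if diffusion < 0:
            raise ValueError("diffusion must be non-negative")
        if diffusion > 0.25:
            raise ValueError("diffusion coefficient above 0.25 is unstable")
        g = self.grid
        if diffusion > 0.0:
            p = np.pad(g, 1, mode="edge")
            lap = p[:-2, 1:-1] + p[2:, 1:-1] + p[1:-1, :-2] + p[1:-1, 2:] - 4.0 * g
            g = g + diffusion * lap
        self.grid = g * (1.0 - evaporation)


def sensor_positions(pos, heading: float, offset: float) -> Tuple[np.ndarray, np.ndarray]:
    """Left/right odor-sensor positions for an agent at ``pos``.

    The two sensors sit at distance ``offset`` from the body center,
    perpendicular to the heading; "left" is counterclockwise of the heading.
    """
    nx, ny = -math.sin(heading), math.cos(heading)   # unit left-normal
    p = np.asarray(pos, dtype=float)
    left = p + offset * np.array([nx, ny])
    right = p - offset * np.array([nx, ny])
    return left, right
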