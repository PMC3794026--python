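"""Toroidal geometry: wrapping, minimal-image displacements and distances.

All simulation space is a square torus of side ``L`` with periodic boundary
conditions.  Coordinates live in the half-open box ``[0, L) x [0, L)``.
Displacements between points follow the minimal-image convention: of all
periodic images the shortest vector is returned, with each component in
``[-L/2, L/2)`` so the antipodal tie resolves deterministically to ``-L/2``.

Functions accept single positions (shape ``(2,)``) or stacks of positions
(shape ``(..., 2)``) and broadcast in the usual numpy fashion.
"""

from __future__ import annotations

import numpy as np

from .config import CELL_SIZE, SimulationConfig


def wrap_position(p: np.ndarray, L: float) -> np.ndarray:
    """Map raw coordinates into the box ``[0, L)`` by modular arithmetic.

    Idempotent; rejects non-finite input.
    """
    p = np.asarray(p, dtype=float)
    if not np.all(np.isfinite(p)):
        raise ValueError("position contains non-finite coordinates")
    wrapped = np.mod(p, L)
    # np.mod can return L itself for tiny negative inputs (e.g. -1e-18 % 10
    # == 10.0 is impossible, but -eps % L can round to L); fold it back.
    wrapped[wrapped >= L] = 0.0
    return wrapped


def toroidal_displacement(a: np.ndarray, b: np.ndarray, L: float) -> np.ndarray:
    """Minimal-image vector from ``a`` to ``b`` with components in [-L/2, L/2)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return np.mod(b - a + L / 2.0, L) - L / 2.0


def toroidal_distance(a: np.ndarray, b: np.ndarray, L: float) -> np.ndarray:
    """Euclidean norm of the minimal-image displacement from ``a`` to ``b``."""
    return np.linalg.norm(toroidal_displacement(a, b, L), axis=-1)


def pairwise_displacements(positions: np.ndarray, L: float) -> np.ndarray:
    """Matrix ``D`` with ``D[i, j]`` = minimal-image vector from j to i.

    Shape ``(N, N, 2)``.  ``D[i, j]`` points from agent j towards agent i,
    i.e. along the direction in which i is repelled by j.
    """
    positions = np.asarray(positions, dtype=float)
    diff = positions[:, None, :] - positions[None, :, :]
    return np.mod(diff + L / 2.0, L) - L / 2.0


def pairwise_distances(positions: np.ndarray, L: float) -> np.ndarray:
    """Symmetric matrix of toroidal distances between all agent pairs."""
    return np.linalg.norm(pairwise_displacements(positions, L), axis=-1)


def cell_of(p: np.ndarray, cfg: SimulationConfig) -> np.ndarray:
    """Grid cell index pair of position(s) ``p``: ``floor(coordinate / 0.1)``.

    Cells are half-open, so a coordinate exactly on a cell boundary belongs
    to the higher cell.  Indices are clipped into ``[0, 10L)`` to guard
    against the floating-point edge where ``p`` rounds up to ``L``.
    """
    p = np.asarray(p, dtype=float)
    idx = np.floor(p / CELL_SIZE).astype(np.intp)
    return np.clip(idx, 0, cfg.grid_side - 1)
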