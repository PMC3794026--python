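"""Dynamics of the paired nutrient fields and the gradient sensor.

Two grids share the toroidal box with the agents: ``Q`` holds nutrients that
are directly available to feeding individuals, ``U`` holds the underlying
reservoir that individuals cannot reach directly.  Five processes move
nutrients each step, each applied as ``rate * dt * stock``:

* infusion (``delta_infuse``): background release U -> Q;
* decay (``delta_decay``): settling Q -> U;
* diffusion (``delta_diffuse``): 4-neighbour conservative spreading within Q;
* disturbance (``delta_disturb``): speed-dependent release U -> Q on the
  cell an individual occupies — the faster the individual moves, the more
  of the local underlying stock it frees;
* depletion (``delta_deplete``): consumption from Q by individuals, removed
  from the system entirely.

When a cell's combined outflow in one step would exceed its stock, all
outflow terms from that cell are scaled by a common factor so that the cell
lands exactly at zero; the available quantity is thereby distributed over
the competing terms according to their relative weighting.  Everything else
is a transfer, so ``sum(Q) + sum(U) + cumulative_consumed`` is invariant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import CELL_SIZE, SimulationConfig
from .geometry import cell_of


@dataclass
class NutrientFields:
    """Paired nutrient grids at one instant.

    ``Q`` and ``U`` are ``(10L, 10L)`` arrays indexed ``[k, l]`` with ``k``
    the x-cell and ``l`` the y-cell (0-based).  ``cumulative_consumed``
    tracks every food unit removed from the system so far, so that
    ``Q.sum() + U.sum() + cumulative_consumed`` equals ``initial_total``
    throughout a run.
    """

    Q: np.ndarray
    U: np.ndarray
    cell_size: float = CELL_SIZE
    cumulative_consumed: float = 0.0
    initial_total: float = field(default=0.0)

    def __post_init__(self) -> None:
        if self.initial_total == 0.0:
            self.initial_total = float(self.Q.sum() + self.U.sum() + self.cumulative_consumed)

    @property
    def total(self) -> float:
        """Nutrients currently in the system plus everything consumed."""
        return float(self.Q.sum() + self.U.sum() + self.cumulative_consumed)

    def mass_error(self) -> float:
        """Relative deviation of the running total from the initial total."""
        if self.initial_total == 0.0:
            return abs(self.total)
        return abs(self.total - self.initial_total) / self.initial_total


@dataclass(frozen=True)
class FieldStepLedger:
    """Food units moved by each named process during one field update."""

    infused_total: float
    decayed_total: float
    diffused_net: float
    disturbed_total: float
    consumed_total: float
    consumed_per_agent: np.ndarray

    def __post_init__(self) -> None:
        assert abs(self.consumed_total - float(self.consumed_per_agent.sum())) <= max(
            1e-12, 1e-12 * abs(self.consumed_total)
        )


def init_fields_homogeneous(cfg: SimulationConfig) -> NutrientFields:
    """Spread ``food_per_cell`` units over every cell of U; Q starts empty."""
    G = cfg.grid_side
    U = np.full((G, G), float(cfg.food_per_cell))
    Q = np.zeros((G, G))
    return NutrientFields(Q=Q, U=U)


def init_fields_patchy(cfg: SimulationConfig, rng: np.random.Generator) -> NutrientFields:
    """Concentrate the full homogeneous total around one random cell.

    The same total as the homogeneous initialization, ``food_per_cell *
    (10L)^2`` units, is placed as unit parcels.  For each parcel two offsets
    are drawn from a standard normal (in grid cells), rounded to integers,
    and added to the randomly chosen patch-centre cell with periodic wrap.
    """
    G = cfg.grid_side
    n_parcels = int(round(cfg.food_per_cell)) * G * G
    centre = rng.integers(0, G, size=2)
    offsets = np.rint(rng.normal(0.0, 1.0, size=(n_parcels, 2))).astype(np.intp)
    cells = np.mod(centre[None, :] + offsets, G)
    U = np.zeros((G, G))
    np.add.at(U, (cells[:, 0], cells[:, 1]), 1.0)
    Q = np.zeros((G, G))
    return NutrientFields(Q=Q, U=U)


def _occupancy(positions: np.ndarray, speeds: np.ndarray, cfg: SimulationConfig):
    """Per-cell agent count and per-cell summed agent speed."""
    G = cfg.grid_side
    cells = cell_of(positions, cfg)
    count = np.zeros((G, G))
    speed_sum = np.zeros((G, G))
    np.add.at(count, (cells[:, 0], cells[:, 1]), 1.0)
    np.add.at(speed_sum, (cells[:, 0], cells[:, 1]), speeds)
    return cells, count, speed_sum


def step_fields(
    fields: NutrientFields,
    positions: np.ndarray,
    velocities: np.ndarray,
    cfg: SimulationConfig,
) -> FieldStepLedger:
    """Advance Q and U by one step in place and return the step ledger.

    All desired flows are computed from the pre-step state and applied
    simultaneously.  Outflows from a cell are clipped jointly (common scale
    factor) so no cell goes negative; inflows are the scaled outflows of the
    source cells, so mass is conserved exactly up to float summation.
    """
    Q, U = fields.Q, fields.U
    if np.any(Q < 0) or np.any(U < 0):
        raise ValueError("nutrient fields contain negative values")
    dt = cfg.dt
    speeds = np.linalg.norm(velocities, axis=-1)
    cells, count, speed_sum = _occupancy(positions, speeds, cfg)

    # Desired outflows, all proportional to the source stock.
    infuse = dt * cfg.delta_infuse * U
    disturb = dt * cfg.delta_disturb * U * speed_sum
    decay = dt * cfg.delta_decay * Q
    diffuse_out_dir = dt * cfg.delta_diffuse * Q  # per each of 4 neighbours
    deplete = dt * cfg.delta_deplete * Q * count

    # Joint clipping per source cell: scale so the cell lands at zero.
    # u_out > U >= 0 implies u_out > 0, so the division is safe.
    u_out = infuse + disturb
    s_u = np.ones_like(U)
    over = u_out > U
    s_u[over] = U[over] / u_out[over]
    q_out = decay + 4.0 * diffuse_out_dir + deplete
    s_q = np.ones_like(Q)
    over = q_out > Q
    s_q[over] = Q[over] / q_out[over]

    infuse *= s_u
    disturb *= s_u
    decay *= s_q
    deplete *= s_q
    diffuse_out_dir = diffuse_out_dir * s_q
    diffuse_out = 4.0 * diffuse_out_dir
    diffuse_in = (
        np.roll(diffuse_out_dir, 1, axis=0)
        + np.roll(diffuse_out_dir, -1, axis=0)
        + np.roll(diffuse_out_dir, 1, axis=1)
        + np.roll(diffuse_out_dir, -1, axis=1)
    )

    Q += infuse + disturb + diffuse_in - decay - diffuse_out - deplete
    U += decay - infuse - disturb
    # Guard against -0.0 / 1-ulp undershoot after exact-zero clipping.
    np.maximum(Q, 0.0, out=Q)
    np.maximum(U, 0.0, out=U)

    consumed_total = float(deplete.sum())
    fields.cumulative_consumed += consumed_total
    # Agents sharing a cell split the cell's consumed amount equally (the
    # per-cell term is proportional to the occupant count, so each agent's
    # share is dt * delta_deplete * Q, scaled by the cell's clipping factor).
    cell_consumed = deplete[cells[:, 0], cells[:, 1]]
    occ = count[cells[:, 0], cells[:, 1]]
    consumed_per_agent = cell_consumed / np.maximum(occ, 1.0)

    return FieldStepLedger(
        infused_total=float(infuse.sum()),
        decayed_total=float(decay.sum()),
        diffused_net=float(diffuse_in.sum() - diffuse_out.sum()),
        disturbed_total=float(disturb.sum()),
        consumed_total=consumed_total,
        consumed_per_agent=consumed_per_agent,
    )


def _gradient_kernel(cfg: SimulationConfig) -> tuple[np.ndarray, np.ndarray]:
    """Offsets and unit vectors of the square sensory window.

    The window contains all cells within ``w = round(R / cell_size)`` index
    steps of the focal cell per axis (half-width 5 cells for R = 0.5), the
    focal cell excluded.  Unit vectors point between cell midpoints along
    the minimal image, so the kernel stays valid on small grids.
    """
    G = cfg.grid_side
    w = int(round(cfg.R / CELL_SIZE))
    dk, dl = np.meshgrid(np.arange(-w, w + 1), np.arange(-w, w + 1), indexing="ij")
    offsets = np.stack([dk.ravel(), dl.ravel()], axis=1)
    offsets = offsets[~np.all(offsets == 0, axis=1)]
    mi = np.mod(offsets + G / 2.0, G) - G / 2.0  # minimal-image midpoint offsets
    norms = np.linalg.norm(mi, axis=1)
    units = np.where(norms[:, None] > 0, mi / np.where(norms[:, None] > 0, norms[:, None], 1.0), 0.0)
    return offsets.astype(np.intp), units


class GradientSensor:
    """Caches the sensory-window kernel for repeated gradient queries."""

    def __init__(self, cfg: SimulationConfig) -> None:
        self.cfg = cfg
        self.offsets, self.units = _gradient_kernel(cfg)

    def directions(self, Q: np.ndarray, cells: np.ndarray) -> np.ndarray:
        """Unit gradient directions for many focal cells at once.

        Parameters
        ----------
        Q : (G, G) array
        cells : (M, 2) integer array of focal cells.

        Returns
        -------
        (M, 2) array of unit vectors; rows are ``(0, 0)`` where the
        vectorial sum cancels (e.g. a locally homogeneous field).
        """
        G = self.cfg.grid_side
        k = np.mod(cells[:, 0][:, None] + self.offsets[:, 0][None, :], G)
        l = np.mod(cells[:, 1][:, None] + self.offsets[:, 1][None, :], G)
        diff = Q[k, l] - Q[cells[:, 0], cells[:, 1]][:, None]
        vec = diff @ self.units
        norm = np.linalg.norm(vec, axis=1)
        nonzero = norm > 1e-12
        out = np.zeros_like(vec)
        out[nonzero] = vec[nonzero] / norm[nonzero, None]
        return out


def gradient_direction(fields: NutrientFields, cell, cfg: SimulationConfig) -> np.ndarray:
    """Unit vector towards the highest available-nutrient gradient at ``cell``.

    Sums ``(Q[m, o] - Q[k, l]) * q_hat`` over every cell of the square
    sensory window around ``(k, l)``, where ``q_hat`` is the unit vector
    between cell midpoints; returns the normalised sum, or ``(0, 0)`` when
    the sum cancels.
    """
    sensor = GradientSensor(cfg)
    return sensor.directions(fields.Q, np.asarray(cell, dtype=np.intp)[None, :])[0]
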