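"""The four force terms acting on each individual, and the motion update.

Per step, with unit mass, each individual feels

* drag ``-gamma * v`` (friction),
* a stochastic kick of uniform random length in ``[0, xi]`` and isotropic
  direction,
* short-range repulsion: one unit vector away from every neighbour closer
  than ``r`` (Heaviside cut-off, minimal-image direction),
* a food force ``f1 + f2``: ``f1`` is the unit direction of the strongest
  available-nutrient gradient within the sensory range (or zero when the
  field is locally flat), and ``f2`` is a unit self-propulsion term that
  keeps individuals from stalling — along ``v`` when the gradient has a
  forward component, otherwise along the orthogonal of ``v`` nearer the
  gradient, so individuals turn towards nutrients instead of braking.

Motion integrates with semi-implicit Euler: velocity is updated from the
current force, then position from the new velocity, then wrapped onto the
torus.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import SimulationConfig
from .geometry import pairwise_displacements, wrap_position


@dataclass(frozen=True)
class ForceBreakdown:
    """Per-agent decomposition of the total force into its four terms.

    Each field is an ``(N, 2)`` array; ``total`` is their exact sum.
    """

    drag: np.ndarray
    stochastic: np.ndarray
    avoid: np.ndarray
    food: np.ndarray
    total: np.ndarray


def drag_force(v: np.ndarray, gamma: float) -> np.ndarray:
    """Friction ``-gamma * v``."""
    return -gamma * np.asarray(v, dtype=float)


def stochastic_force(n: int, xi: float, rng: np.random.Generator) -> np.ndarray:
    """``n`` independent kicks: length ~ U[0, xi], angle ~ U[0, 2*pi)."""
    lengths = rng.uniform(0.0, xi, size=n)
    angles = rng.uniform(0.0, 2.0 * np.pi, size=n)
    return lengths[:, None] * np.stack([np.cos(angles), np.sin(angles)], axis=1)


def avoidance_forces(positions: np.ndarray, cfg: SimulationConfig) -> np.ndarray:
    """Summed unit repulsion from every neighbour within range ``r``.

    The contribution of neighbour j to agent i is the unit minimal-image
    vector from j towards i, gated by ``d_ij < r``.  Exactly coincident
    agents (d = 0, direction undefined) contribute nothing.
    """
    disp = pairwise_displacements(positions, cfg.L)  # [i, j] points j -> i
    dist = np.linalg.norm(disp, axis=-1)
    active = (dist < cfg.r) & (dist > 0.0)
    inv = np.zeros_like(dist)
    inv[active] = 1.0 / dist[active]
    return (disp * inv[:, :, None]).sum(axis=1)


def avoidance_force(i: int, positions: np.ndarray, cfg: SimulationConfig) -> np.ndarray:
    """Repulsion felt by agent ``i`` alone (convenience wrapper)."""
    return avoidance_forces(positions, cfg)[i]


def propulsion_term(f1: np.ndarray, v: np.ndarray) -> np.ndarray:
    """The unit self-propulsion vector ``f2`` for each agent.

    Rules, with ``s = v . f1``:

    * ``s > 0``: along ``v``;
    * ``s < 0``: the unit vector orthogonal to ``v`` that minimises the
      angle to ``f1`` (equivalently, the orthogonal on the sign side of the
      cross product ``v x f1``);
    * ``s = 0`` with both nonzero: treated as the orthogonal branch, the
      tie between the two orthogonals broken towards positive cross product;
    * ``f1 = 0``: along ``v`` (pure self-propulsion; zero if ``v`` is too);
    * ``v = 0``: along ``f1``.
    """
    f1 = np.atleast_2d(np.asarray(f1, dtype=float))
    v = np.atleast_2d(np.asarray(v, dtype=float))
    speed = np.linalg.norm(v, axis=1)
    f1_len = np.linalg.norm(f1, axis=1)
    f2 = np.zeros_like(v)

    still = speed == 0.0
    f2[still] = f1[still]

    flat = (~still) & (f1_len == 0.0)
    f2[flat] = v[flat] / speed[flat, None]

    both = (~still) & (f1_len > 0.0)
    dot = np.einsum("ij,ij->i", v, f1)
    forward = both & (dot > 0.0)
    f2[forward] = v[forward] / speed[forward, None]

    turning = both & (dot <= 0.0)
    if np.any(turning):
        cross = v[:, 0] * f1[:, 1] - v[:, 1] * f1[:, 0]
        safe = np.where(speed > 0.0, speed, 1.0)
        left = np.stack([-v[:, 1], v[:, 0]], axis=1) / safe[:, None]
        chosen = np.where(cross[:, None] >= 0.0, left, -left)
        f2[turning] = chosen[turning]
    return f2


def food_force(f1: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Total nutrient-seeking force ``f1 + f2`` (magnitude at most 2)."""
    f1_arr = np.atleast_2d(np.asarray(f1, dtype=float))
    out = f1_arr + propulsion_term(f1_arr, v)
    return out[0] if np.asarray(f1).ndim == 1 else out


def total_forces(
    positions: np.ndarray,
    velocities: np.ndarray,
    f1: np.ndarray,
    cfg: SimulationConfig,
    rng: np.random.Generator,
) -> ForceBreakdown:
    """Compose the four force terms for every agent.

    ``f1`` is the per-agent gradient direction, supplied by the caller so
    the environment query happens once per step for the whole population.
    """
    drag = drag_force(velocities, cfg.gamma)
    stochastic = stochastic_force(cfg.N, cfg.xi, rng)
    avoid = avoidance_forces(positions, cfg)
    food = f1 + propulsion_term(f1, velocities)
    total = drag + stochastic + avoid + food
    return ForceBreakdown(drag=drag, stochastic=stochastic, avoid=avoid, food=food, total=total)


def integrate_step(
    positions: np.ndarray,
    velocities: np.ndarray,
    forces: np.ndarray,
    cfg: SimulationConfig,
) -> tuple[np.ndarray, np.ndarray]:
    """Semi-implicit Euler with unit mass.

    ``v' = v + dt * F``; ``x' = wrap(x + dt * v')``.  Returns the new
    positions and velocities; rejects non-finite forces.
    """
    forces = np.asarray(forces, dtype=float)
    if not np.all(np.isfinite(forces)):
        raise ValueError("non-finite force")
    v_new = velocities + cfg.dt * forces
    x_new = wrap_position(positions + cfg.dt * v_new, cfg.L)
    return x_new, v_new
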