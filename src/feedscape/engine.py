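"""Run orchestration: initialization, strict update ordering, recording.

Each of the ``duration / dt`` steps proceeds in a fixed order: first the
nutrient fields are updated using the current positions and velocities,
then all forces are computed from the freshly updated fields, then every
individual moves synchronously.  The initial state (t = 0) is recorded in
addition to the per-step states, and all randomness flows from a single
generator seeded by the configuration, so a run is a pure function of its
config.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import SimulationConfig, validate_config
from .fields import (
    GradientSensor,
    NutrientFields,
    init_fields_homogeneous,
    init_fields_patchy,
    step_fields,
)
from .forces import integrate_step, total_forces
from .geometry import cell_of

logger = logging.getLogger("feedscape")


@dataclass
class PopulationState:
    """Positions and velocities of all agents at one instant."""

    positions: np.ndarray  # (N, 2), each coordinate in [0, L)
    velocities: np.ndarray  # (N, 2)
    time: float = 0.0


@dataclass
class TrajectoryRecord:
    """Everything recorded over one run.

    ``positions`` has one row per recorded state (initial state plus one
    per step); ``displacements[t]`` and ``consumed[t]`` describe the move
    and intake that produced ``positions[t + 1]``.  Displacements are the
    actual per-step motion vectors (``dt * v``), consistent with the
    minimal-image difference of consecutive wrapped positions.
    """

    config: SimulationConfig
    positions: np.ndarray  # (T + 1, N, 2)
    displacements: np.ndarray  # (T, N, 2)
    consumed: np.ndarray  # (T, N)
    times: np.ndarray  # (T + 1,)
    mass_totals: np.ndarray  # (T + 1,) sum(Q) + sum(U) + cumulative_consumed
    final_fields: NutrientFields | None = None
    field_snapshots: list[tuple[float, np.ndarray, np.ndarray]] = field(default_factory=list)

    @property
    def n_steps(self) -> int:
        return self.displacements.shape[0]

    def unwrapped_positions(self) -> np.ndarray:
        """Continuous (non-wrapped) paths built from accumulated displacements."""
        out = np.empty_like(self.positions)
        out[0] = self.positions[0]
        np.cumsum(self.displacements, axis=0, out=out[1:])
        out[1:] += self.positions[0]
        return out

    def to_frame(self) -> pd.DataFrame:
        """Long-format trajectory table: time, agent_id, x, y, dx, dy, consumed."""
        T, N = self.consumed.shape
        times = np.repeat(self.times, N)
        agent = np.tile(np.arange(N), T + 1)
        flat_pos = self.positions.reshape(-1, 2)
        dx = np.vstack([np.full((1, N), np.nan), self.displacements[:, :, 0]]).ravel()
        dy = np.vstack([np.full((1, N), np.nan), self.displacements[:, :, 1]]).ravel()
        cons = np.vstack([np.full((1, N), np.nan), self.consumed]).ravel()
        return pd.DataFrame(
            {
                "time": times,
                "agent_id": agent,
                "x": flat_pos[:, 0],
                "y": flat_pos[:, 1],
                "dx": dx,
                "dy": dy,
                "consumed": cons,
            }
        )


def initialize_simulation(
    cfg: SimulationConfig, rng: np.random.Generator
) -> tuple[PopulationState, NutrientFields]:
    """Draw the initial population state and build the nutrient fields.

    Positions are iid uniform on the box; every initial velocity has unit
    length with an iid uniform heading.  Fields follow ``cfg.init_mode``.
    """
    positions = rng.uniform(0.0, cfg.L, size=(cfg.N, 2))
    headings = rng.uniform(0.0, 2.0 * np.pi, size=cfg.N)
    velocities = np.stack([np.cos(headings), np.sin(headings)], axis=1)
    if cfg.init_mode == "patchy":
        fields = init_fields_patchy(cfg, rng)
    else:
        fields = init_fields_homogeneous(cfg)
    return PopulationState(positions=positions, velocities=velocities), fields


def run(
    cfg: SimulationConfig,
    *,
    snapshot_interval: float | None = None,
    log_every: float | None = None,
) -> TrajectoryRecord:
    """Execute a full simulation and return the trajectory record.

    Parameters
    ----------
    cfg : SimulationConfig
        Validated (re-validated here) run configuration; ``cfg.seed``
        determines every random draw.
    snapshot_interval : float, optional
        If given, copies of Q and U are stored every that many seconds
        (and at the final step).
    log_every : float, optional
        If given, progress is logged to standard error every that many
        seconds of simulated time.
    """
    cfg = validate_config(cfg)
    rng = np.random.default_rng(cfg.seed)
    state, fields = initialize_simulation(cfg, rng)
    sensor = GradientSensor(cfg)

    T, N = cfg.n_steps, cfg.N
    positions = np.empty((T + 1, N, 2))
    displacements = np.empty((T, N, 2))
    consumed = np.empty((T, N))
    mass_totals = np.empty(T + 1)
    positions[0] = state.positions
    mass_totals[0] = fields.total

    snap_steps = None
    snapshots: list[tuple[float, np.ndarray, np.ndarray]] = []
    if snapshot_interval is not None:
        snap_steps = max(1, int(round(snapshot_interval / cfg.dt)))
    log_steps = None
    if log_every is not None:
        log_steps = max(1, int(round(log_every / cfg.dt)))

    for t in range(T):
        ledger = step_fields(fields, state.positions, state.velocities, cfg)
        cells = cell_of(state.positions, cfg)
        f1 = sensor.directions(fields.Q, cells)
        breakdown = total_forces(state.positions, state.velocities, f1, cfg, rng)
        new_pos, new_vel = integrate_step(state.positions, state.velocities, breakdown.total, cfg)
        displacements[t] = cfg.dt * new_vel
        state.positions, state.velocities = new_pos, new_vel
        state.time = (t + 1) * cfg.dt
        positions[t + 1] = new_pos
        consumed[t] = ledger.consumed_per_agent
        mass_totals[t + 1] = fields.total
        if snap_steps is not None and ((t + 1) % snap_steps == 0 or t == T - 1):
            snapshots.append((state.time, fields.Q.copy(), fields.U.copy()))
        if log_steps is not None and (t + 1) % log_steps == 0:
            logger.info("t = %.1f s / %.1f s", state.time, cfg.duration)

    times = np.arange(T + 1) * cfg.dt
    return TrajectoryRecord(
        config=cfg,
        positions=positions,
        displacements=displacements,
        consumed=consumed,
        times=times,
        mass_totals=mass_totals,
        final_fields=fields,
        field_snapshots=snapshots,
    )


def write_field_snapshot(path: str | Path, time: float, Q: np.ndarray, U: np.ndarray,
                         cfg: SimulationConfig) -> None:
    """Write one field snapshot as two delimited text matrices plus a sidecar.

    Creates ``<path>.Q.txt``, ``<path>.U.txt`` (row-major, one grid row per
    line) and ``<path>.meta.txt`` describing L, cell size and time.
    """
    path = Path(path)
    np.savetxt(path.with_suffix(".Q.txt"), Q)
    np.savetxt(path.with_suffix(".U.txt"), U)
    path.with_suffix(".meta.txt").write_text(
        f"L = {cfg.L}\ncell_size = 0.1\ntime = {time}\nlayout = row-major, index [k, l] = (x, y)\n"
    )


def enable_stderr_logging(level: int = logging.INFO) -> None:
    """Attach a simple stderr handler to the package logger (idempotent)."""
    if not logger.handlers:
        handler = logging.StreamHandler(sys.stderr)
        handler.setFormatter(logging.Formatter("%(name)s: %(message)s"))
        logger.addHandler(handler)
    logger.setLevel(level)
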