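"""Run configuration for the feeding-landscape simulator.

A single :class:`SimulationConfig` carries every model parameter (population
size, box geometry, force coefficients, nutrient-field rates) together with
the run-control settings (duration, analysis window, initialization mode,
seed).  Defaults correspond to the standard parameterisation of the model:
20 individuals in a 10x10 toroidal box, 0.1 s time steps, friction
coefficient 1.2/s, and weak background exchange between the underlying and
available nutrient layers.  The two interaction-strength rates
``delta_deplete`` and ``delta_disturb`` default to 0 (individuals do not
touch the nutrient fields), which is the baseline condition of the model;
both are conventionally explored on [0, 1].
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import yaml

#: Side length of one nutrient grid cell, in space units.  The grid
#: resolution is fixed by the model definition: an L x L box is discretised
#: into 10L x 10L cells of 0.1 x 0.1 units.
CELL_SIZE: float = 0.1

INIT_MODES = ("homogeneous", "patchy")


class ConfigError(ValueError):
    """Raised when a configuration violates a model invariant."""


@dataclass(frozen=True)
class SimulationConfig:
    """All model and run parameters for one simulation.

    Parameters
    ----------
    N : int
        Number of individuals.
    L : float
        Side length of the square toroidal box, in space units.  ``10 * L``
        must be a whole number of grid cells.
    dt : float
        Length of one update step, in seconds.
    gamma : float
        Friction coefficient (1/s) of the drag force ``-gamma * v``.
    xi : float
        Maximum length of the stochastic force; lengths are drawn uniformly
        from ``[0, xi]`` with isotropic direction.
    r : float
        Short-range repulsion radius between individuals (units); also the
        connectivity radius used to define groups.
    R : float
        Sensory range over which individuals detect gradients in the
        available nutrient field (units).
    delta_infuse, delta_decay, delta_deplete, delta_diffuse, delta_disturb :
        Rates (1/s) of the five nutrient-field processes: background release
        from the underlying field U into the available field Q, settling
        back from Q into U, consumption from Q by individuals, diffusion
        within Q, and speed-dependent release from U into Q caused by
        individual movement.
    food_per_cell : float
        Initial underlying nutrient stock per grid cell (food units).
    duration : float
        Total simulated time (s).
    analysis_window : float
        Length of the trailing window over which summary statistics are
        averaged (s); must not exceed ``duration``.
    init_mode : str
        ``"homogeneous"`` spreads the initial stock evenly over U;
        ``"patchy"`` concentrates the same total around one random cell.
    seed : int
        Seed for the run's random number generator.
    """

    N: int = 20
    L: float = 10.0
    dt: float = 0.1
    gamma: float = 1.2
    xi: float = 1.0
    r: float = 0.3
    R: float = 0.5
    delta_infuse: float = 0.001
    delta_decay: float = 0.1
    delta_deplete: float = 0.0
    delta_diffuse: float = 0.001
    delta_disturb: float = 0.0
    food_per_cell: float = 10.0
    duration: float = 300.0
    analysis_window: float = 50.0
    init_mode: str = "homogeneous"
    seed: int = 0

    @property
    def grid_side(self) -> int:
        """Number of nutrient grid cells along one axis (``10 * L``)."""
        return int(round(self.L / CELL_SIZE))

    @property
    def n_steps(self) -> int:
        """Number of update steps in a run (``duration / dt``)."""
        return int(round(self.duration / self.dt))

    @property
    def window_steps(self) -> int:
        """Number of steps in the trailing analysis window."""
        return int(round(self.analysis_window / self.dt))

    def replace(self, **changes: Any) -> "SimulationConfig":
        """Return a copy with the given fields replaced (and re-validated)."""
        return validate_config(dataclasses.replace(self, **changes))

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "SimulationConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
        return validate_config(cls(**data))

    @classmethod
    def from_file(cls, path: str | Path) -> "SimulationConfig":
        """Load a flat key/value YAML or JSON configuration file.

        Keys mirror the field names of this class exactly.  Files ending in
        ``.json`` are parsed as JSON, anything else as YAML (of which JSON
        is a subset anyway).
        """
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ConfigError(f"configuration file {path} is not a mapping")
        return cls.from_dict(data)

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix == ".json":
            path.write_text(json.dumps(self.to_dict(), indent=2) + "\n")
        else:
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


def validate_config(cfg: SimulationConfig) -> SimulationConfig:
    """Check every invariant of a configuration; return it unchanged if valid.

    Raises
    ------
    ConfigError
        Naming the violated field.
    """
    if not isinstance(cfg.N, (int,)) or cfg.N < 1:
        raise ConfigError(f"N must be a positive integer, got {cfg.N}")
    if not (cfg.L > 0):
        raise ConfigError(f"L must be positive, got {cfg.L}")
    if not (cfg.dt > 0):
        raise ConfigError("dt must be positive")
    for name in ("gamma", "xi", "r", "R", "delta_infuse", "delta_decay",
                 "delta_deplete", "delta_diffuse", "delta_disturb",
                 "food_per_cell"):
        value = getattr(cfg, name)
        if not math.isfinite(value) or value < 0:
            raise ConfigError(f"{name} must be a non-negative finite number, got {value}")
    if not (cfg.duration > 0):
        raise ConfigError(f"duration must be positive, got {cfg.duration}")
    if cfg.analysis_window < 0:
        raise ConfigError(f"analysis_window must be non-negative, got {cfg.analysis_window}")
    if cfg.analysis_window > cfg.duration:
        raise ConfigError(
            f"analysis_window ({cfg.analysis_window}) exceeds duration ({cfg.duration})"
        )
    cells = cfg.L / CELL_SIZE
    if abs(cells - round(cells)) > 1e-9:
        raise ConfigError(
            f"L = {cfg.L} does not give a whole number of {CELL_SIZE}-unit grid cells"
        )
    if cfg.init_mode not in INIT_MODES:
        raise ConfigError(f"init_mode must be one of {INIT_MODES}, got {cfg.init_mode!r}")
    if not isinstance(cfg.seed, int):
        raise ConfigError(f"seed must be an integer, got {cfg.seed!r}")
    return cfg
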