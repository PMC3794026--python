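"""Replicated sweep drivers over the interaction-strength parameters.

Three designs probe how individual-to-landscape interaction strength shapes
the emergent dynamics:

* interaction sweep: a grid of ``(delta_deplete, delta_disturb)``
  combinations on [0, 1] (the full design is 15 equally spaced values per
  axis, 225 combinations, 100 replicates each; desk-scale defaults are
  smaller);
* infusion sweep: varying ``delta_infuse`` for three reference interaction
  combinations (0, 0), (0.214, 0.5) and (1, 1);
* density sweep: varying N for the baseline (0, 0) and the swirling
  (1, 0.1) combinations, reporting the largest group normalised by N.

A time-course driver bins the statistics over the whole run rather than
only the trailing window.  Every run's seed is a pure function of the
master seed, the combination index and the replicate index, so any table
is exactly reproducible and any single run can be re-executed in
isolation.
"""

from __future__ import annotations

from collections.abc import Iterable, Sequence

import numpy as np
import pandas as pd

from .config import SimulationConfig
from .engine import run
from .stats import consumption_stats, per_step_group_stats, summarize, tortuosity

#: Reference interaction combinations used by the infusion sweep and the
#: time-course analyses.
INFUSION_COMBOS: tuple[tuple[float, float], ...] = ((0.0, 0.0), (0.214, 0.5), (1.0, 1.0))
#: Reference combinations used by the density sweep: baseline and swirling.
DENSITY_COMBOS: tuple[tuple[float, float], ...] = ((0.0, 0.0), (1.0, 0.1))

STAT_COLUMNS = [
    "n_groups",
    "largest_group_size",
    "polarisation",
    "angular_momentum",
    "tortuosity",
    "consumption_abs",
    "consumption_norm",
]


def derive_seed(master_seed: int, combo_index: int, rep: int) -> int:
    """Deterministic per-run seed: a pure function of its three indices."""
    ss = np.random.SeedSequence((int(master_seed), int(combo_index), int(rep)))
    return int(ss.generate_state(1)[0] % (2**31))


def interaction_grid(n_values: int = 15) -> np.ndarray:
    """Equally spaced values on [0, 1] including both endpoints."""
    return np.linspace(0.0, 1.0, n_values)


def run_single(cfg: SimulationConfig) -> dict[str, float]:
    """One run reduced to its summary-statistic row."""
    record = run(cfg)
    return summarize(record).to_dict()


def _aggregate(runs: pd.DataFrame, keys: list[str]) -> pd.DataFrame:
    """Mean and standard deviation per combination, re-derivable from runs."""
    agg = runs.groupby(keys, as_index=False)[STAT_COLUMNS].agg(["mean", "std"])
    agg.columns = [c if isinstance(c, str) else "_".join(filter(None, c)) for c in agg.columns]
    return agg


def sweep_interaction(
    deplete_values: Sequence[float] | None = None,
    disturb_values: Sequence[float] | None = None,
    reps: int = 10,
    base: SimulationConfig | None = None,
    master_seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sweep the ``(delta_deplete, delta_disturb)`` grid.

    Returns ``(runs, aggregate)``: one row per run with all six statistics,
    and per-combination mean/sd.  Desk-scale defaults (5 x 5 grid); pass
    ``interaction_grid(15)`` for both axes to reproduce the full design.
    """
    base = base or SimulationConfig()
    deplete_values = list(deplete_values if deplete_values is not None else interaction_grid(5))
    disturb_values = list(disturb_values if disturb_values is not None else interaction_grid(5))
    rows = []
    combo_index = 0
    for dep in deplete_values:
        for dis in disturb_values:
            for rep in range(reps):
                seed = derive_seed(master_seed, combo_index, rep)
                cfg = base.replace(delta_deplete=float(dep), delta_disturb=float(dis), seed=seed)
                rows.append(
                    {
                        "delta_deplete": float(dep),
                        "delta_disturb": float(dis),
                        "rep": rep,
                        "seed": seed,
                        **run_single(cfg),
                    }
                )
            combo_index += 1
    runs = pd.DataFrame(rows)
    return runs, _aggregate(runs, ["delta_deplete", "delta_disturb"])


def sweep_infusion(
    infuse_values: Sequence[float],
    combos: Sequence[tuple[float, float]] = INFUSION_COMBOS,
    reps: int = 10,
    base: SimulationConfig | None = None,
    master_seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Vary ``delta_infuse`` for each reference interaction combination."""
    base = base or SimulationConfig()
    rows = []
    combo_index = 0
    for inf in infuse_values:
        for dep, dis in combos:
            for rep in range(reps):
                seed = derive_seed(master_seed, combo_index, rep)
                cfg = base.replace(
                    delta_infuse=float(inf),
                    delta_deplete=float(dep),
                    delta_disturb=float(dis),
                    seed=seed,
                )
                rows.append(
                    {
                        "delta_infuse": float(inf),
                        "delta_deplete": float(dep),
                        "delta_disturb": float(dis),
                        "rep": rep,
                        "seed": seed,
                        **run_single(cfg),
                    }
                )
            combo_index += 1
    runs = pd.DataFrame(rows)
    return runs, _aggregate(runs, ["delta_infuse", "delta_deplete", "delta_disturb"])


def sweep_density(
    n_values: Sequence[int],
    combos: Sequence[tuple[float, float]] = DENSITY_COMBOS,
    reps: int = 15,
    base: SimulationConfig | None = None,
    master_seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Vary the population size N for each reference combination.

    Adds ``largest_group_frac`` (largest group size normalised by N) to
    every row.
    """
    base = base or SimulationConfig()
    rows = []
    combo_index = 0
    for n in n_values:
        for dep, dis in combos:
            for rep in range(reps):
                seed = derive_seed(master_seed, combo_index, rep)
                cfg = base.replace(
                    N=int(n), delta_deplete=float(dep), delta_disturb=float(dis), seed=seed
                )
                stats = run_single(cfg)
                rows.append(
                    {
                        "N": int(n),
                        "delta_deplete": float(dep),
                        "delta_disturb": float(dis),
                        "rep": rep,
                        "seed": seed,
                        **stats,
                        "largest_group_frac": stats["largest_group_size"] / n,
                    }
                )
            combo_index += 1
    runs = pd.DataFrame(rows)
    agg = runs.groupby(["N", "delta_deplete", "delta_disturb"], as_index=False)[
        STAT_COLUMNS + ["largest_group_frac"]
    ].agg(["mean", "std"])
    agg.columns = [c if isinstance(c, str) else "_".join(filter(None, c)) for c in agg.columns]
    return runs, agg


def time_course(
    combos: Sequence[tuple[float, float]] = INFUSION_COMBOS,
    reps: int = 10,
    bin_width: float = 8.0,
    base: SimulationConfig | None = None,
    master_seed: int = 0,
) -> pd.DataFrame:
    """Statistics binned over the whole run, not just the trailing window.

    One row per (combo, rep, bin) with the bin-averaged statistics plus
    absolute consumption and the population-level polarisation.  A partial
    final bin (when ``bin_width`` does not divide the duration) is dropped.
    """
    base = base or SimulationConfig()
    bin_steps = int(round(bin_width / base.dt))
    rows = []
    for combo_index, (dep, dis) in enumerate(combos):
        for rep in range(reps):
            seed = derive_seed(master_seed, combo_index, rep)
            cfg = base.replace(delta_deplete=float(dep), delta_disturb=float(dis), seed=seed)
            record = run(cfg)
            unwrapped = record.unwrapped_positions()
            n_bins = record.n_steps // bin_steps
            for b in range(n_bins):
                sl = slice(b * bin_steps, (b + 1) * bin_steps)
                series = per_step_group_stats(record, cfg, sl, population_polarisation=True)
                cons_abs, cons_norm = consumption_stats(record, cfg, step_slice=sl)
                with np.errstate(invalid="ignore"):
                    rows.append(
                        {
                            "delta_deplete": float(dep),
                            "delta_disturb": float(dis),
                            "rep": rep,
                            "seed": seed,
                            "bin_start": b * bin_width,
                            "bin_end": (b + 1) * bin_width,
                            "n_groups": float(series["n_groups"].mean()),
                            "largest_group_size": float(series["largest_group_size"].mean()),
                            "polarisation": float(series["polarisation"].mean()),
                            "polarisation_population": float(
                                series["polarisation_population"].mean()
                            ),
                            "angular_momentum": float(series["angular_momentum"].mean()),
                            "tortuosity": tortuosity(unwrapped, cfg, sl),
                            "consumption_abs": cons_abs,
                            "consumption_norm": cons_norm,
                        }
                    )
    return pd.DataFrame(rows)
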