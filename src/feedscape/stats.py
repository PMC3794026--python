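"""Summary statistics of the emergent movement dynamics.

Six statistics quantify a run, each computed per step and averaged over the
trailing analysis window:

* number of groups and size of the largest group, with groups defined as
  connected components of the "within repulsion range r" graph;
* polarisation of the largest group: the length of the mean unit
  displacement vector (1 = perfectly aligned, 0 = no net direction);
* angular momentum of the largest group: ``|sum_j r_jc x s_j| / N_l`` with
  unit centre-to-member vectors ``r_jc`` and unit displacement vectors
  ``s_j`` (1 = perfect mill);
* arc-chord tortuosity: path length over a 2-second window divided by the
  straight-line distance between its endpoints, averaged across
  individuals and windows (1 = straight motion);
* consumption: mean food units consumed per individual per step, reported
  both absolute and normalised by ``delta_deplete``.

Polarisation and angular momentum require the largest group to contain at
least two members; steps where it does not are excluded from their
averages, and a statistic with no valid step at all is reported as NaN
(the explicit missing marker used throughout this module).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .config import SimulationConfig
from .engine import TrajectoryRecord
from .geometry import pairwise_distances, toroidal_displacement

#: Length of one tortuosity window, seconds.
TORTUOSITY_WINDOW_S = 2.0
#: Chords shorter than this are treated as degenerate (closed loops) and
#: the window is dropped rather than producing an unbounded ratio.
CHORD_EPS = 1e-9


@dataclass(frozen=True)
class SummaryStatistics:
    """The six statistics of one run, averaged over the analysis window."""

    n_groups: float
    largest_group_size: float
    polarisation: float  # NaN when never defined in the window
    angular_momentum: float  # NaN when never defined in the window
    tortuosity: float  # NaN when every window was degenerate
    consumption_abs: float
    consumption_norm: float

    def to_dict(self) -> dict[str, float]:
        return {
            "n_groups": self.n_groups,
            "largest_group_size": self.largest_group_size,
            "polarisation": self.polarisation,
            "angular_momentum": self.angular_momentum,
            "tortuosity": self.tortuosity,
            "consumption_abs": self.consumption_abs,
            "consumption_norm": self.consumption_norm,
        }


def find_groups(positions: np.ndarray, cfg: SimulationConfig) -> list[np.ndarray]:
    """Partition agents into groups: connected components at range ``r``.

    Two agents are connected when their toroidal distance is strictly below
    ``cfg.r``; groups are chains of such connections.  Returns a disjoint
    cover of all agents, each group as a sorted index array, groups ordered
    by their lowest member index.
    """
    n = len(positions)
    dist = pairwise_distances(positions, cfg.L)
    adj = (dist < cfg.r) & ~np.eye(n, dtype=bool)
    _, labels = connected_components(csr_matrix(adj), directed=False)
    groups = [np.flatnonzero(labels == lab) for lab in np.unique(labels)]
    groups.sort(key=lambda g: g[0])
    return groups


def largest_group(partition: list[np.ndarray]) -> tuple[int, np.ndarray]:
    """Size and member set of the largest group.

    All-singleton partitions give size 1.  Ties go to the group containing
    the lowest agent index.
    """
    best = max(partition, key=lambda g: (len(g), -g[0]))
    return len(best), best


def polarisation(displacements: np.ndarray) -> float:
    """Length of the mean unit displacement vector of the given members.

    Zero-length displacements contribute a zero vector while still counting
    in the denominator, keeping the formula total.
    """
    d = np.atleast_2d(np.asarray(displacements, dtype=float))
    norms = np.linalg.norm(d, axis=1)
    units = np.zeros_like(d)
    moving = norms > 0
    units[moving] = d[moving] / norms[moving, None]
    return float(np.linalg.norm(units.mean(axis=0)))


def group_centre(positions: np.ndarray, L: float) -> np.ndarray:
    """Centre of a member set on the torus via the per-axis circular mean."""
    theta = np.asarray(positions, dtype=float) / L * 2.0 * np.pi
    mean_angle = np.arctan2(np.sin(theta).mean(axis=0), np.cos(theta).mean(axis=0))
    return np.mod(mean_angle / (2.0 * np.pi) * L, L)


def angular_momentum(
    positions: np.ndarray,
    displacements: np.ndarray,
    members: np.ndarray,
    cfg: SimulationConfig,
) -> float:
    """Degree of rotation of a group about its centre, in [0, 1].

    ``|sum_j r_jc x s_j| / N_l`` with ``r_jc`` the unit vector from the
    group centre to member j (minimal image) and ``s_j`` the member's unit
    displacement.  NaN when the group has fewer than two members or a
    member sits exactly at the centre.
    """
    members = np.asarray(members)
    if len(members) < 2:
        return float("nan")
    pos = np.asarray(positions, dtype=float)[members]
    disp = np.asarray(displacements, dtype=float)[members]
    centre = group_centre(pos, cfg.L)
    radial = toroidal_displacement(centre, pos, cfg.L)
    r_norm = np.linalg.norm(radial, axis=1)
    if np.any(r_norm == 0):
        return float("nan")
    r_hat = radial / r_norm[:, None]
    d_norm = np.linalg.norm(disp, axis=1)
    s_hat = np.zeros_like(disp)
    moving = d_norm > 0
    s_hat[moving] = disp[moving] / d_norm[moving, None]
    cross = r_hat[:, 0] * s_hat[:, 1] - r_hat[:, 1] * s_hat[:, 0]
    return float(abs(cross.sum()) / len(members))


def tortuosity(unwrapped: np.ndarray, cfg: SimulationConfig,
               step_slice: slice | None = None) -> float:
    """Mean arc-chord ratio over consecutive 2-second windows.

    Parameters
    ----------
    unwrapped : (T + 1, N, 2) array
        Continuous per-agent paths (wrap-free, built from accumulated
        minimal-image displacements).
    step_slice : slice, optional
        Range of *step* indices (into the T displacement steps) to analyse;
        defaults to the whole record.  Windows are non-overlapping and a
        trailing partial window is dropped, as are windows whose chord is
        shorter than ``CHORD_EPS``.

    Returns NaN if no window survives.
    """
    w = int(round(TORTUOSITY_WINDOW_S / cfg.dt))
    T = unwrapped.shape[0] - 1
    start, stop, _ = (step_slice or slice(0, T)).indices(T)
    ratios: list[np.ndarray] = []
    for w0 in range(start, stop - w + 1, w):
        seg = unwrapped[w0 : w0 + w + 1]  # (w + 1, N, 2) positions
        steps = np.linalg.norm(np.diff(seg, axis=0), axis=2)  # (w, N)
        arc = steps.sum(axis=0)
        chord = np.linalg.norm(seg[-1] - seg[0], axis=1)
        ok = chord >= CHORD_EPS
        if np.any(ok):
            ratios.append(arc[ok] / chord[ok])
    if not ratios:
        return float("nan")
    return float(np.concatenate(ratios).mean())


def consumption_stats(
    record: TrajectoryRecord,
    cfg: SimulationConfig,
    members: np.ndarray | None = None,
    step_slice: slice | None = None,
) -> tuple[float, float]:
    """Mean consumption per individual per step, absolute and normalised.

    Restricting to a ``members`` subset supports contrasts such as largest
    versus smallest group.  The normalised value divides by
    ``delta_deplete`` and is defined as exactly 0 when that rate is 0.
    """
    consumed = record.consumed
    if step_slice is not None:
        consumed = consumed[step_slice]
    if members is not None:
        consumed = consumed[:, np.asarray(members)]
    consumption_abs = float(consumed.mean()) if consumed.size else 0.0
    if cfg.delta_deplete == 0:
        return consumption_abs, 0.0
    return consumption_abs, consumption_abs / cfg.delta_deplete


def per_step_group_stats(
    record: TrajectoryRecord,
    cfg: SimulationConfig,
    step_slice: slice | None = None,
    population_polarisation: bool = False,
) -> pd.DataFrame:
    """Per-step series of the group-level statistics.

    One row per step in ``step_slice`` with columns ``time``, ``n_groups``,
    ``largest_group_size``, ``polarisation``, ``angular_momentum`` (NaN on
    steps where the largest group has fewer than two members) and, when
    requested, ``polarisation_population`` over all N agents.
    """
    T = record.n_steps
    start, stop, _ = (step_slice or slice(0, T)).indices(T)
    rows = []
    for t in range(start, stop):
        pos = record.positions[t + 1]
        disp = record.displacements[t]
        partition = find_groups(pos, cfg)
        size, members = largest_group(partition)
        row = {
            "time": record.times[t + 1],
            "n_groups": len(partition),
            "largest_group_size": size,
            "polarisation": polarisation(disp[members]) if size >= 2 else np.nan,
            "angular_momentum": angular_momentum(pos, disp, members, cfg)
            if size >= 2
            else np.nan,
        }
        if population_polarisation:
            row["polarisation_population"] = polarisation(disp)
        rows.append(row)
    return pd.DataFrame(rows)


def summarize(
    record: TrajectoryRecord,
    cfg: SimulationConfig | None = None,
    population_polarisation: bool = False,
) -> SummaryStatistics:
    """All six statistics averaged over the trailing analysis window."""
    cfg = cfg or record.config
    W = cfg.window_steps
    T = record.n_steps
    if W > T:
        raise ValueError("record shorter than the analysis window")
    window = slice(T - W, T)
    series = per_step_group_stats(record, cfg, window, population_polarisation)
    unwrapped = record.unwrapped_positions()
    tort = tortuosity(unwrapped, cfg, window)
    cons_abs, cons_norm = consumption_stats(record, cfg, step_slice=window)
    with np.errstate(invalid="ignore"):
        pol = float(series["polarisation"].mean())
        ang = float(series["angular_momentum"].mean())
    return SummaryStatistics(
        n_groups=float(series["n_groups"].mean()),
        largest_group_size=float(series["largest_group_size"].mean()),
        polarisation=pol,
        angular_momentum=ang,
        tortuosity=tort,
        consumption_abs=cons_abs,
        consumption_norm=cons_norm,
    )
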