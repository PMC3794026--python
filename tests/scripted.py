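"""Scripted motion fixtures with closed-form expected statistics.

These generators build position/displacement arrays (and, where useful,
full unwrapped paths) for configurations whose summary statistics are known
exactly: parallel marchers (polarisation 1, tortuosity 1), a perfect mill
(angular momentum 1) and a seeded random walk (only the bounds are known).
"""

from __future__ import annotations

import numpy as np


def marchers(n: int = 5, heading: float = 0.0, step: float = 0.05,
             n_steps: int = 40, spacing: float = 1.0):
    """Agents on a line all stepping in the same direction.

    Returns ``(paths, displacements)`` with ``paths`` of shape
    ``(n_steps + 1, n, 2)`` (unwrapped) and constant per-step
    displacements.  Polarisation of any step is exactly 1 and every
    arc-chord window ratio is exactly 1.
    """
    d = step * np.array([np.cos(heading), np.sin(heading)])
    start = np.stack([np.zeros(n), spacing * np.arange(n)], axis=1)
    paths = start[None, :, :] + np.arange(n_steps + 1)[:, None, None] * d[None, None, :]
    disp = np.broadcast_to(d, (n_steps, n, 2)).copy()
    return paths, disp


def mill(n: int = 4, radius: float = 1.0, centre=(5.0, 5.0), speed: float = 0.1,
         clockwise: bool = False):
    """A perfect mill: evenly spaced agents with exactly tangential motion.

    Returns ``(positions, displacements)`` for a single instant.  Evenly
    spaced agents come in antipodal pairs, so the per-axis circular-mean
    centre coincides exactly with ``centre`` and every unit
    centre-to-agent vector is exactly orthogonal to its agent's
    displacement: the angular momentum is exactly 1.
    """
    assert n % 2 == 0, "antipodal pairing requires an even count"
    phi = 2.0 * np.pi * np.arange(n) / n
    radial = np.stack([np.cos(phi), np.sin(phi)], axis=1)
    positions = np.asarray(centre) + radius * radial
    tangent = np.stack([-np.sin(phi), np.cos(phi)], axis=1)
    if clockwise:
        tangent = -tangent
    return positions, speed * tangent


def random_walk(n: int = 5, n_steps: int = 60, step: float = 0.1,
                seed: int = 0, box: float = 10.0):
    """Unbiased random walk paths (unwrapped) for bound checks."""
    rng = np.random.default_rng(seed)
    angles = rng.uniform(0.0, 2.0 * np.pi, size=(n_steps, n))
    disp = step * np.stack([np.cos(angles), np.sin(angles)], axis=2)
    start = rng.uniform(0.0, box, size=(n, 2))
    paths = np.concatenate([start[None], start[None] + np.cumsum(disp, axis=0)], axis=0)
    return paths, disp
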