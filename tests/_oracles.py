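"""Independent numerical oracles kept separate from the code they check."""

from __future__ import annotations

import numpy as np

import myoregen as mr
from myoregen.dynamics import rhs_array


def euler_reference(params: mr.RateParameters, initial: mr.CellState, grid, dt=1e-4):
    """Fixed-step explicit Euler integration on raw vectors.

    Deliberately naive: a first-order method with a tiny step whose only
    shared machinery with the adaptive solver is the right-hand side.
    """
    grid = np.asarray(grid, dtype=float)
    p = params.to_array()
    y = initial.to_array()
    out = np.empty((grid.size, y.size))
    gi = 0
    if grid[0] == 0.0:
        out[0] = y
        gi = 1
    n_steps = int(round(grid[-1] / dt))
    for k in range(1, n_steps + 1):
        y = y + dt * rhs_array(y, p)
        t = k * dt
        while gi < grid.size and t >= grid[gi] - dt / 2:
            out[gi] = y
            gi += 1
    return out
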