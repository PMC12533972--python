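"""Local one-at-a-time perturbation sensitivity of the model trajectory.

For each of the 17 rate constants, the model is re-simulated with that
constant increased by 0.1% and the unperturbed hourly trajectory is
subtracted, giving a raw difference matrix (parameters x time points)
per cell type.  Each cell type's matrix is then scaled by the absolute
value of its largest-magnitude entry, so normalized sensitivities lie in
[-1, 1] and are comparable within, but not across, cell types.  They are
rendered as diverging heatmaps (blue = decrease, white = none, red =
increase).

Raw trajectory differences are stored as-is by default; dividing by the
absolute parameter perturbation (a finite-difference derivative
estimate) is available via ``mode='derivative'`` and yields the same
normalized matrices per cell type.

Because the immune block does not feed back from the myogenic block,
perturbing any satellite-cell parameter leaves the Md/N/Nd/M/M1/M2
trajectories unchanged; simulation is run at tight tolerances and
differences below a dead-band of 1e-9 times the trajectory scale are
snapped to exactly zero so these structural zeros are exact.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import GridLike, SimulationError, resolve_grid, simulate
from .state import PARAM_ORDER, STATE_ORDER, CellState, RateParameters, ValidationError

#: Parameters that act only on the myogenic (satellite-cell) block.
SATELLITE_PARAMETERS: tuple[str, ...] = (
    "cQSCN",
    "cQSCMd",
    "cASCM2",
    "cASCpro",
    "cASCdiff",
    "cMcout",
)

#: Cell types that receive no influence from the myogenic block.
IMMUNE_TYPES: tuple[str, ...] = ("Md", "N", "Nd", "M", "M1", "M2")


def normalize_matrix(matrix: np.ndarray) -> np.ndarray:
    """Scale a matrix by its largest absolute entry into [-1, 1].

    All-zero matrices are returned unchanged (no 0/0), and normalization
    is idempotent: renormalizing a normalized matrix is a no-op.
    """
    matrix = np.asarray(matrix, dtype=float)
    peak = np.max(np.abs(matrix)) if matrix.size else 0.0
    if peak == 0.0:
        return matrix.copy()
    return matrix / peak


@dataclass(frozen=True)
class SensitivityTensor:
    """Per-cell-type (17 x T) perturbation matrices.

    ``raw`` holds the trajectory differences (perturbed - unperturbed, or
    their derivative estimates); ``normalized`` the per-cell-type scaled
    versions in [-1, 1].  Rows follow PARAM_ORDER, columns the time grid.
    """

    times: np.ndarray
    raw: dict[str, np.ndarray]
    normalized: dict[str, np.ndarray]
    rel_delta: float
    mode: str

    def __post_init__(self) -> None:
        for name in STATE_ORDER:
            for store in (self.raw, self.normalized):
                if name not in store:
                    raise ValidationError(f"missing sensitivity matrix for {name}")
                if store[name].shape != (len(PARAM_ORDER), self.times.size):
                    raise ValidationError(f"bad sensitivity matrix shape for {name}")

    def matrix(self, cell_type: str) -> pd.DataFrame:
        """Normalized matrix as a DataFrame (parameters x times)."""
        return pd.DataFrame(
            self.normalized[cell_type], index=list(PARAM_ORDER), columns=self.times
        )


def perturbation_sensitivity(
    params: RateParameters,
    initial: CellState,
    rel_delta: float = 0.001,
    grid: GridLike = "hourly",
    mode: str = "difference",
    rtol: float = 1e-10,
    atol: float = 1e-12,
    deadband: float = 1e-9,
) -> SensitivityTensor:
    """One-sided perturbation sensitivities of every population.

    Each parameter p is increased to p*(1 + rel_delta) in turn and the
    unperturbed trajectory subtracted.  ``mode='difference'`` stores raw
    differences; ``mode='derivative'`` divides them by the absolute
    perturbation p*rel_delta (finite-difference derivative).  Entries
    smaller than ``deadband`` times the cell type's unperturbed
    trajectory maximum are treated as exact zeros.
    """
    if rel_delta <= 0:
        raise ValidationError("rel_delta must be positive")
    if mode not in ("difference", "derivative"):
        raise ValidationError(f"unknown sensitivity mode {mode!r}")
    t = resolve_grid(grid)

    base = simulate(params, initial, grid=t, rtol=rtol, atol=atol)
    p0 = params.to_array()
    n_params, n_times = len(PARAM_ORDER), t.size
    stacks = {name: np.zeros((n_params, n_times)) for name in STATE_ORDER}
    # dead-band scale: solver noise is relative to each trajectory's size
    scales = {name: float(np.max(np.abs(base.get(name)))) for name in STATE_ORDER}

    for i, pname in enumerate(PARAM_ORDER):
        p = p0.copy()
        delta = p[i] * rel_delta
        p[i] = p[i] + delta
        try:
            perturbed = simulate(RateParameters.from_array(p), initial, grid=t, rtol=rtol, atol=atol)
        except SimulationError as exc:
            raise SimulationError(
                f"simulation failed while perturbing {pname}: {exc}", exc.time, exc.last_state
            ) from exc
        diff = perturbed.states - base.states  # (T, 9)
        for j, name in enumerate(STATE_ORDER):
            row = diff[:, j]
            row = np.where(np.abs(row) < deadband * scales[name], 0.0, row)
            if mode == "derivative":
                # a zero parameter cannot be perturbed multiplicatively;
                # its difference row is exactly zero anyway
                row = row / delta if delta > 0 else np.zeros_like(row)
            stacks[name][i] = row

    raw = {name: stacks[name] for name in STATE_ORDER}
    normalized = {name: normalize_matrix(stacks[name]) for name in STATE_ORDER}
    return SensitivityTensor(times=t, raw=raw, normalized=normalized, rel_delta=rel_delta, mode=mode)


def export_heatmaps(
    tensor: SensitivityTensor,
    path: str | Path,
    image_format: str = "png",
    cmap: str = "bwr",
    dpi: int = 150,
) -> dict[str, dict[str, Path]]:
    """Write one diverging heatmap and one CSV matrix per cell type.

    Heatmaps use a blue-white-red gradient pinned to [-1, +1]; rows are
    the 17 parameters in canonical order, columns the hourly time points.
    The CSV holds the normalized matrix and round-trips exactly through
    :func:`pandas.read_csv`.  Returns the written paths per cell type.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(path)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, dict[str, Path]] = {}
    for name in STATE_ORDER:
        matrix = tensor.normalized[name]
        csv_path = outdir / f"sensitivity_{name}.csv"
        # %.17g guarantees bit-exact float64 round-trip through the CSV
        tensor.matrix(name).rename_axis("parameter").to_csv(csv_path, float_format="%.17g")

        fig, ax = plt.subplots(figsize=(8, 4.5))
        im = ax.imshow(
            matrix,
            aspect="auto",
            cmap=cmap,
            vmin=-1.0,
            vmax=1.0,
            interpolation="nearest",
            extent=(tensor.times[0], tensor.times[-1], len(PARAM_ORDER) - 0.5, -0.5),
        )
        ax.set_yticks(range(len(PARAM_ORDER)))
        ax.set_yticklabels(PARAM_ORDER, fontsize=6)
        ax.set_xlabel("days post-injury")
        ax.set_title(f"{name} sensitivity (normalized trajectory {tensor.mode})")
        fig.colorbar(im, ax=ax, label="normalized change")
        img_path = outdir / f"sensitivity_{name}.{image_format}"
        fig.savefig(img_path, dpi=dpi, bbox_inches="tight")
        plt.close(fig)
        written[name] = {"csv": csv_path, "image": img_path}
    return written
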