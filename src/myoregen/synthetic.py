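"""Synthetic annotated-cell-count data with the study's replicate structure.

The generator forward-simulates the regeneration ODE to obtain true
densities, then emulates what an annotated single-cell experiment would
observe: per day, a handful of replicate libraries of 10,000-20,000
sequenced cells, about half of which belong to unmodeled tissue types
(fibro-adipogenic, endothelial, ...) that are discarded before
proportions are computed.  Cross-replicate compositional variability is
modeled as Dirichlet noise around the true composition, with counts
drawn multinomially (a Dirichlet-multinomial observation model); real
time courses show replicate-to-replicate swings of tens of percentage
points in the dominant types, which the default concentration emulates.

Dead cells (Md, Nd) are unobservable and never appear in count tables.
The generator also returns the matching reference lineage densities and
the noise-free calibrated targets, so calibration and fitting can be
scored against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calibration import (
    CalibratedTargets,
    LINEAGE_TYPES,
    ReferenceLineageCounts,
    calibrate,
)
from .simulate import simulate
from .state import OBSERVABLE_TYPES, STATE_ORDER, CellState, RateParameters, ValidationError

#: Reference measurement days: the day-3 slot is applied to day-3.5 data.
REFERENCE_DAYS: tuple[float, ...] = (0.0, 1.0, 3.0, 7.0)


@dataclass(frozen=True)
class SyntheticStudyConfig:
    """Replicate structure and noise levels of the emulated study.

    Defaults mirror the training time course: six observation days with
    3-4 replicates each, libraries of 10,000-20,000 cells before
    unmodeled types are discarded, unmodeled types making up about half
    of each library, and strong cross-replicate compositional noise
    (Dirichlet concentration 10 gives mid-proportion swings of roughly
    +/- 15 percentage points across replicates, matching the variability
    seen in real time courses).
    """

    days: tuple[float, ...] = (0.0, 1.0, 2.0, 3.5, 5.0, 7.0)
    replicates: tuple[int, ...] = (4, 4, 3, 4, 3, 3)
    cells_min: int = 10_000
    cells_max: int = 20_000
    other_fraction: float = 0.5
    concentration: float = 10.0
    reference_noise_sigma: float = 0.0  # lognormal sigma on reference counts
    seed: int = 0

    def __post_init__(self) -> None:
        days = tuple(float(d) for d in self.days)
        if tuple(sorted(days)) != days:
            raise ValidationError("days must be sorted")
        reps = self.replicates
        if isinstance(reps, int):
            reps = (reps,) * len(days)
        reps = tuple(int(r) for r in reps)
        if len(reps) != len(days):
            raise ValidationError("need one replicate count per day")
        if any(r < 1 for r in reps):
            raise ValidationError("replicate counts must be >= 1")
        if not (0 <= self.other_fraction < 1):
            raise ValidationError("other_fraction must be in [0, 1)")
        if self.concentration is not None and self.concentration <= 0:
            raise ValidationError("Dirichlet concentration must be positive (or None for no noise)")
        if self.cells_min < 1 or self.cells_max < self.cells_min:
            raise ValidationError("invalid cells-per-replicate range")
        object.__setattr__(self, "days", days)
        object.__setattr__(self, "replicates", reps)


def _true_proportions(states: np.ndarray) -> np.ndarray:
    """Observable-type composition of each row of a (D, 9) state array."""
    idx = [STATE_ORDER.index(t) for t in OBSERVABLE_TYPES]
    obs = states[:, idx]
    totals = obs.sum(axis=1)
    if np.any(totals <= 0):
        raise ValidationError("all observable densities are zero at a requested day")
    return obs / totals[:, None]


def generate_ground_truth(
    params: RateParameters,
    initial: CellState,
    cfg: SyntheticStudyConfig | None = None,
) -> tuple[pd.DataFrame, ReferenceLineageCounts, CalibratedTargets]:
    """Simulate the model and observe it through a noisy replicate design.

    Returns ``(count_table, reference, true_targets)``:

    * ``count_table`` -- long frame (day, replicate, cell_type, count)
      with integer counts for the seven observable types, obtained by
      Dirichlet-multinomial sampling of the true composition (with the
      lumped "other" category generated and discarded);
    * ``reference`` -- monocyte/macrophage-lineage densities at the
      reference days, read off the true trajectory (the day-3 slot holds
      the day-3.5 truth, mirroring how that measurement is applied);
    * ``true_targets`` -- calibration of the noise-free composition with
      that reference, the ground truth for recovery scoring.
    """
    if cfg is None:
        cfg = SyntheticStudyConfig()
    rng = np.random.default_rng(cfg.seed)

    # truth at observation days plus the reference measurement days
    ref_sample_days = [0.0, 1.0, 3.5, 7.0]
    all_days = np.array(sorted(set(cfg.days) | set(ref_sample_days)))
    traj = simulate(params, initial, grid=all_days)
    day_row = {d: i for i, d in enumerate(all_days)}

    obs_days = np.array(cfg.days)
    obs_states = traj.states[[day_row[d] for d in obs_days]]
    true_props = _true_proportions(obs_states)

    # reference lineage densities from the true trajectory
    lineage_idx = [STATE_ORDER.index(t) for t in LINEAGE_TYPES]
    ref_counts = []
    for d in ref_sample_days:
        total = float(traj.states[day_row[d], lineage_idx].sum())
        if cfg.reference_noise_sigma > 0:
            total *= float(rng.lognormal(0.0, cfg.reference_noise_sigma))
        ref_counts.append(max(total, 1e-9))
    reference = ReferenceLineageCounts(days=REFERENCE_DAYS, counts=tuple(ref_counts))

    rows = []
    for d_idx, (day, n_reps) in enumerate(zip(cfg.days, cfg.replicates)):
        # library composition: observables scaled down, plus lumped "other"
        base = np.append(true_props[d_idx] * (1.0 - cfg.other_fraction), cfg.other_fraction)
        for rep in range(1, n_reps + 1):
            props = _noisy_composition(base, cfg.concentration, rng)
            n_cells = int(rng.integers(cfg.cells_min, cfg.cells_max + 1))
            counts = rng.multinomial(n_cells, props)[: len(OBSERVABLE_TYPES)]  # discard "other"
            for cell_type, count in zip(OBSERVABLE_TYPES, counts):
                rows.append(
                    {"day": day, "replicate": f"rep{rep}", "cell_type": cell_type, "count": int(count)}
                )
    count_table = pd.DataFrame(rows)

    true_prop_frame = pd.DataFrame(
        {
            "day": np.repeat(obs_days, len(OBSERVABLE_TYPES)),
            "replicate": "truth",
            "cell_type": np.tile(OBSERVABLE_TYPES, obs_days.size),
            "proportion": true_props.ravel(),
        }
    )
    true_targets = calibrate(true_prop_frame, reference=reference)
    return count_table, reference, true_targets


def _noisy_composition(base: np.ndarray, concentration: float | None, rng) -> np.ndarray:
    """Dirichlet draw around ``base``; zero-probability types stay exactly zero."""
    if concentration is None or np.isinf(concentration):
        return base
    positive = base > 0
    alpha = concentration * base[positive]
    draw = np.zeros_like(base)
    draw[positive] = rng.dirichlet(alpha)
    return draw


def generate_validation_set(
    params: RateParameters,
    initial: CellState,
    cfg: SyntheticStudyConfig | None = None,
) -> pd.DataFrame:
    """Count table with the validation time course's day structure.

    The validation series lacks a day-1 time point: it observes days
    0, 2, 5 and 7 only.  Other settings are taken from ``cfg``.
    """
    if cfg is None:
        cfg = SyntheticStudyConfig()
    days = (0.0, 2.0, 5.0, 7.0)
    reps = dict(zip(cfg.days, cfg.replicates))
    cfg_val = SyntheticStudyConfig(
        days=days,
        replicates=tuple(reps.get(d, 3) for d in days),
        cells_min=cfg.cells_min,
        cells_max=cfg.cells_max,
        other_fraction=cfg.other_fraction,
        concentration=cfg.concentration,
        reference_noise_sigma=cfg.reference_noise_sigma,
        seed=cfg.seed,
    )
    counts, _, _ = generate_ground_truth(params, initial, cfg_val)
    return counts
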