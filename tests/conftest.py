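"""Shared fixtures: canonical model setup and expensive shared computations."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import myoregen as mr

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")
from myoregen.calibration import default_dead_cell_frame


@pytest.fixture(scope="session")
def optimized_params() -> mr.RateParameters:
    return mr.presets.optimized_parameters()


@pytest.fixture(scope="session")
def initial_state() -> mr.CellState:
    return mr.presets.default_initial_state()


@pytest.fixture(scope="session")
def fitted_hourly_trajectory(optimized_params, initial_state) -> mr.Trajectory:
    """Hourly trajectory of the fitted model over the 7-day window."""
    return mr.simulate(optimized_params, initial_state, grid="hourly")


@pytest.fixture(scope="session")
def noise_free_targets(optimized_params, initial_state) -> mr.CalibratedTargets:
    """Targets generated by simulating the fitted model (no noise),

    including the fixed single-cell day-7 dead-cell targets.
    """
    traj = mr.simulate(optimized_params, initial_state, grid="observation")
    rows = []
    for ct in mr.OBSERVABLE_TYPES:
        for d, v in zip(traj.times, traj.get(ct)):
            rows.append(
                {"day": d, "cell_type": ct, "target": v, "sd": 0.0, "scale_factor": np.nan}
            )
    return mr.CalibratedTargets(
        frame=pd.DataFrame(rows), dead_cell_frame=default_dead_cell_frame()
    )


@pytest.fixture(scope="session")
def self_consistency_fit(noise_free_targets, initial_state) -> mr.FitResult:
    """Bounded Nelder-Mead fit to noise-free self-generated targets.

    Started from the order-of-magnitude heuristic estimates with
    deterministic fresh-simplex restarts; shared because it is the most
    expensive computation in the suite.
    """
    return mr.fit(
        None,
        noise_free_targets,
        initial_state,
        maxfev=4000,
        restarts=2,
        xatol=1e-6,
        fatol=1e-8,
    )


@pytest.fixture(scope="session")
def sensitivity_tensor(optimized_params, initial_state) -> mr.SensitivityTensor:
    """Hourly 0.1% one-sided perturbation sensitivities at the fitted point."""
    return mr.perturbation_sensitivity(optimized_params, initial_state)
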