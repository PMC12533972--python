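"""Parameter estimation for the regeneration model.

The fit minimizes a normalized absolute-deviation error between simulated
and calibrated target densities,

    E(theta) = sum_X sum_d |Sim_X(d | theta) - T_X(d)| / max_d T_X(d),

where X ranges over the seven observable cell types at their target days
and, additionally, over the dead cells Md and Nd, each contributing only
a day-7 term with target 1 cell/mm^3 (normalized by its own max target,
which is 1).  Dividing by each type's maximum target keeps abundant
types from dominating the error.

Initial estimates are coarse order-of-magnitude values chosen so that
each flux term is roughly the size of the variable it drives (e.g. a
bilinear clearance constant is one over the partner population's peak).
The search box spans a factor of 100 below and above each initial
estimate, and optimization is bound-constrained Nelder-Mead in linear
parameter space (a log-space reparameterization is available, since the
constants span ~8 orders of magnitude).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping

import numpy as np
import pandas as pd
from scipy.optimize import Bounds, minimize
from sklearn.base import BaseEstimator

from . import presets
from .calibration import CalibratedTargets
from .simulate import SimulationError, simulate
from .state import (
    OBSERVABLE_TYPES,
    PARAM_ORDER,
    STATE_ORDER,
    CellState,
    RateParameters,
    ValidationError,
)

BOUND_FACTOR = 100.0


@dataclass(frozen=True)
class HeuristicScales:
    """Magnitude assumptions behind the order-of-magnitude initial estimates.

    All densities in cells/mm^3, fluxes in cells/mm^3 per day.
    """

    peak_n: float = 1000.0          # largest calibrated neutrophil density
    peak_m1: float = 10000.0        # order of the M1 macrophage peak
    peak_m2: float = 10000.0        # order of the M2 macrophage peak
    initial_md: float = 30000.0     # dead myonuclei left by a strong injury
    neutrophil_influx: float = 1000.0  # neutrophils entering in ~1 day
    monocyte_influx: float = 5000.0    # monocytes entering in ~1 day
    debris_saturation: float = 1000.0  # debris level halving the M1->M2 switch
    exit_rate: float = 1.0          # generic first-order exit (1/day)


def heuristic_initial_estimates(
    scales: HeuristicScales | Mapping[str, float] | None = None,
    bound_factor: float = BOUND_FACTOR,
) -> "ParameterSpec":
    """Order-of-magnitude initial estimates and their search box.

    Bilinear interaction constants are set to 1/(partner population's
    assumed peak); influx constants to (required flux)/(driver
    magnitude); first-order exits to 1/day; the M1->M2 transition scale
    and its saturation constant to the debris scale.  Bounds are the
    estimate divided/multiplied by ``bound_factor``.
    """
    if scales is None:
        scales = HeuristicScales()
    if isinstance(scales, Mapping):
        scales = HeuristicScales(**scales)

    rules: dict[str, Callable[[HeuristicScales], float]] = {
        "cNMd": lambda s: 1.0 / s.peak_n,
        "cM1Md": lambda s: 1.0 / s.peak_m1,
        "cNin": lambda s: s.neutrophil_influx / s.initial_md,
        "cNout": lambda s: s.exit_rate,
        "cM1Nd": lambda s: 1.0 / s.peak_m1,
        "cMin": lambda s: s.monocyte_influx / s.peak_n,
        "cMM1": lambda s: 1.0 / s.initial_md,
        "cMout": lambda s: s.exit_rate,
        "cM1M2": lambda s: s.debris_saturation,
        "cM1M2inhib": lambda s: s.debris_saturation,
        "cM2out": lambda s: s.exit_rate,
        "cQSCN": lambda s: 1.0 / s.peak_n,
        "cQSCMd": lambda s: 1.0 / s.initial_md,
        "cASCM2": lambda s: 1.0 / s.peak_m2,
        "cASCpro": lambda s: 1.0 / s.peak_m1,
        "cASCdiff": lambda s: 1.0 / s.peak_m2,
        "cMcout": lambda s: s.exit_rate,
    }
    initial = {}
    for name in PARAM_ORDER:
        try:
            value = rules[name](scales)
        except (AttributeError, TypeError) as exc:
            raise ValidationError(f"missing magnitude assumption for {name}") from exc
        if not np.isfinite(value) or value <= 0:
            raise ValidationError(f"heuristic estimate for {name} is not positive: {value}")
        initial[name] = value
    return ParameterSpec.from_initial(initial, bound_factor=bound_factor)


@dataclass(frozen=True)
class ParameterSpec:
    """Initial estimate and box bounds for each rate constant."""

    initial: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    names: tuple[str, ...] = PARAM_ORDER

    def __post_init__(self) -> None:
        for label in ("initial", "lower", "upper"):
            arr = np.asarray(getattr(self, label), dtype=float)
            if arr.shape != (len(self.names),):
                raise ValidationError(f"{label} must have {len(self.names)} entries")
            object.__setattr__(self, label, arr)
        if np.any(self.lower <= 0):
            raise ValidationError("lower bounds must be positive")
        if np.any(self.lower > self.upper):
            raise ValidationError("lower bounds must not exceed upper bounds")
        if np.any((self.initial < self.lower) | (self.initial > self.upper)):
            raise ValidationError("initial estimates must lie within the bounds")

    @classmethod
    def from_initial(
        cls, initial: Mapping[str, float], bound_factor: float = BOUND_FACTOR
    ) -> "ParameterSpec":
        vec = np.array([float(initial[name]) for name in PARAM_ORDER])
        return cls(initial=vec, lower=vec / bound_factor, upper=vec * bound_factor)

    def initial_parameters(self) -> RateParameters:
        return RateParameters.from_array(self.initial)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "parameter": list(self.names),
                "initial": self.initial,
                "lower": self.lower,
                "upper": self.upper,
            }
        )


def _prepare_target_arrays(
    targets: CalibratedTargets, include_dead_cells: bool
) -> tuple[np.ndarray, list[tuple[int, np.ndarray, np.ndarray]]]:
    """Precompute (days, [(state_index, day_indices, scaled targets)]).

    Each cell type contributes |Sim - T| / max_d T at its own target
    days; returned structures let the objective avoid any pandas work.
    """
    frame = targets.full_frame() if include_dead_cells else targets.frame
    days = np.sort(frame["day"].unique())
    day_index = {d: i for i, d in enumerate(days)}
    entries = []
    for cell_type, sub in frame.groupby("cell_type"):
        t = sub["target"].to_numpy(dtype=float)
        max_t = np.max(t)
        if max_t <= 0:
            raise ValidationError(f"all targets are zero for cell type {cell_type}")
        idx = np.array([day_index[d] for d in sub["day"]], dtype=int)
        entries.append((STATE_ORDER.index(cell_type), idx, t, 1.0 / max_t))
    return days, entries


Simulator = Callable[[RateParameters, CellState, np.ndarray], np.ndarray]


class ObjectiveFunction:
    """Callable E(theta) on raw parameter vectors, with target caching.

    ``simulator``, if given, replaces ODE integration: it must map
    (params, initial, days) to a (len(days), 9) array in STATE_ORDER
    (used for stubbing in tests).
    """

    def __init__(
        self,
        targets: CalibratedTargets,
        initial: CellState,
        include_dead_cells: bool = True,
        rtol: float = 1e-6,
        atol: float = 1e-9,
        simulator: Simulator | None = None,
    ):
        if targets.frame.empty:
            raise ValidationError("no calibrated targets provided")
        self.targets = targets
        self.initial = initial
        self.days, self._entries = _prepare_target_arrays(targets, include_dead_cells)
        self.rtol = rtol
        self.atol = atol
        self.simulator = simulator

    def _simulated(self, params: RateParameters) -> np.ndarray:
        if self.simulator is not None:
            sim = np.asarray(self.simulator(params, self.initial, self.days), dtype=float)
            if sim.shape != (self.days.size, len(STATE_ORDER)):
                raise ValidationError(
                    f"stub simulator returned shape {sim.shape}, "
                    f"expected {(self.days.size, len(STATE_ORDER))}"
                )
            return sim
        traj = simulate(params, self.initial, grid=self.days, rtol=self.rtol, atol=self.atol)
        return traj.states

    def __call__(self, theta: np.ndarray) -> float:
        params = RateParameters.from_array(theta)
        try:
            sim = self._simulated(params)
        except SimulationError as exc:
            exc.params = params  # attach the offending parameter vector
            raise
        total = 0.0
        for state_idx, day_idx, t, inv_max in self._entries:
            total += float(np.sum(np.abs(sim[day_idx, state_idx] - t)) * inv_max)
        return total


def error(
    params: RateParameters,
    targets: CalibratedTargets,
    initial: CellState,
    include_dead_cells: bool = True,
    simulator: Simulator | None = None,
    rtol: float = 1e-6,
    atol: float = 1e-9,
) -> float:
    """Normalized absolute-deviation error E(theta) for one parameter set."""
    obj = ObjectiveFunction(
        targets,
        initial,
        include_dead_cells=include_dead_cells,
        rtol=rtol,
        atol=atol,
        simulator=simulator,
    )
    return obj(params.to_array())


@dataclass(frozen=True)
class FitResult:
    """Outcome of a bounded Nelder-Mead fit."""

    params: RateParameters
    error: float
    trace: np.ndarray  # best-so-far error after each function evaluation
    converged: bool
    n_evaluations: int
    spec: ParameterSpec
    targets: CalibratedTargets
    initial_state: CellState

    def to_frame(self) -> pd.DataFrame:
        """Table 'parameter, initial, lower, upper, optimized'."""
        df = self.spec.to_frame()
        df["optimized"] = self.params.to_array()
        return df


class RegenerationModelFitter(BaseEstimator):
    """Bound-constrained Nelder-Mead fitter for the regeneration model.

    scikit-learn-style estimator: :meth:`fit` takes calibrated targets,
    after which ``params_`` holds the fitted :class:`RateParameters` and
    :meth:`predict` simulates trajectories with them.

    Parameters
    ----------
    spec
        Initial estimates and bounds; defaults to the order-of-magnitude
        heuristic with 100-fold bounds.
    include_dead_cell_targets
        Include the fixed single-cell day-7 targets for Md and Nd in the
        error.  Their normalization by a max target of 1 gives them
        weight comparable to thousands of live cells; disable to inspect
        the fit without them.
    maxfev
        Function-evaluation budget for each Nelder-Mead run.
    log_scale
        Optimize log10(parameters) instead of the parameters themselves.
    restarts
        Additional Nelder-Mead runs, each started with a fresh simplex
        from the best point found so far (0 = single run from the
        initial estimate).  Restarting counters simplex collapse and is
        fully deterministic.
    seed
        Seed for the optional random jitter applied to restart points
        when ``jitter > 0``; unused otherwise (the fit is deterministic).
    jitter
        Half-width, in decades, of a seeded log-uniform perturbation of
        each restart point (0 = restart exactly from the best point).
    """

    def __init__(
        self,
        spec: ParameterSpec | None = None,
        include_dead_cell_targets: bool = True,
        maxfev: int = 10_000,
        xatol: float = 1e-4,
        fatol: float = 1e-6,
        log_scale: bool = False,
        restarts: int = 0,
        seed: int | None = None,
        jitter: float = 0.0,
        rtol: float = 1e-6,
        atol: float = 1e-9,
        simulator: Simulator | None = None,
    ):
        self.spec = spec
        self.include_dead_cell_targets = include_dead_cell_targets
        self.maxfev = maxfev
        self.xatol = xatol
        self.fatol = fatol
        self.log_scale = log_scale
        self.restarts = restarts
        self.seed = seed
        self.jitter = jitter
        self.rtol = rtol
        self.atol = atol
        self.simulator = simulator

    # -- internal ----------------------------------------------------
    def _penalized(self, objective: ObjectiveFunction, trace: list[float], incumbent: dict):
        """Wrap the objective: solver failures become +inf, best-so-far traced.

        ``incumbent`` keeps the best (error, theta) ever evaluated; the
        Nelder-Mead final vertex is not always the best point visited.
        """

        def fun(theta: np.ndarray) -> float:
            try:
                value = objective(theta)
            except SimulationError:
                value = np.inf
            if value < incumbent.get("f", np.inf):
                incumbent["f"] = value
                incumbent["x"] = np.array(theta, dtype=float)
            trace.append(incumbent.get("f", np.inf))
            return value

        return fun

    def _run_nelder_mead(self, fun, x0, lower, upper):
        if self.log_scale:
            inner = lambda z: fun(10.0 ** z)
            res = minimize(
                inner,
                np.log10(x0),
                method="Nelder-Mead",
                bounds=Bounds(np.log10(lower), np.log10(upper)),
                options={
                    "maxfev": self.maxfev,
                    "xatol": self.xatol,
                    "fatol": self.fatol,
                    "adaptive": True,
                },
            )
            x_best = np.clip(10.0 ** res.x, lower, upper)
        else:
            res = minimize(
                fun,
                x0,
                method="Nelder-Mead",
                bounds=Bounds(lower, upper),
                options={
                    "maxfev": self.maxfev,
                    "xatol": self.xatol,
                    "fatol": self.fatol,
                    "adaptive": True,
                },
            )
            x_best = np.clip(res.x, lower, upper)
        return x_best, float(res.fun), bool(res.success)

    # -- estimator API -----------------------------------------------
    def fit(
        self,
        X: CalibratedTargets | pd.DataFrame,
        y=None,
        initial_state: CellState | None = None,
    ) -> "RegenerationModelFitter":
        targets = X if isinstance(X, CalibratedTargets) else _targets_from_frame(X)
        initial = initial_state if initial_state is not None else presets.default_initial_state()
        spec = self.spec if self.spec is not None else heuristic_initial_estimates()

        objective = ObjectiveFunction(
            targets,
            initial,
            include_dead_cells=self.include_dead_cell_targets,
            rtol=self.rtol,
            atol=self.atol,
            simulator=self.simulator,
        )
        trace: list[float] = []
        incumbent: dict = {}
        fun = self._penalized(objective, trace, incumbent)

        e0 = fun(spec.initial)
        if "x" not in incumbent:  # even the starting point failed to simulate
            incumbent["x"], incumbent["f"] = spec.initial.copy(), e0
        if np.array_equal(spec.lower, spec.upper):
            # degenerate box: nothing to optimize
            self._finalize(spec, targets, initial, spec.initial, e0, trace, True)
            return self

        _, _, success = self._run_nelder_mead(fun, spec.initial, spec.lower, spec.upper)
        if self.restarts > 0:
            rng = np.random.default_rng(self.seed)
            for _ in range(self.restarts):
                x0 = incumbent["x"]
                if self.jitter > 0:
                    factors = 10.0 ** rng.uniform(-self.jitter, self.jitter, size=x0.size)
                    x0 = np.clip(x0 * factors, spec.lower, spec.upper)
                _, _, s_r = self._run_nelder_mead(fun, x0, spec.lower, spec.upper)
                success = success or s_r

        # report the best feasible point ever evaluated
        x_best = np.clip(incumbent["x"], spec.lower, spec.upper)
        self._finalize(spec, targets, initial, x_best, incumbent["f"], trace, success)
        return self

    def _finalize(self, spec, targets, initial, x, f, trace, converged) -> None:
        self.spec_ = spec
        self.targets_ = targets
        self.initial_state_ = initial
        self.params_ = RateParameters.from_array(x)
        self.error_ = float(f)
        self.trace_ = np.asarray(trace)
        self.n_evaluations_ = len(trace)
        self.converged_ = bool(converged)

    def predict(self, grid="hourly"):
        """Simulate a trajectory with the fitted parameters."""
        if not hasattr(self, "params_"):
            raise ValidationError("fitter is not fitted")
        return simulate(self.params_, self.initial_state_, grid=grid, rtol=self.rtol, atol=self.atol)

    def score(self, X=None, y=None) -> float:
        """Negative fitted error (larger is better, sklearn convention)."""
        if not hasattr(self, "error_"):
            raise ValidationError("fitter is not fitted")
        return -self.error_

    def result(self) -> FitResult:
        if not hasattr(self, "params_"):
            raise ValidationError("fitter is not fitted")
        return FitResult(
            params=self.params_,
            error=self.error_,
            trace=self.trace_,
            converged=self.converged_,
            n_evaluations=self.n_evaluations_,
            spec=self.spec_,
            targets=self.targets_,
            initial_state=self.initial_state_,
        )


def _targets_from_frame(frame: pd.DataFrame) -> CalibratedTargets:
    dead = frame[frame["cell_type"].isin(["Md", "Nd"])]
    obs = frame[~frame["cell_type"].isin(["Md", "Nd"])]
    return CalibratedTargets(
        frame=obs.reset_index(drop=True),
        dead_cell_frame=dead.reset_index(drop=True) if len(dead) else None,
    )


def fit(
    spec: ParameterSpec | None,
    targets: CalibratedTargets,
    initial: CellState,
    seed: int | None = None,
    **settings,
) -> FitResult:
    """Thin functional wrapper over :class:`RegenerationModelFitter`."""
    fitter = RegenerationModelFitter(spec=spec, seed=seed, **settings)
    fitter.fit(targets, initial_state=initial)
    return fitter.result()
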