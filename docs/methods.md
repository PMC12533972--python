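# Methods

## Model and assumptions

The model tracks nine cell populations in one cubic millimeter of
injured muscle over seven days, in units of cells/mm³ and days. Injury
is encoded entirely in the initial condition (30,000 damaged myonuclei;
no ongoing damage process), and every interaction is a mass-action
(bilinear) or first-order term except the M1→M2 polarization switch,
which is a saturating transition `cM1M2·M1/(cM1M2inhib + Nd + Md)`
*inhibited* by remaining debris: macrophages stay pro-inflammatory as
long as there is material to clear, then convert. Damaged myonuclei
only ever decay; every loss term for a population contains that
population as a factor, so trajectories started non-negative remain
non-negative analytically. Influence is strictly one-way from the
immune block {Md, N, Nd, M, M1, M2} to the myogenic block
{QSC, ASC, Mc} — there is no feedback from satellite cells to immune
cells, which several tests exploit as an exact-zero prediction.
Myocyte "exit" stands for fusion into myofibers, which is not modeled;
the model makes no claims beyond the 7-day window (QSCs, for example,
have no turnover absent injury, so there is no meaningful steady state
to extrapolate to).

Two populations (Md, Nd) are unobservable in single-cell data and are
constrained only by fixed day-7 targets of one cell each, encoding
"debris is essentially gone when regeneration resolves".

## Simulation

Integration uses `scipy.integrate.solve_ivp` (adaptive explicit
Runge–Kutta, RK45) with defaults rtol = 1e-6, atol = 1e-9 — tighter
than the solver's own defaults so that reported grid values are stable
to further tightening (verified to < 0.1 % of each variable's
trajectory maximum); `loose_tolerances=True` restores the solver
defaults. The solver is evaluated exactly at the requested grid times
rather than interpolating a coarse solution. Two named grids exist: the
six empirical observation days {0, 1, 2, 3.5, 5, 7} and an hourly grid
(169 points). Tiny negative floating-point excursions (all observed
> −1e-9) are clamped to zero in reported trajectories only — never fed
back into the integration state. Peak summaries report the grid maximum
with ties broken to the earliest time, so constant trajectories peak at
t = 0. The adaptive solution is cross-checked in the tests against an
independent fixed-step explicit Euler integration (step 1e-4 days) kept
deliberately naive and separate from the implementation.

## Calibration

Per-replicate proportions are computed over the seven observable types
only (unmodeled tissue types must be discarded upstream; the loader
rejects them). The reference monocyte/macrophage-lineage densities
(100, 5,000, 20,000, 5,000 cells/mm³ at days 0, 1, 3, 7; flow
cytometry, Martinez et al.) are linearly interpolated at unmeasured
days, with one convention: day-3.5 observations use the day-3 value
directly rather than an interpolation. No extrapolation outside the
reference range is permitted. Scale factors use *unweighted*
cross-replicate mean proportions (not pooled counts); target SDs are
S(d) times the sample (n−1) SD of the proportions, with a single
replicate giving SD 0. Which denominator the original analysis used is
not stated anywhere we know of; n−1 is the conventional choice for a
handful of replicates. Days with no replicates are simply absent from
the output rather than imputed. Two identities follow algebraically and
are enforced in tests: the calibrated lineage total equals the
interpolated reference exactly, and rescaling all counts in a replicate
leaves the targets unchanged.

## Parameter fitting

The error is the normalized absolute deviation
E(θ) = Σ_X Σ_d |Sim_X(d|θ) − T_X(d)| / max_d T_X(d), with the seven
observable types contributing at every target day and Md, Nd
contributing only their day-7 unit targets. Because those two terms are
normalized by a maximum target of 1, a stray thousand simulated debris
cells at day 7 adds a thousand to E — a deliberate, strong penalty that
can be disabled (`include_dead_cell_targets=False`) for inspection.
Targets' SDs are carried for plotting but never weight the error.

Initial estimates are order-of-magnitude values constructed so each
flux term is roughly the size of the variable it drives: bilinear
constants are 1/(assumed partner peak) (peak N ≈ 1000, peak M1 and
M2 ≈ 10,000), influx constants are (required flux)/(driver magnitude)
(≈1000 neutrophils/day drawn by 30,000 Md; ≈5000 monocytes/day drawn by
1000 N), first-order exits default to 1/day, and the polarization-switch
scale and its saturation constant both take the debris scale 1000.
Bounds are the estimates ÷/× 100, and all constants are kept positive.

Optimization is Nelder–Mead with box constraints (scipy's clipped
simplex), run in linear parameter space by default; a log10
reparameterization is available since the constants span ~8 decades.
The default budget is 10,000 function evaluations. Because a collapsed
simplex is the dominant failure mode in 17 dimensions, `restarts=k`
re-runs the optimizer k further times with a fresh simplex from the
best point evaluated so far — fully deterministic (an optional seeded
log-uniform `jitter` turns this into a randomized multi-start). The
reported parameters are always the best *evaluated* feasible point, the
per-evaluation best-so-far trace is monotone by construction, and
solver failures during line search are treated as infinite error rather
than aborting the fit. Degenerate boxes (lower = upper) return the
initial estimate after a single evaluation.

On noise-free self-generated targets, fitting from the heuristic
estimates reduces E from ~2.5e4 (dominated by the dead-cell terms) by
more than five orders of magnitude, but plateaus near E ≈ 0.08 — above
the E ≈ 0.03 attained by the generating parameters themselves — even
with tens of thousands of evaluations. A local simplex method on a
17-parameter model with no identifiability guarantee should not be
expected to reproduce a particular fitted vector, and the tests
therefore score error reduction, bound respect, and determinism rather
than parameter recovery.

## Sensitivity analysis

For each rate constant in turn, the model is re-simulated with that
constant increased by 0.1 % and the unperturbed trajectory subtracted,
on the hourly grid. Differences are stored raw (per the operational
one-sided-perturbation procedure); dividing by the absolute parameter
perturbation — a finite-difference derivative, which changes
cross-parameter comparability inside each heatmap but not within-row
shapes — is available as `mode="derivative"`. Each cell type's 17×169
matrix is scaled by its largest absolute entry into [−1, 1]; all-zero
matrices stay all-zero rather than dividing 0/0.

Two numerical choices make the structural zeros exact: sensitivity
simulations run at tight tolerances (rtol 1e-10, atol 1e-12), and
differences below a dead-band of 1e-9 × (the cell type's trajectory
maximum) are snapped to zero. Without these, the adaptive solver's
step-size coupling would leave ~1e-6-relative noise in the
immune × satellite-parameter blocks that the model structure says are
exactly zero. Heatmaps use a blue–white–red gradient pinned to
[−1, +1]; the accompanying CSVs are written at %.17g so they round-trip
float64 exactly (read them back with pandas'
`float_precision="round_trip"`).

One caveat discovered while testing at the canonical fitted point:
because the fitted cNMd sits at its lower bound, the *direct* effect of
increasing it (faster clearance of Md by neutrophils) dominates only in
the first half-day; afterwards the indirect path — more
phagocytosis-induced neutrophil death → fewer monocytes and M1
macrophages → slower Md clearance — wins, and the Md sensitivity to
cNMd turns weakly positive (≈5 % of the heatmap color scale, i.e.
visually white). The package asserts only the early-window negativity
in its unit tests.

## Synthetic data

The generator forward-simulates the model, then emulates an annotated
single-cell experiment: six observation days with (4, 4, 3, 4, 3, 3)
replicates, libraries of 10,000–20,000 cells, and a lumped "other"
category (default 50 % of each library) representing unmodeled tissue
types that is generated and discarded before proportions are computed,
mirroring the real analysis's discarding step. Cross-replicate
compositional noise is Dirichlet (concentration × true composition)
with multinomial counting on top — a Dirichlet-multinomial observation
model. The default concentration of 10 produces replicate-to-replicate
swings of roughly ±15 percentage points in mid-range proportions,
comparable to the strong variability reported for real replicates; the
generator makes no attempt to distinguish biological from technical
variability. Cell types with exactly zero true density stay exactly
zero. Dead cells are never emitted. Reference lineage densities are
read off the true trajectory at days 0, 1, 3, 7 — with the day-3 slot
holding the day-3.5 truth, so the day-3.5 reuse convention is exact —
and can be degraded with lognormal noise. The returned "true targets"
are the calibration of the noise-free composition with that reference;
at days whose reference value is interpolated (2 and 5) they differ
from the raw simulated densities by the interpolation error, which is
the correct ground truth for scoring the calibrate-then-fit pipeline.
A validation-style table restricted to days {0, 2, 5, 7} (no day-1
time point) is also available.

What passing synthetic tests show: the calibration arithmetic inverts
the generator exactly in the noise-free large-library limit, and the
full generate → calibrate → fit pipeline recovers targets well under
realistic noise. What they do not show: robustness to annotation error,
doublets, ambient RNA, or day-to-day technical batch effects, none of
which the generator models.

## Problem sizes

Default test-suite sizes: 20 random draws for the Euler-oracle
comparison, hourly grids for trajectory-level checks, and fit budgets
of 4,000 evaluations with 1–2 restarts for the self-consistency and
end-to-end recovery tests — enough for the error-reduction criteria
with comfortable margin while keeping the suite in a few minutes on one
CPU.
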