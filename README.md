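# myoregen

Cell-population dynamics of skeletal muscle regeneration after acute
injury, as a tested Python package: a nine-population nonlinear ODE
model of the injury–immune–stem-cell cascade, calibration of
single-cell-derived cell-type proportions to absolute tissue densities,
bounded Nelder–Mead parameter fitting, local perturbation sensitivity
analysis, and a synthetic-data generator that emulates the replicate
structure of annotated scRNA-seq time courses.

## The problem

After a toxin injury (e.g. notexin in mouse tibialis anterior), muscle
passes through an inflammatory phase (neutrophils, then monocytes and
pro-inflammatory M1 macrophages clear debris), an anti-inflammatory
phase (M1 → M2 polarization), and a myogenic phase (quiescent satellite
cells activate, proliferate, and differentiate into myocytes, with a few
returning to quiescence). Annotated scRNA-seq time series give per-day,
per-replicate *proportions* of these cell types; the package turns those
into absolute densities and asks whether known cell–cell interactions
suffice to reproduce the observed population dynamics.

## The model

Nine populations (cells/mm³) — damaged myonuclei Md, neutrophils N,
dead neutrophils Nd, monocytes M, M1 and M2 macrophages, quiescent
(QSC) and activated (ASC) satellite cells, myocytes Mc — coupled by 17
non-negative rate constants:

    dMd/dt  = −cNMd·N·Md − cM1Md·M1·Md
    dN/dt   =  cNin·Md − cNout·N − cNMd·N·Md
    dNd/dt  =  cNMd·N·Md − cM1Nd·M1·Nd
    dM/dt   =  cMin·N − cMM1·M·(Nd+Md) − cMout·M
    dM1/dt  =  cMM1·M·(Nd+Md) − cM1M2·M1/(cM1M2inhib+Nd+Md)
    dM2/dt  =  cM1M2·M1/(cM1M2inhib+Nd+Md) − cM2out·M2
    dQSC/dt = −cQSCN·QSC·N − cQSCMd·QSC·Md + cASCM2·ASC·M2
    dASC/dt =  cQSCN·QSC·N + cQSCMd·QSC·Md − cASCM2·ASC·M2
               + cASCpro·ASC·M1 − cASCdiff·ASC·M2
    dMc/dt  =  cASCdiff·ASC·M2 − cMcout·Mc

Injury is an initial condition (Md(0) = 30,000). The M1→M2 switch is
*inhibited* by remaining debris (the saturating term), and M2
macrophages both differentiate ASCs into myocytes and return them to
quiescence. Influence runs one way, immune → myogenic.

Calibration uses externally measured monocyte/macrophage-lineage
densities T(d) (flow cytometry; 100, 5,000, 20,000, 5,000 cells/mm³ at
days 0, 1, 3, 7): with cross-replicate mean proportions P_X(d), the
day-d scale factor is S(d) = T(d)/P_{M+M1+M2}(d) and the target for
cell type X is T_X(d) = S(d)·P_X(d).

Fitting minimizes the normalized absolute deviation
E(θ) = Σ_X Σ_d |Sim_X(d|θ) − T_X(d)| / max_d T_X(d) over a 100-fold
box around order-of-magnitude initial estimates, with bound-constrained
Nelder–Mead.

## Worked example

```python
import myoregen as mr

params = mr.presets.optimized_parameters()      # fitted rate constants
initial = mr.presets.default_initial_state()    # calibrated day-0 state
traj = mr.simulate(params, initial, grid="hourly")
print(mr.summarize_peaks(traj).set_index("cell_type").round(1))
```

prints

```
           peak_value  peak_time
cell_type
Md            30000.0        0.0
N              1094.8        0.9
Nd              141.4        1.0
M              5069.1        1.4
M1             7050.8        1.8
M2             6037.8        7.0
QSC            2105.1        7.0
ASC             913.6        3.5
Mc              247.4        5.0
```

i.e. the fitted model produces the expected regeneration choreography:
a neutrophil wave peaking near day 1 at ~1,100 cells/mm³, monocytes and
M1 macrophages peaking between days 1 and 2 (M1 ≈ 7,000 cells/mm³), the
anti-inflammatory M2 population rising through the week, satellite-cell
activation peaking around day 3.5, and myocytes appearing late.

The same pipeline runs from the shell:

```sh
myoregen synth --outdir data/            # synthetic replicate counts + truth
myoregen calibrate --counts data/counts.csv --reference data/reference.csv \
                   --out targets.csv     # proportions -> cells/mm^3
myoregen fit --targets targets.csv --out fitted.csv
myoregen simulate --out trajectory.csv --peaks peaks.csv
myoregen sensitivity --outdir heatmaps/  # per-cell-type heatmaps + CSV
```

Estimator-style classes (`DensityCalibrator`, `RegenerationModelFitter`)
expose the calibration and fitting steps with the scikit-learn
`fit`/`transform`/`predict` conventions.

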