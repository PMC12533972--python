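"""Right-hand side of the nine coupled population ODEs.

The model couples an injury/immune cascade to the myogenic lineage:

    dMd/dt  = -cNMd*N*Md - cM1Md*M1*Md
    dN/dt   =  cNin*Md - cNout*N - cNMd*N*Md
    dNd/dt  =  cNMd*N*Md - cM1Nd*M1*Nd
    dM/dt   =  cMin*N - cMM1*M*(Nd+Md) - cMout*M
    dM1/dt  =  cMM1*M*(Nd+Md) - cM1M2*M1/(cM1M2inhib+Nd+Md)
    dM2/dt  =  cM1M2*M1/(cM1M2inhib+Nd+Md) - cM2out*M2
    dQSC/dt = -cQSCN*QSC*N - cQSCMd*QSC*Md + cASCM2*ASC*M2
    dASC/dt =  cQSCN*QSC*N + cQSCMd*QSC*Md - cASCM2*ASC*M2
               + cASCpro*ASC*M1 - cASCdiff*ASC*M2
    dMc/dt  =  cASCdiff*ASC*M2 - cMcout*Mc

Structural consequences used throughout the test suite: damaged myonuclei
only decay; every negative term in dX/dt carries X as a factor (so
trajectories started non-negative stay non-negative); the immune block
{Md, N, Nd, M, M1, M2} evolves independently of the myogenic block
{QSC, ASC, Mc} (one-way coupling); and in the absence of
influx/outflux/proliferation terms the neutrophil, monocyte-lineage and
myogenic totals are each conserved.
"""

from __future__ import annotations

import numpy as np

from .state import PARAM_ORDER, STATE_ORDER, CellState, RateParameters

#: Names of the distinct flux expressions appearing in the equations.
FLUX_NAMES: tuple[str, ...] = (
    "N_Md_phagocytosis",  # cNMd*N*Md   (Md loss, N loss, Nd gain)
    "M1_Md_clearance",    # cM1Md*M1*Md (Md loss)
    "N_influx",           # cNin*Md     (N gain)
    "N_outflux",          # cNout*N     (N loss)
    "M1_Nd_clearance",    # cM1Nd*M1*Nd (Nd loss)
    "M_influx",           # cMin*N      (M gain)
    "M_to_M1",            # cMM1*M*(Nd+Md) (M loss, M1 gain)
    "M_outflux",          # cMout*M     (M loss)
    "M1_to_M2",           # cM1M2*M1/(cM1M2inhib+Nd+Md) (M1 loss, M2 gain)
    "M2_outflux",         # cM2out*M2   (M2 loss)
    "QSC_activation_by_N",   # cQSCN*QSC*N   (QSC loss, ASC gain)
    "QSC_activation_by_Md",  # cQSCMd*QSC*Md (QSC loss, ASC gain)
    "ASC_deactivation",      # cASCM2*ASC*M2 (ASC loss, QSC gain)
    "ASC_proliferation",     # cASCpro*ASC*M1 (ASC gain)
    "ASC_differentiation",   # cASCdiff*ASC*M2 (ASC loss, Mc gain)
    "Mc_outflux",            # cMcout*Mc  (Mc loss)
)

#: Signed incidence of each flux on each state variable, in STATE_ORDER.
#: Summing sign * flux per variable reconstructs the right-hand side.
FLUX_SIGNS: dict[str, dict[str, int]] = {
    "N_Md_phagocytosis": {"Md": -1, "N": -1, "Nd": +1},
    "M1_Md_clearance": {"Md": -1},
    "N_influx": {"N": +1},
    "N_outflux": {"N": -1},
    "M1_Nd_clearance": {"Nd": -1},
    "M_influx": {"M": +1},
    "M_to_M1": {"M": -1, "M1": +1},
    "M_outflux": {"M": -1},
    "M1_to_M2": {"M1": -1, "M2": +1},
    "M2_outflux": {"M2": -1},
    "QSC_activation_by_N": {"QSC": -1, "ASC": +1},
    "QSC_activation_by_Md": {"QSC": -1, "ASC": +1},
    "ASC_deactivation": {"QSC": +1, "ASC": -1},
    "ASC_proliferation": {"ASC": +1},
    "ASC_differentiation": {"ASC": -1, "Mc": +1},
    "Mc_outflux": {"Mc": -1},
}


def _saturating_transition(numerator: float, denominator: float) -> float:
    """The M1->M2 flux cM1M2*M1 / (cM1M2inhib + Nd + Md), as written.

    A zero denominator can only occur with cM1M2inhib = 0 and no debris;
    the flux is then zero whenever no M1 are present to transition (the
    0/0 limit along admissible states), and genuinely singular otherwise.
    """
    if denominator > 0.0:
        return numerator / denominator
    return 0.0 if numerator == 0.0 else np.inf


def rhs_array(y: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Evaluate the nine derivatives (cells/mm^3 per day) on raw vectors.

    ``y`` is a length-9 state in :data:`~myoregen.state.STATE_ORDER`;
    ``p`` a length-17 parameter vector in
    :data:`~myoregen.state.PARAM_ORDER`.  No validation is performed;
    this is the hot path used inside the ODE solver.
    """
    Md, N, Nd, M, M1, M2, QSC, ASC, Mc = y
    (cNMd, cM1Md, cNin, cNout, cM1Nd, cMin, cMM1, cMout, cM1M2,
     cM1M2inhib, cM2out, cQSCN, cQSCMd, cASCM2, cASCpro, cASCdiff,
     cMcout) = p

    phagocytosis = cNMd * N * Md
    debris = Nd + Md
    m_to_m1 = cMM1 * M * debris
    m1_to_m2 = _saturating_transition(cM1M2 * M1, cM1M2inhib + debris)
    activation = cQSCN * QSC * N + cQSCMd * QSC * Md
    deactivation = cASCM2 * ASC * M2
    differentiation = cASCdiff * ASC * M2

    return np.array(
        [
            -phagocytosis - cM1Md * M1 * Md,
            cNin * Md - cNout * N - phagocytosis,
            phagocytosis - cM1Nd * M1 * Nd,
            cMin * N - m_to_m1 - cMout * M,
            m_to_m1 - m1_to_m2,
            m1_to_m2 - cM2out * M2,
            -activation + deactivation,
            activation - deactivation + cASCpro * ASC * M1 - differentiation,
            differentiation - cMcout * Mc,
        ]
    )


def rhs(state: CellState, params: RateParameters) -> np.ndarray:
    """Evaluate the nine derivatives for a validated state and parameters.

    Returns a length-9 vector in :data:`~myoregen.state.STATE_ORDER`.
    Validation (non-negativity, field naming on error) happens when the
    ``CellState``/``RateParameters`` are constructed.
    """
    return rhs_array(state.to_array(), params.to_array())


def flux_terms(state: CellState, params: RateParameters) -> dict[str, float]:
    """Evaluate every distinct flux expression of the model.

    Shared terms (e.g. the phagocytosis flux ``cNMd*N*Md``, which drains
    Md and N and feeds Nd) are reported once; :data:`FLUX_SIGNS` records
    how each flux enters each equation, and the signed per-variable sums
    reproduce :func:`rhs` up to floating-point rounding.
    """
    Md, N, Nd, M, M1, M2, QSC, ASC, Mc = state.to_array()
    p = params
    debris = Nd + Md
    return {
        "N_Md_phagocytosis": p.cNMd * N * Md,
        "M1_Md_clearance": p.cM1Md * M1 * Md,
        "N_influx": p.cNin * Md,
        "N_outflux": p.cNout * N,
        "M1_Nd_clearance": p.cM1Nd * M1 * Nd,
        "M_influx": p.cMin * N,
        "M_to_M1": p.cMM1 * M * debris,
        "M_outflux": p.cMout * M,
        "M1_to_M2": _saturating_transition(p.cM1M2 * M1, p.cM1M2inhib + debris),
        "M2_outflux": p.cM2out * M2,
        "QSC_activation_by_N": p.cQSCN * QSC * N,
        "QSC_activation_by_Md": p.cQSCMd * QSC * Md,
        "ASC_deactivation": p.cASCM2 * ASC * M2,
        "ASC_proliferation": p.cASCpro * ASC * M1,
        "ASC_differentiation": p.cASCdiff * ASC * M2,
        "Mc_outflux": p.cMcout * Mc,
    }


def rhs_from_fluxes(fluxes: dict[str, float]) -> np.ndarray:
    """Reassemble the derivative vector from named fluxes via FLUX_SIGNS."""
    out = np.zeros(len(STATE_ORDER))
    index = {name: i for i, name in enumerate(STATE_ORDER)}
    for flux_name, incidence in FLUX_SIGNS.items():
        value = fluxes[flux_name]
        for var, sign in incidence.items():
            out[index[var]] += sign * value
    return out


# every parameter must appear in at least one flux, and flux bookkeeping
# must be internally consistent
assert set(FLUX_SIGNS) == set(FLUX_NAMES)
assert len(PARAM_ORDER) == 17 and len(STATE_ORDER) == 9
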