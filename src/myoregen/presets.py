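"""Canonical parameterization of the regeneration model.

These constants describe the notexin-injury regeneration time course in
mouse tibialis anterior muscle: the order-of-magnitude initial estimates
used to seed parameter fitting, the 100-fold search bounds around them,
the fitted (optimized) rate constants, the calibrated day-0 initial
densities, and the flow-cytometry reference counts of the
monocyte/macrophage lineage (Martinez et al.) used for calibrating
single-cell proportions to absolute densities.
"""

from __future__ import annotations

from .state import CellState, RateParameters

#: Days post-injury at which the training time series was observed.
OBSERVATION_DAYS: tuple[float, ...] = (0.0, 1.0, 2.0, 3.5, 5.0, 7.0)

#: Days post-injury in the independent validation time series.
VALIDATION_DAYS: tuple[float, ...] = (0.0, 2.0, 5.0, 7.0)

#: Order-of-magnitude initial estimates for the rate constants.
INITIAL_ESTIMATES: dict[str, float] = {
    "cNMd": 1.0000e-03,
    "cM1Md": 1.0000e-04,
    "cNin": 3.3333e-02,
    "cNout": 1.0000e00,
    "cM1Nd": 1.0000e-04,
    "cMin": 5.0000e00,
    "cMM1": 3.3333e-05,
    "cMout": 1.0000e00,
    "cM1M2": 1.0000e03,
    "cM1M2inhib": 1.0000e03,
    "cM2out": 1.0000e00,
    "cQSCN": 1.0000e-03,
    "cQSCMd": 3.3333e-05,
    "cASCM2": 1.0000e-04,
    "cASCpro": 1.0000e-04,
    "cASCdiff": 1.0000e-04,
    "cMcout": 1.0000e00,
}

#: Fitted rate constants for the notexin-injury time course.
OPTIMIZED_PARAMETERS: dict[str, float] = {
    "cNMd": 1.0000e-05,
    "cM1Md": 3.8885e-04,
    "cNin": 8.9560e-02,
    "cNout": 1.2987e00,
    "cM1Nd": 2.2054e-04,
    "cMin": 2.1884e01,
    "cMM1": 9.2002e-05,
    "cMout": 3.2537e00,
    "cM1M2": 3.7605e02,
    "cM1M2inhib": 1.0522e03,
    "cM2out": 1.6957e-02,
    "cQSCN": 6.1567e-04,
    "cQSCMd": 1.1516e-06,
    "cASCM2": 2.7655e-04,
    "cASCpro": 2.2439e-04,
    "cASCdiff": 6.9390e-05,
    "cMcout": 5.1369e-01,
}

#: Calibrated day-0 densities (cells/mm^3): a strong injury leaves 30,000
#: dead myonuclei; immune and myogenic populations start at their
#: calibrated day-0 values; dead neutrophils, M1 macrophages, activated
#: satellite cells and myocytes start at zero.
DEFAULT_INITIAL_STATE_VALUES: dict[str, float] = {
    "Md": 30000.0,
    "N": 20.0,
    "Nd": 0.0,
    "M": 44.0,
    "M1": 0.0,
    "M2": 56.0,
    "QSC": 111.0,
    "ASC": 0.0,
    "Mc": 0.0,
}

#: Flow-cytometry counts of the total monocyte/macrophage lineage
#: (M + M1 + M2, cells/mm^3) at days 0, 1, 3 and 7 post-injury in
#: wild-type mice (Martinez et al.). The day-3 value is conventionally
#: reused for day-3.5 observations.
MARTINEZ_LINEAGE_COUNTS: dict[float, float] = {0.0: 100.0, 1.0: 5000.0, 3.0: 20000.0, 7.0: 5000.0}


def optimized_parameters() -> RateParameters:
    """The fitted rate constants as a :class:`RateParameters`."""
    return RateParameters.from_mapping(OPTIMIZED_PARAMETERS)


def initial_estimate_parameters() -> RateParameters:
    """The order-of-magnitude initial estimates as a :class:`RateParameters`."""
    return RateParameters.from_mapping(INITIAL_ESTIMATES)


def default_initial_state() -> CellState:
    """The calibrated day-0 state as a :class:`CellState`."""
    return CellState.from_mapping(DEFAULT_INITIAL_STATE_VALUES)
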