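"""Domain types for the muscle-regeneration population model.

The model tracks nine cell populations in a cubic millimeter of injured
tissue, each in units of cells/mm^3:

=====  ==================================================================
Md     damaged (dead) myonuclei -- the injury itself; unobservable
N      neutrophils
Nd     apoptotic (dead) neutrophils; unobservable
M      monocytes
M1     classically activated (pro-inflammatory) macrophages
M2     alternatively activated (anti-inflammatory) macrophages
QSC    quiescent satellite cells (muscle stem cells)
ASC    activated / proliferating satellite cells
Mc     myocytes (differentiated, pre-fusion myogenic cells)
=====  ==================================================================

Md and Nd cannot be captured by single-cell assays, so they are flagged
unobservable; the other seven populations are the observable cell types
that count tables and calibrated targets refer to.

Seventeen non-negative rate constants govern the fluxes between these
populations; see :mod:`myoregen.dynamics` for the equations.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import yaml

#: Fixed ordering of the nine state variables, used for all vectorization.
STATE_ORDER: tuple[str, ...] = ("Md", "N", "Nd", "M", "M1", "M2", "QSC", "ASC", "Mc")

#: The seven cell types observable in annotated single-cell data.
OBSERVABLE_TYPES: tuple[str, ...] = ("N", "M", "M1", "M2", "QSC", "ASC", "Mc")

#: Populations that never appear in count tables (dead cells).
UNOBSERVABLE_TYPES: tuple[str, ...] = ("Md", "Nd")

#: Fixed ordering of the seventeen rate constants, used for the
#: optimization vector and all serialization.
PARAM_ORDER: tuple[str, ...] = (
    "cNMd",
    "cM1Md",
    "cNin",
    "cNout",
    "cM1Nd",
    "cMin",
    "cMM1",
    "cMout",
    "cM1M2",
    "cM1M2inhib",
    "cM2out",
    "cQSCN",
    "cQSCMd",
    "cASCM2",
    "cASCpro",
    "cASCdiff",
    "cMcout",
)


class ValidationError(ValueError):
    """A state or parameter value violates the model's domain constraints."""


def _check_non_negative(obj, names: Iterable[str]) -> None:
    for name in names:
        value = getattr(obj, name)
        if not np.isfinite(value):
            raise ValidationError(f"{type(obj).__name__}.{name} must be finite, got {value!r}")
        if value < 0:
            raise ValidationError(
                f"{type(obj).__name__}.{name} must be non-negative, got {value!r}"
            )


@dataclass(frozen=True)
class CellState:
    """Densities of the nine cell populations at one instant (cells/mm^3)."""

    Md: float
    N: float
    Nd: float
    M: float
    M1: float
    M2: float
    QSC: float
    ASC: float
    Mc: float

    def __post_init__(self) -> None:
        for name in STATE_ORDER:
            object.__setattr__(self, name, float(getattr(self, name)))
        _check_non_negative(self, STATE_ORDER)

    def to_array(self) -> np.ndarray:
        """Return the state as a length-9 vector in :data:`STATE_ORDER`."""
        return np.array([getattr(self, name) for name in STATE_ORDER], dtype=float)

    @classmethod
    def from_array(cls, values: np.ndarray) -> "CellState":
        values = np.asarray(values, dtype=float)
        if values.shape != (len(STATE_ORDER),):
            raise ValidationError(f"expected {len(STATE_ORDER)} state values, got shape {values.shape}")
        return cls(**dict(zip(STATE_ORDER, values)))

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, float]) -> "CellState":
        missing = set(STATE_ORDER) - set(mapping)
        if missing:
            raise ValidationError(f"missing state variables: {sorted(missing)}")
        extra = set(mapping) - set(STATE_ORDER)
        if extra:
            raise ValidationError(f"unknown state variables: {sorted(extra)}")
        return cls(**{k: float(v) for k, v in mapping.items()})

    def to_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in STATE_ORDER}


@dataclass(frozen=True)
class RateParameters:
    """The seventeen rate constants of the regeneration model.

    Bilinear clearance/interaction constants carry units of
    1/(day * cells/mm^3); first-order influx/outflux rates are 1/day.
    ``cM1M2inhib`` is a saturation constant in cells/mm^3: the M1->M2
    transition proceeds at ``cM1M2 * M1 / (cM1M2inhib + Nd + Md)``, so the
    transition is inhibited while dead-cell debris remains.
    """

    cNMd: float
    cM1Md: float
    cNin: float
    cNout: float
    cM1Nd: float
    cMin: float
    cMM1: float
    cMout: float
    cM1M2: float
    cM1M2inhib: float
    cM2out: float
    cQSCN: float
    cQSCMd: float
    cASCM2: float
    cASCpro: float
    cASCdiff: float
    cMcout: float

    def __post_init__(self) -> None:
        for name in PARAM_ORDER:
            object.__setattr__(self, name, float(getattr(self, name)))
        _check_non_negative(self, PARAM_ORDER)

    def to_array(self) -> np.ndarray:
        """Return the parameters as a length-17 vector in :data:`PARAM_ORDER`."""
        return np.array([getattr(self, name) for name in PARAM_ORDER], dtype=float)

    @classmethod
    def from_array(cls, values: np.ndarray) -> "RateParameters":
        values = np.asarray(values, dtype=float)
        if values.shape != (len(PARAM_ORDER),):
            raise ValidationError(
                f"expected {len(PARAM_ORDER)} parameter values, got shape {values.shape}"
            )
        return cls(**dict(zip(PARAM_ORDER, values)))

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, float]) -> "RateParameters":
        missing = set(PARAM_ORDER) - set(mapping)
        if missing:
            raise ValidationError(f"missing rate constants: {sorted(missing)}")
        extra = set(mapping) - set(PARAM_ORDER)
        if extra:
            raise ValidationError(f"unknown rate constants: {sorted(extra)}")
        return cls(**{k: float(v) for k, v in mapping.items()})

    def to_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in PARAM_ORDER}

    def replace(self, **changes: float) -> "RateParameters":
        values = self.to_dict()
        values.update(changes)
        return RateParameters.from_mapping(values)


# dataclass sanity: the declared fields must match the canonical orders
assert tuple(f.name for f in fields(CellState)) == STATE_ORDER
assert tuple(f.name for f in fields(RateParameters)) == PARAM_ORDER


def read_config(path: str | Path) -> tuple[RateParameters, CellState]:
    """Read rate constants and initial densities from a YAML config file.

    The file must contain a ``parameters`` mapping (one key per rate
    constant) and an ``initial_state`` mapping (one key per state variable).
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "parameters" not in doc or "initial_state" not in doc:
        raise ValidationError(
            f"config {path} must contain 'parameters' and 'initial_state' mappings"
        )
    params = RateParameters.from_mapping(doc["parameters"])
    initial = CellState.from_mapping(doc["initial_state"])
    return params, initial


def write_config(path: str | Path, params: RateParameters, initial: CellState) -> None:
    """Write a config file readable by :func:`read_config` (round-trip safe)."""
    doc = {"parameters": params.to_dict(), "initial_state": initial.to_dict()}
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
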