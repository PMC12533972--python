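"""Calibration of cell-type proportions to absolute densities.

Annotated single-cell data yields per-replicate cell counts for the seven
observable populations, but only as proportions of an indefinite amount
of captured tissue.  Because the monocyte/macrophage lineage (M + M1 +
M2) has externally measured absolute densities at several days
post-injury (flow cytometry, Martinez et al.), each day's proportions can
be rescaled to cells/mm^3:

    S(d)   = T_{M+M1+M2}(d) / P_{M+M1+M2}(d)
    T_X(d) = S(d) * P_X(d)

where P_X(d) is the cross-replicate mean proportion of type X at day d,
and T_{M+M1+M2}(d) is the reference lineage density (linearly
interpolated at days without a reference measurement; the day-3 reference
value is reused directly for day-3.5 observations).  The cross-replicate
SD of a target is S(d) times the SD of the proportions.

Dead cells (Md, Nd) never appear in count tables; the only targets for
them are the fixed single-cell day-7 values attached for model fitting.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .presets import MARTINEZ_LINEAGE_COUNTS
from .state import OBSERVABLE_TYPES, ValidationError

LINEAGE_TYPES: tuple[str, ...] = ("M", "M1", "M2")

COUNT_COLUMNS = ("day", "replicate", "cell_type", "count")


def load_count_table(source: str | Path | pd.DataFrame) -> pd.DataFrame:
    """Load and validate a long-format count table.

    Expected columns: day, replicate, cell_type, count.  Cell types
    outside the seven observables are rejected -- discarding unmodeled
    types (fibro-adipogenic, endothelial, ...) is the caller's job.
    """
    df = source.copy() if isinstance(source, pd.DataFrame) else pd.read_csv(source)
    missing = set(COUNT_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"count table missing columns: {sorted(missing)}")
    df = df.loc[:, list(COUNT_COLUMNS)]
    unknown = set(df["cell_type"]) - set(OBSERVABLE_TYPES)
    if unknown:
        raise ValidationError(
            f"count table contains unmodeled cell types {sorted(unknown)}; "
            "discard them before loading"
        )
    if (df["count"] < 0).any():
        raise ValidationError("counts must be non-negative")
    df["day"] = df["day"].astype(float)
    df["count"] = df["count"].astype(float)
    return df


def proportions_from_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """Per-replicate proportions of the seven observable cell types.

    Returns a long frame (day, replicate, cell_type, proportion) in which
    every replicate carries all seven types (absent types get 0) and
    proportions sum to 1 per replicate.
    """
    counts = load_count_table(counts)
    wide = (
        counts.pivot_table(
            index=["day", "replicate"], columns="cell_type", values="count", aggfunc="sum"
        )
        .reindex(columns=list(OBSERVABLE_TYPES))
        .fillna(0.0)
    )
    totals = wide.sum(axis=1)
    zero = totals[totals <= 0]
    if len(zero):
        day, rep = zero.index[0]
        raise ValidationError(f"zero total cell count at day {day}, replicate {rep!r}")
    props = wide.div(totals, axis=0)
    return (
        props.reset_index()
        .melt(id_vars=["day", "replicate"], var_name="cell_type", value_name="proportion")
        .sort_values(["day", "replicate", "cell_type"], kind="stable")
        .reset_index(drop=True)
    )


@dataclass(frozen=True)
class ReferenceLineageCounts:
    """Absolute monocyte/macrophage-lineage densities at reference days.

    ``day_35_uses_day_3`` encodes the convention that a day-3 reference
    measurement is applied directly to day-3.5 observations instead of
    being interpolated.
    """

    days: tuple[float, ...] = tuple(MARTINEZ_LINEAGE_COUNTS)
    counts: tuple[float, ...] = tuple(MARTINEZ_LINEAGE_COUNTS.values())
    day_35_uses_day_3: bool = True

    def __post_init__(self) -> None:
        days = np.asarray(self.days, dtype=float)
        counts = np.asarray(self.counts, dtype=float)
        if days.size != counts.size or days.size < 2:
            raise ValidationError("reference needs >= 2 (day, count) pairs of equal length")
        if np.any(np.diff(days) <= 0):
            raise ValidationError("reference days must be strictly increasing")
        if np.any(counts <= 0):
            raise ValidationError("reference lineage densities must be positive")
        object.__setattr__(self, "days", tuple(days))
        object.__setattr__(self, "counts", tuple(counts))

    @classmethod
    def from_mapping(cls, mapping: Mapping[float, float], **kw) -> "ReferenceLineageCounts":
        days = sorted(mapping)
        return cls(days=tuple(days), counts=tuple(mapping[d] for d in days), **kw)

    @classmethod
    def from_csv(cls, path: str | Path, **kw) -> "ReferenceLineageCounts":
        df = pd.read_csv(path)
        if not {"day", "lineage_count"} <= set(df.columns):
            raise ValidationError("reference CSV needs columns (day, lineage_count)")
        df = df.sort_values("day")
        return cls(days=tuple(df["day"].astype(float)), counts=tuple(df["lineage_count"].astype(float)), **kw)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"day": self.days, "lineage_count": self.counts}).to_csv(path, index=False)

    def interpolate(self, days: Iterable[float]) -> np.ndarray:
        """Expected lineage density at each requested day.

        Exact at reference days; linear between bracketing reference
        days; day 3.5 returns the day-3 value when the convention is
        enabled.  Extrapolation outside the reference range is refused.
        """
        ref_days = np.asarray(self.days)
        ref_counts = np.asarray(self.counts)
        out = []
        for d in days:
            d = float(d)
            if self.day_35_uses_day_3 and d == 3.5 and 3.0 in ref_days:
                out.append(ref_counts[ref_days == 3.0][0])
                continue
            if d < ref_days[0] or d > ref_days[-1]:
                raise ValidationError(
                    f"day {d} outside the reference range [{ref_days[0]}, {ref_days[-1]}]; "
                    "no extrapolation"
                )
            out.append(float(np.interp(d, ref_days, ref_counts)))
        return np.array(out)


def interpolate_reference(ref: ReferenceLineageCounts, days: Sequence[float]) -> np.ndarray:
    """Functional alias for :meth:`ReferenceLineageCounts.interpolate`."""
    return ref.interpolate(days)


@dataclass(frozen=True)
class CalibratedTargets:
    """Per-day absolute density targets with cross-replicate SDs.

    ``frame`` has columns (day, cell_type, target, sd, scale_factor) for
    the observable types.  ``dead_cell_frame``, when present, holds the
    fixed single-cell day-7 targets for Md and Nd used in model fitting.
    """

    frame: pd.DataFrame
    dead_cell_frame: pd.DataFrame | None = None

    @property
    def days(self) -> np.ndarray:
        return np.sort(self.frame["day"].unique())

    @property
    def cell_types(self) -> list[str]:
        return sorted(self.frame["cell_type"].unique())

    def target(self, cell_type: str, day: float) -> float:
        sel = self.frame[(self.frame["cell_type"] == cell_type) & (self.frame["day"] == day)]
        if sel.empty:
            raise KeyError((cell_type, day))
        return float(sel["target"].iloc[0])

    def full_frame(self) -> pd.DataFrame:
        """Observable and dead-cell targets in one frame."""
        if self.dead_cell_frame is None:
            return self.frame.copy()
        return pd.concat([self.frame, self.dead_cell_frame], ignore_index=True)

    def to_csv(self, path: str | Path) -> None:
        self.full_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "CalibratedTargets":
        df = pd.read_csv(path)
        needed = {"day", "cell_type", "target", "sd"}
        if not needed <= set(df.columns):
            raise ValidationError(f"targets CSV needs columns {sorted(needed)}")
        dead = df[df["cell_type"].isin(["Md", "Nd"])]
        obs = df[~df["cell_type"].isin(["Md", "Nd"])]
        return cls(frame=obs.reset_index(drop=True), dead_cell_frame=dead.reset_index(drop=True) if len(dead) else None)


DEAD_CELL_DAY = 7.0
DEAD_CELL_TARGET = 1.0


def default_dead_cell_frame() -> pd.DataFrame:
    """Fixed day-7 targets of a single cell for Md and Nd.

    Dead cells should be virtually absent once regeneration resolves, so
    fitting pins them to one cell/mm^3 at day 7; they have no targets at
    other days.
    """
    return pd.DataFrame(
        {
            "day": [DEAD_CELL_DAY, DEAD_CELL_DAY],
            "cell_type": ["Md", "Nd"],
            "target": [DEAD_CELL_TARGET, DEAD_CELL_TARGET],
            "sd": [0.0, 0.0],
            "scale_factor": [np.nan, np.nan],
        }
    )


def calibrate(
    proportions: pd.DataFrame,
    reference: ReferenceLineageCounts | None = None,
    dead_cell_targets: bool = True,
) -> CalibratedTargets:
    """Scale cross-replicate mean proportions to absolute densities.

    ``proportions`` is the long frame from :func:`proportions_from_counts`.
    Cross-replicate means are unweighted; SDs use the sample (n-1)
    denominator, with single-replicate days getting SD 0.  Days with no
    replicates are simply absent; days whose mean lineage proportion is
    zero are an error (the scale factor is undefined there).
    """
    if reference is None:
        reference = ReferenceLineageCounts()
    needed = {"day", "cell_type", "proportion"}
    if not needed <= set(proportions.columns):
        raise ValidationError(f"proportions frame needs columns {sorted(needed)}")

    stats = (
        proportions.groupby(["day", "cell_type"])["proportion"]
        .agg(mean="mean", sd=lambda s: s.std(ddof=1) if len(s) > 1 else 0.0)
        .reset_index()
    )
    days = np.sort(stats["day"].unique())
    ref_totals = reference.interpolate(days)

    rows = []
    for day, ref_total in zip(days, ref_totals):
        sub = stats[stats["day"] == day].set_index("cell_type")
        lineage_prop = float(sub.loc[sub.index.isin(LINEAGE_TYPES), "mean"].sum())
        if lineage_prop <= 0:
            raise ValidationError(
                f"monocyte/macrophage lineage proportion is zero at day {day}; "
                "scale factor undefined"
            )
        scale = ref_total / lineage_prop
        for cell_type in OBSERVABLE_TYPES:
            if cell_type not in sub.index:
                continue
            rows.append(
                {
                    "day": day,
                    "cell_type": cell_type,
                    "target": scale * float(sub.loc[cell_type, "mean"]),
                    "sd": scale * float(sub.loc[cell_type, "sd"]),
                    "scale_factor": scale,
                }
            )
    frame = pd.DataFrame(rows)
    return CalibratedTargets(
        frame=frame, dead_cell_frame=default_dead_cell_frame() if dead_cell_targets else None
    )


class DensityCalibrator(TransformerMixin, BaseEstimator):
    """Transformer from replicate count tables to calibrated density targets.

    Parameters
    ----------
    reference
        Absolute lineage densities; defaults to the wild-type
        flow-cytometry measurements.
    dead_cell_targets
        Attach the fixed single-cell day-7 targets for Md and Nd.

    Attributes (after :meth:`fit`)
    ------------------------------
    proportions_ : per-replicate proportion frame
    scale_factors_ : per-day scale factors S(d)
    targets_ : the :class:`CalibratedTargets`
    """

    def __init__(
        self,
        reference: ReferenceLineageCounts | None = None,
        dead_cell_targets: bool = True,
    ):
        self.reference = reference
        self.dead_cell_targets = dead_cell_targets

    def fit(self, X: pd.DataFrame, y=None) -> "DensityCalibrator":
        counts = load_count_table(X)
        self.proportions_ = proportions_from_counts(counts)
        self.targets_ = calibrate(
            self.proportions_,
            reference=self.reference,
            dead_cell_targets=self.dead_cell_targets,
        )
        self.scale_factors_ = (
            self.targets_.frame.groupby("day")["scale_factor"].first().to_dict()
        )
        return self

    def transform(self, X: pd.DataFrame | None = None) -> pd.DataFrame:
        """Return the calibrated target frame (recomputed if new counts given)."""
        if X is not None:
            return DensityCalibrator(
                reference=self.reference, dead_cell_targets=self.dead_cell_targets
            ).fit(X).targets_.full_frame()
        if not hasattr(self, "targets_"):
            raise ValidationError("DensityCalibrator is not fitted")
        return self.targets_.full_frame()
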