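"""Response traces, normalization, dose x time matrices and recovery scores.

Raw per-well FMS values are normalized to the drug-free control wells
of the same plate at the same timepoint, averaged across replicate
wells per condition, and assembled into time traces or dose x time
grids from which dose-response columns and kinetic rows can be pulled.
A proportional recovery score quantifies how much of the maximal
paralysis a population regains by the end of the assay.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Condition",
    "ResponseTrace",
    "DoseTimeMatrix",
    "RecoveryScore",
    "normalize_to_controls",
    "build_dose_time_matrix",
    "proportional_recovery",
    "classify_response",
    "recovery_window",
]

#: control wells with mean FMS below this at a timepoint make that
#: timepoint unusable (division by a near-zero control is meaningless)
CONTROL_FLOOR = 0.05


@dataclass(frozen=True)
class Condition:
    """One experimental condition: a compound at a dose in a strain/stage."""

    compound: str
    dose: float
    unit: str = ""
    strain: str = ""
    stage: str = ""

    def label(self) -> str:
        parts = [self.compound, f"{self.dose:g}{self.unit}"]
        if self.strain:
            parts.append(self.strain)
        if self.stage:
            parts.append(self.stage)
        return " ".join(parts)


@dataclass
class ResponseTrace:
    """Control-normalized FMS over time for one condition.

    ``fms_norm`` may exceed 1 (wells can move more than controls) and
    holds NaN at timepoints where the control floor failed.
    """

    condition: Condition
    times: np.ndarray
    fms_norm: np.ndarray
    n_wells: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.fms_norm = np.asarray(self.fms_norm, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.fms_norm.shape:
            raise ValueError("times and fms_norm must be 1-D and equal length")
        if (np.diff(self.times) <= 0).any():
            raise ValueError("times must be strictly increasing")
        if self.n_wells is None:
            self.n_wells = np.ones_like(self.times, dtype=int)


def normalize_to_controls(
    records: pd.DataFrame,
    plate_map: pd.DataFrame,
    *,
    control_floor: float = CONTROL_FLOOR,
) -> list[ResponseTrace]:
    """Normalize drug-well FMS to same-timepoint drug-free controls.

    ``records`` is the tidy results table (columns ``well``,
    ``time_min``, ``fms``, ``valid``); ``plate_map`` assigns each well a
    compound, dose, strain, stage and control flag.  For each condition
    and timepoint the normalized value is

        mean(FMS of that condition's valid wells)
        / mean(FMS of valid control wells)

    Timepoints where the control mean falls below ``control_floor`` are
    marked NaN with a warning.  A plate without any control wells is an
    error.
    """
    plate_map = plate_map.copy()
    if not plate_map["is_control"].any():
        raise ValueError("plate has no drug-free control wells")

    # results CSVs already carry the annotation columns; the plate map is
    # authoritative, so merge only the measurements
    measurements = records[["well", "time_min", "fms", "valid"]]
    merged = measurements.merge(plate_map, on="well", how="left", validate="m:1")
    if merged["is_control"].isna().any():
        missing = sorted(merged.loc[merged["is_control"].isna(), "well"].unique())
        raise ValueError(f"records reference wells absent from plate map: {missing}")
    valid = merged[merged["valid"].astype(bool)]

    ctrl = (
        valid[valid["is_control"].astype(bool)]
        .groupby("time_min")["fms"]
        .mean()
        .sort_index()
    )
    low = ctrl[ctrl < control_floor]
    for t in low.index:
        warnings.warn(
            f"control FMS {ctrl[t]:.3f} below floor {control_floor} at "
            f"t={t:g} min; timepoint marked missing"
        )
    ctrl = ctrl.where(ctrl >= control_floor)

    traces = []
    drug = valid
    keys = ["compound", "dose", "unit", "strain", "stage", "is_control"]
    for cond_key, grp in drug.groupby(keys, dropna=False):
        compound, dose, unit, strain, stage, _ = cond_key
        by_t = grp.groupby("time_min")["fms"].agg(["mean", "count"]).sort_index()
        times = by_t.index.to_numpy(dtype=float)
        norm = by_t["mean"].to_numpy() / ctrl.reindex(by_t.index).to_numpy()
        traces.append(
            ResponseTrace(
                condition=Condition(
                    compound=str(compound),
                    dose=float(dose),
                    unit=str(unit),
                    strain=str(strain),
                    stage=str(stage),
                ),
                times=times,
                fms_norm=norm,
                n_wells=by_t["count"].to_numpy(dtype=int),
            )
        )
    return traces


@dataclass
class DoseTimeMatrix:
    """Normalized FMS on a dose x time grid (doses are rows).

    Row extraction gives the kinetic response to one dose; column
    extraction gives the dose-response curve at one timepoint.
    """

    doses: np.ndarray
    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.doses = np.asarray(self.doses, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.doses.size, self.times.size):
            raise ValueError("values must be shaped (n_doses, n_times)")
        if (np.diff(self.doses) <= 0).any():
            raise ValueError("doses must be strictly increasing")

    def kinetic_trace(self, dose: float) -> np.ndarray:
        """Row: FMS over time at a fixed dose."""
        idx = int(np.flatnonzero(np.isclose(self.doses, dose))[0])
        return self.values[idx, :]

    def dose_response(self, time_min: float) -> np.ndarray:
        """Column: FMS across doses at a fixed timepoint."""
        idx = int(np.flatnonzero(np.isclose(self.times, time_min))[0])
        return self.values[:, idx]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.doses, columns=self.times)


def build_dose_time_matrix(traces: list[ResponseTrace]) -> DoseTimeMatrix:
    """Assemble one compound's traces (one per dose) into a grid."""
    if not traces:
        raise ValueError("no traces given")
    ids = {(t.condition.compound, t.condition.strain, t.condition.stage) for t in traces}
    if len(ids) > 1:
        raise ValueError(f"traces mix conditions: {sorted(ids)}")
    doses = [t.condition.dose for t in traces]
    if len(set(doses)) != len(doses):
        raise ValueError("duplicate dose among traces")
    order = np.argsort(doses)
    traces = [traces[i] for i in order]
    times = traces[0].times
    for t in traces[1:]:
        if not np.array_equal(t.times, times):
            raise ValueError("traces have unequal time grids")
    values = np.vstack([t.fms_norm for t in traces])
    return DoseTimeMatrix(doses=np.asarray(doses)[order], times=times, values=values)


@dataclass
class RecoveryScore:
    """Proportional recovery from maximal paralysis.

    score = (FMS_after_recovery - FMS_min) / (1 - FMS_min), where
    FMS_after_recovery is the mean over the recovery window (final 30
    minutes by default) and FMS_min the minimum over the whole assay.
    Undefined when the trace never paralyses (minimum ~ 1).
    """

    score: float
    fms_max_paralysis: float
    fms_after_recovery: float
    defined: bool


def recovery_window(total_min: float) -> tuple[float, float]:
    """Default recovery window: (150, 180) for the standard 3-hr assay,
    otherwise the final 30 minutes."""
    if np.isclose(total_min, 180.0):
        return (150.0, 180.0)
    return (total_min - 30.0, total_min)


def proportional_recovery(
    trace: ResponseTrace,
    window: tuple[float, float] | None = None,
    *,
    epsilon: float = 0.05,
) -> RecoveryScore:
    """Score recovery from maximal paralysis for one trace.

    The minimum is taken over the full assay, the post-recovery level is
    the mean over ``window`` (inclusive).  Traces whose minimum never
    drops below ``1 - epsilon`` show no paralysis, so the score is
    undefined rather than a 0/0 artifact.
    """
    finite = np.isfinite(trace.fms_norm)
    times = trace.times[finite]
    vals = trace.fms_norm[finite]
    if times.size == 0:
        raise ValueError("trace has no finite values")
    if window is None:
        window = recovery_window(times[-1])
    lo, hi = window
    if times[-1] < hi or times[0] > lo:
        raise ValueError(
            f"trace spans [{times[0]:g}, {times[-1]:g}] min but the recovery "
            f"window needs [{lo:g}, {hi:g}]"
        )
    in_win = (times >= lo) & (times <= hi)
    if not in_win.any():
        raise ValueError("no timepoints inside the recovery window")
    fms_min = float(vals.min())
    fms_after = float(vals[in_win].mean())
    if fms_min >= 1.0 - epsilon:
        return RecoveryScore(
            score=float("nan"),
            fms_max_paralysis=fms_min,
            fms_after_recovery=fms_after,
            defined=False,
        )
    score = (fms_after - fms_min) / (1.0 - fms_min)
    return RecoveryScore(
        score=score,
        fms_max_paralysis=fms_min,
        fms_after_recovery=fms_after,
        defined=True,
    )


def classify_response(
    trace: ResponseTrace,
    *,
    no_effect_min: float = 0.8,
    sustained_paralysis_score: float = 0.2,
    sustained_recovery_gap: float = 0.1,
    window: tuple[float, float] | None = None,
) -> str:
    """Label a trace's time-course archetype.

    Returns one of ``no_effect`` (minimum stays above ``no_effect_min``),
    ``sustained_paralysis`` (recovery score below
    ``sustained_paralysis_score``), ``sustained_recovery`` (final-window
    mean within ``sustained_recovery_gap`` of the post-paralysis
    maximum) or ``transient_recovery``.  The thresholds operationalize
    the qualitative notion of multi-phase ("complex") responses and are
    deliberately configurable.
    """
    finite = np.isfinite(trace.fms_norm)
    times = trace.times[finite]
    vals = trace.fms_norm[finite]
    if float(vals.min()) > no_effect_min:
        return "no_effect"
    rec = proportional_recovery(trace, window=window)
    if not rec.defined or rec.score < sustained_paralysis_score:
        return "sustained_paralysis"
    i_min = int(np.argmin(vals))
    post_max = float(vals[i_min:].max())
    if rec.fms_after_recovery >= post_max - sustained_recovery_gap:
        return "sustained_recovery"
    return "transient_recovery"
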