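"""End-to-end plate workflows: quantify -> normalize -> fit -> recovery.

These functions are what the command-line interface wraps; they operate
on the tidy tables defined in :mod:`wellmotion.plate_io` so results can
be written out and re-read at any stage.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .dose_response import DoseResponseModel, select_model
from .plate_io import PlateImageSet, PlateMap, read_frame_pair
from .response import (
    build_dose_time_matrix,
    classify_response,
    normalize_to_controls,
    proportional_recovery,
)
from .segmentation import MobilityRecord, SegmentationParams, quantify_well

logger = logging.getLogger("wellmotion")

__all__ = ["quantify_plate", "fit_plate", "recovery_table", "condition_traces"]


def quantify_plate(
    image_set: PlateImageSet,
    params: SegmentationParams | None = None,
) -> list[MobilityRecord]:
    """Run the FMS pipeline over every frame pair of a plate."""
    params = params or SegmentationParams()
    records = []
    n_invalid = 0
    for (well, t_idx) in sorted(image_set.frame_pairs):
        f1, f2 = read_frame_pair(image_set, well, t_idx)
        rec = quantify_well(f1, f2, params)
        rec.well_id = well
        rec.timepoint_min = t_idx * image_set.cadence_min
        records.append(rec)
        n_invalid += not rec.valid
    logger.info(
        "quantified %d well-timepoints (%d valid, %d invalid)",
        len(records), len(records) - n_invalid, n_invalid,
    )
    return records


def condition_traces(results: pd.DataFrame, plate_map: PlateMap):
    """Normalized traces for the non-control conditions of a plate."""
    traces = normalize_to_controls(results, plate_map.table)
    return [t for t in traces if not _is_control_trace(t, plate_map)]


def _is_control_trace(trace, plate_map: PlateMap) -> bool:
    ctrl = plate_map.table[plate_map.table["is_control"]]
    return ((ctrl["compound"] == trace.condition.compound)
            & (ctrl["dose"] == trace.condition.dose)).any()


def fit_plate(
    results: pd.DataFrame,
    plate_map: PlateMap,
    *,
    times: list[float] | None = None,
    model: str = "auto",
) -> pd.DataFrame:
    """Fit a dose-response curve per compound per timepoint.

    Returns a table with one row per (compound, strain, stage, time):
    family used, parameter estimates, rss and EC50 (NaN for the
    exponential family).  Timepoints with too few distinct doses are
    flagged rather than fatal.
    """
    traces = condition_traces(results, plate_map)
    rows = []
    by_cond: dict[tuple, list] = {}
    for t in traces:
        key = (t.condition.compound, t.condition.strain, t.condition.stage)
        by_cond.setdefault(key, []).append(t)
    for (compound, strain, stage), cond_traces_ in sorted(by_cond.items()):
        try:
            matrix = build_dose_time_matrix(cond_traces_)
        except ValueError as e:
            logger.warning("cannot grid %s: %s", compound, e)
            continue
        use_times = times if times is not None else matrix.times
        for t_min in use_times:
            y = matrix.dose_response(t_min)
            ok = np.isfinite(y)
            x = matrix.doses[ok]
            yv = y[ok]
            row = {
                "compound": compound, "strain": strain, "stage": stage,
                "time_min": t_min, "model": "", "A": np.nan, "B": np.nan,
                "M": np.nan, "rss": np.nan, "ec50": np.nan, "converged": False,
                "note": "",
            }
            family = select_model(x, yv, None if model == "auto" else model)
            min_needed = 4 if family == "logistic3" else 3
            if np.unique(x).size < min_needed:
                row["note"] = f"insufficient doses for {family}"
                rows.append(row)
                continue
            res = DoseResponseModel(x, yv, model=family).fit()
            row.update(model=res.family, rss=res.rss, converged=res.converged,
                       **res.params)
            if res.family == "logistic3" and res.converged:
                row["ec50"] = res.ec50
            rows.append(row)
        logger.info("fitted %s: %d timepoints", compound, len(use_times))
    return pd.DataFrame(rows)


def recovery_table(
    results: pd.DataFrame,
    plate_map: PlateMap,
    *,
    window: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Proportional recovery score and response class per condition."""
    traces = condition_traces(results, plate_map)
    rows = []
    for t in sorted(traces, key=lambda t: (t.condition.compound, t.condition.dose)):
        rec = proportional_recovery(t, window=window)
        label = classify_response(t, window=window)
        rows.append(
            {
                "compound": t.condition.compound,
                "dose": t.condition.dose,
                "unit": t.condition.unit,
                "strain": t.condition.strain,
                "stage": t.condition.stage,
                "score": rec.score,
                "fms_max_paralysis": rec.fms_max_paralysis,
                "fms_after_recovery": rec.fms_after_recovery,
                "defined": rec.defined,
                "response_class": label,
            }
        )
    return pd.DataFrame(rows)
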