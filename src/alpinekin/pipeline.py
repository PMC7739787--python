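"""End-to-end run analysis: filter, segment, trim, summarize."""

from __future__ import annotations

from typing import List, Optional, Tuple

import pandas as pd

from .filtering import FilterSpec, apply_filter
from .io import RunRecord
from .phases import DEFAULT_THRESHOLD, angular_velocity, summarize_run
from .segmentation import (
    CycleSegment,
    detect_turn_switches,
    resultant_acceleration,
    segment_cycles,
    trim_cycles,
)


def analyze_run(
    run: RunRecord,
    run_id: str = "run0",
    threshold: float = DEFAULT_THRESHOLD,
    cutoff: float = 1.0,
    order: int = 4,
    min_separation: float | str = "auto",
    min_prominence: float = 0.05,
) -> Tuple[List[CycleSegment], pd.DataFrame]:
    """Full per-run analysis; returns the segments and the metrics table.

    Angle channels are low-pass filtered zero-phase before differentiation;
    turn switches come from the filtered resultant acceleration.  Only
    retained (non-excluded) half-cycles produce metrics rows.
    """
    spec = FilterSpec(order=order, cutoff=cutoff, fs=run.fs)
    knee_f = apply_filter(run.knee, spec)
    hip_f = apply_filter(run.hip, spec) if run.hip is not None else None

    accr = resultant_acceleration(run.acc_x, run.acc_y, run.acc_z)
    switches = detect_turn_switches(
        accr, spec=spec, min_separation=min_separation, min_prominence=min_prominence
    )

    filtered_run = RunRecord(
        knee=knee_f,
        hip=hip_f,
        acc_x=run.acc_x,
        acc_y=run.acc_y,
        acc_z=run.acc_z,
        skier_id=run.skier_id,
        session_id=run.session_id,
        discipline=run.discipline,
        figure_spans=run.figure_spans,
    )
    segments = segment_cycles(filtered_run, switches)
    trim_cycles(segments, filtered_run)

    knee_vel = angular_velocity(knee_f)
    hip_vel = angular_velocity(hip_f) if hip_f is not None else None
    metrics = summarize_run(
        segments,
        knee_velocity=knee_vel,
        hip_angle=hip_f,
        hip_velocity=hip_vel,
        threshold=threshold,
        run_id=run_id,
        skier_session_id=run.session_id,
        discipline=run.discipline,
    )
    return segments, metrics


def pooled_samples(
    run: RunRecord,
    segments: List[CycleSegment],
    cutoff: float = 1.0,
    order: int = 4,
):
    """(angle, velocity) sample pairs pooled over retained segments per leg.

    Returns a dict leg -> (angles, velocities) for density grids.
    """
    import numpy as np

    spec = FilterSpec(order=order, cutoff=cutoff, fs=run.fs)
    knee_f = apply_filter(run.knee, spec)
    vel = angular_velocity(knee_f)
    out = {}
    for leg in ("IL", "OL"):
        angs, vels = [], []
        for seg in segments:
            if seg.excluded or seg.leg != leg:
                continue
            angs.append(knee_f.values[seg.start_idx:seg.end_idx])
            vels.append(vel.values[seg.start_idx:seg.end_idx])
        if angs:
            out[leg] = (np.concatenate(angs), np.concatenate(vels))
    return out
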