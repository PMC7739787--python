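"""Angular velocity and per-cycle contraction-mode metrics.

Two partitions of each half-cycle are computed:

* tripartite — eccentric (velocity < -20 deg/s), quasi-isometric (closed
  window [-20, +20] deg/s), concentric (> +20 deg/s); the window boundary
  itself is quasi-isometric;
* bipartite — the legacy extrema scheme: samples from the segment's global
  maximum angle to its global minimum are flexion (eccentric), from minimum
  to maximum extension (concentric), with no isometric class.

Velocities are reported as magnitudes; the mode name carries the sign
semantics (eccentric = flexion, concentric = extension of the joint).
"""

from __future__ import annotations

from typing import Dict, Optional

import numpy as np
import pandas as pd

from .io import TimeSeries
from .segmentation import CycleSegment

DEFAULT_THRESHOLD = 20.0  # deg/s

TRI_MODES = ("ECC", "ISO", "CON")
BI_MODES = ("ECC", "CON")


def angular_velocity(angle: TimeSeries) -> TimeSeries:
    """First derivative of a joint angle, deg/s; extension positive.

    Central differences in the interior (2nd-order accurate, zero phase),
    one-sided differences at the endpoints.
    """
    if len(angle) < 3:
        raise ValueError("need at least 3 samples to differentiate")
    omega = np.gradient(angle.values) * angle.fs
    return TimeSeries(omega, angle.fs, "deg/s", angle.t0)


def classify_tripartite(omega, threshold: float = DEFAULT_THRESHOLD) -> np.ndarray:
    """Per-sample ECC / ISO / CON labels from signed angular velocity."""
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    values = omega.values if isinstance(omega, TimeSeries) else np.asarray(omega, float)
    labels = np.full(values.shape, "ISO", dtype="<U3")
    labels[values < -threshold] = "ECC"
    labels[values > threshold] = "CON"
    return labels


def classify_bipartite(angle) -> tuple[np.ndarray, bool]:
    """Per-sample ECC / CON labels from the segment's angle extrema.

    Labels wrap within the segment so that every sample is covered.  A
    constant segment has no extrema: all samples are labeled CON and the
    degenerate flag is returned True.
    """
    values = angle.values if isinstance(angle, TimeSeries) else np.asarray(angle, float)
    n = values.size
    if n == 0:
        raise ValueError("empty segment")
    labels = np.full(n, "CON", dtype="<U3")
    if np.ptp(values) == 0:
        return labels, True
    imax = int(np.argmax(values))
    imin = int(np.argmin(values))
    if imax < imin:
        labels[imax:imin] = "ECC"
    else:
        labels[imax:] = "ECC"
        labels[:imin] = "ECC"
    return labels, False


def _mode_metrics(labels: np.ndarray, omega: np.ndarray, modes, fs: float,
                  prefix: str, out: Dict[str, float]) -> None:
    n = labels.size
    speed = np.abs(omega)
    for mode in modes:
        m = labels == mode
        count = int(m.sum())
        out[f"{prefix}_{mode.lower()}_abs_ms"] = 1000.0 * count / fs
        out[f"{prefix}_{mode.lower()}_rel_pct"] = 100.0 * count / n
        if count:
            out[f"{prefix}_{mode.lower()}_mean_vel"] = float(speed[m].mean())
            out[f"{prefix}_{mode.lower()}_max_vel"] = float(speed[m].max())
        else:
            out[f"{prefix}_{mode.lower()}_mean_vel"] = np.nan
            out[f"{prefix}_{mode.lower()}_max_vel"] = np.nan


def summarize_cycle(
    segment: CycleSegment,
    omega: np.ndarray,
    threshold: float = DEFAULT_THRESHOLD,
    joint: str = "knee",
    angle: Optional[np.ndarray] = None,
) -> Dict[str, float]:
    """Per-cycle metrics for one joint of one retained half-cycle.

    ``omega`` is the signed angular velocity over the segment's samples
    (deg/s); ``angle`` defaults to the segment's knee trace.  Tripartite
    dynamic-mode means exclude quasi-isometric samples by construction;
    bipartite means cover every sample of each phase.
    """
    if segment.excluded:
        raise ValueError(f"segment excluded ({segment.reason}); no metrics computed")
    if angle is None:
        angle = segment.angle
    angle = np.asarray(angle, dtype=float)
    omega = np.asarray(omega, dtype=float)
    if angle.size != segment.n_samples or omega.size != segment.n_samples:
        raise ValueError("angle/velocity length must match the segment span")

    out: Dict[str, float] = {
        "leg": segment.leg,
        "cycle_number": segment.cycle_number,
        "joint": joint,
        "min_angle": float(np.min(angle)),
        "max_angle": float(np.max(angle)),
        "turn_duration_ms": segment.duration_ms,
    }
    tri = classify_tripartite(omega, threshold)
    _mode_metrics(tri, omega, TRI_MODES, segment.fs, "tri", out)
    bi, degenerate = classify_bipartite(angle)
    _mode_metrics(bi, omega, BI_MODES, segment.fs, "bi", out)
    out["bi_degenerate"] = degenerate
    return out


def summarize_run(
    segments,
    knee_velocity: TimeSeries,
    hip_angle: Optional[TimeSeries] = None,
    hip_velocity: Optional[TimeSeries] = None,
    threshold: float = DEFAULT_THRESHOLD,
    run_id: str = "run0",
    skier_session_id: str = "",
    discipline: str = "",
) -> pd.DataFrame:
    """Metrics table: one row per retained (half-cycle, joint).

    Velocities are sliced from full-run derivatives so that the central
    differences at segment borders use true neighboring samples.
    """
    rows = []
    for seg in segments:
        if seg.excluded:
            continue
        omega = knee_velocity.values[seg.start_idx:seg.end_idx]
        row = summarize_cycle(seg, omega, threshold, joint="knee")
        rows.append(row)
        if hip_angle is not None and hip_velocity is not None:
            omega_h = hip_velocity.values[seg.start_idx:seg.end_idx]
            angle_h = hip_angle.values[seg.start_idx:seg.end_idx]
            rows.append(summarize_cycle(seg, omega_h, threshold, joint="hip", angle=angle_h))
    df = pd.DataFrame(rows)
    if not df.empty:
        df.insert(0, "run_id", run_id)
        df.insert(1, "ID", skier_session_id)
        df.insert(2, "discipline", discipline)
    return df
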