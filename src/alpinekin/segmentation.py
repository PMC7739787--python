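"""Turn-switch detection, half-cycle segmentation, trimming, time-normalization.

Turn switches are local minima of the low-pass filtered resultant trunk
acceleration (negative-to-positive sign change of the first derivative),
gated by a minimum prominence and a minimum separation.  Consecutive
switches bound IL/OL half-cycles; leg roles are assigned from the knee angle
(the outside leg is the more extended one), with the IL/OL alternation phase
decided once per run by majority vote.  The first and last full cycle, any
segment overlapping an annotated figure, and segments containing missing
samples are excluded before analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
from scipy.signal import find_peaks

from .filtering import FilterSpec, apply_filter
from .io import RunRecord, TimeSeries


@dataclass
class CycleSegment:
    """One IL or OL half-cycle (half-open sample span)."""

    start_idx: int
    end_idx: int
    leg: str  # IL or OL
    cycle_number: int
    fs: float
    angle: np.ndarray  # deg, knee
    hip_angle: Optional[np.ndarray] = None
    excluded: bool = False
    reason: Optional[str] = None  # first_last / figure / missing_data
    low_confidence: bool = False

    def __post_init__(self) -> None:
        if self.end_idx <= self.start_idx:
            raise ValueError("segment span must be non-empty")
        if self.leg not in ("IL", "OL"):
            raise ValueError(f"leg must be IL or OL, got {self.leg!r}")

    @property
    def n_samples(self) -> int:
        return self.end_idx - self.start_idx

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    @property
    def duration_ms(self) -> float:
        return 1000.0 * self.duration_s

    @property
    def start_s(self) -> float:
        return self.start_idx / self.fs

    @property
    def end_s(self) -> float:
        return self.end_idx / self.fs


def resultant_acceleration(x: TimeSeries, y: TimeSeries, z: TimeSeries) -> TimeSeries:
    """Per-sample Euclidean norm of the three acceleration axes (in g)."""
    if not (len(x) == len(y) == len(z)):
        raise ValueError("acceleration channels must have equal length")
    if not (np.isclose(x.fs, y.fs) and np.isclose(x.fs, z.fs)):
        raise ValueError("acceleration channels must share the sample rate")
    values = np.sqrt(x.values**2 + y.values**2 + z.values**2)
    return TimeSeries(values, x.fs, "g", x.t0)


def detect_turn_switches(
    accr: TimeSeries,
    spec: FilterSpec | None = None,
    min_separation: float | str = "auto",
    min_prominence: float = 0.05,
) -> np.ndarray:
    """Sample indices of turn switches (minima of filtered resultant acc.).

    ``min_separation="auto"`` runs a bootstrap: detect with a 0.3 s floor,
    re-estimate the median switch spacing, then re-detect requiring 0.4x that
    spacing.  When two minima fall closer than the separation the deeper one
    is kept.
    """
    if spec is None:
        spec = FilterSpec(fs=accr.fs)
    filtered = apply_filter(accr, spec).values

    def _find(sep_s: float) -> np.ndarray:
        distance = max(1, int(round(sep_s * accr.fs)))
        idx, _ = find_peaks(-filtered, prominence=min_prominence, distance=distance)
        return idx

    if min_separation == "auto":
        idx = _find(0.3)
        if len(idx) >= 3:
            median_spacing = float(np.median(np.diff(idx))) / accr.fs
            idx = _find(0.4 * median_spacing)
    else:
        idx = _find(float(min_separation))
    if len(idx) == 0:
        raise ValueError("no acceleration minima found; cannot segment run")
    return idx


def assign_legs(mean_angles: Sequence[float]) -> tuple[List[str], bool]:
    """IL/OL labels for consecutive half-cycles from their mean knee angles.

    A segment votes OL when its mean angle exceeds the run median of segment
    means; a single global alternation phase is then chosen by majority vote
    (no per-segment flips).  Returns ``(labels, low_confidence)`` where
    low_confidence marks an exact tie broken as first = OL.
    """
    means = np.asarray(mean_angles, dtype=float)
    if means.size == 0:
        raise ValueError("no segments")
    votes_ol = means > np.median(means)
    even_ol = np.array([i % 2 == 0 for i in range(means.size)])
    agree_even = int(np.sum(votes_ol == even_ol))
    agree_odd = means.size - agree_even
    low_confidence = agree_even == agree_odd
    first_is_ol = agree_even >= agree_odd
    labels = [
        ("OL" if (i % 2 == 0) == first_is_ol else "IL") for i in range(means.size)
    ]
    return labels, low_confidence


def assign_leg(angle: np.ndarray, run_median_mean: float) -> str:
    """Leg role of a single segment relative to the run's median mean angle."""
    angle = np.asarray(angle, dtype=float)
    if angle.size == 0:
        raise ValueError("empty segment")
    return "OL" if np.nanmean(angle) > run_median_mean else "IL"


def segment_cycles(run: RunRecord, switches: Sequence[int]) -> List[CycleSegment]:
    """Cut a run into half-cycles between consecutive switch indices."""
    switches = np.asarray(switches, dtype=int)
    if len(switches) < 3:
        raise ValueError("need at least 3 switches to form cycles")
    knee = run.knee.values
    hip = run.hip.values if run.hip is not None else None
    spans = [(int(switches[i]), int(switches[i + 1])) for i in range(len(switches) - 1)]
    means = [np.nanmean(knee[s:e]) for s, e in spans]
    labels, low_conf = assign_legs(means)
    segments = []
    for i, ((s, e), leg) in enumerate(zip(spans, labels)):
        segments.append(
            CycleSegment(
                start_idx=s,
                end_idx=e,
                leg=leg,
                cycle_number=i // 2,
                fs=run.fs,
                angle=knee[s:e].copy(),
                hip_angle=hip[s:e].copy() if hip is not None else None,
                low_confidence=low_conf,
            )
        )
    return segments


def trim_cycles(segments: List[CycleSegment], run: RunRecord) -> List[CycleSegment]:
    """Mark exclusions: first/last full cycle, figure overlaps, missing data.

    Operates in place on the segment list and returns it.
    """
    n = len(segments)
    for i, seg in enumerate(segments):
        if i < 2 or i >= n - 2:
            seg.excluded, seg.reason = True, "first_last"
    for seg in segments:
        if seg.excluded:
            continue
        for span in run.figure_spans:
            f0, f1 = float(span[0]), float(span[1])
            if seg.start_s < f1 and seg.end_s > f0:
                seg.excluded, seg.reason = True, "figure"
                break
    for seg in segments:
        if seg.excluded:
            continue
        bad = np.any(~np.isfinite(seg.angle))
        if seg.hip_angle is not None:
            bad = bad or np.any(~np.isfinite(seg.hip_angle))
        if bad:
            seg.excluded, seg.reason = True, "missing_data"
    return segments


def retained(segments: Sequence[CycleSegment]) -> List[CycleSegment]:
    return [s for s in segments if not s.excluded]


def time_normalize(segment, n_points: int = 101) -> np.ndarray:
    """Linearly resample a segment's angle onto 0-100% of the half-cycle.

    Accepts a :class:`CycleSegment` or a plain array; endpoints are preserved
    exactly.
    """
    angle = segment.angle if isinstance(segment, CycleSegment) else np.asarray(segment, float)
    if angle.size < 4:
        raise ValueError("segment too short to time-normalize")
    x = np.linspace(0.0, 1.0, angle.size)
    xi = np.linspace(0.0, 1.0, n_points)
    return np.interp(xi, x, angle)
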