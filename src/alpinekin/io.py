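"""Run input/output and goniometer calibration.

A run is stored as a plain CSV (columns ``time_s,knee,hip,acc_x,acc_y,acc_z``,
the ``hip`` column optional) plus a sidecar JSON file with metadata
(``skier_id``, ``session_id``, ``discipline``, ``figure_spans``).  Missing
samples are encoded as empty cells and read back as NaN — never as zero.

Goniometers report raw electrical units; the three-posture calibration
(standing / seated / crouched, reference angles from video) yields an affine
raw-to-degrees map.  Angles are degrees of joint extension: larger values
mean a more extended joint (full knee extension ~180 deg).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

DISCIPLINES = ("SL", "GS", "SG", "DH")

#: float format used for run CSVs; 17 significant digits round-trips IEEE
#: doubles exactly.
_FLOAT_FMT = "%.17g"


@dataclass
class TimeSeries:
    """Uniformly sampled scalar channel."""

    values: np.ndarray
    fs: float
    units: str = "raw"  # one of deg, deg/s, g, raw
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("TimeSeries values must be 1-D")
        if not np.isfinite(self.fs) or self.fs <= 0:
            raise ValueError(f"sample rate must be positive, got {self.fs}")
        if self.units not in ("deg", "deg/s", "g", "raw"):
            raise ValueError(f"unknown units {self.units!r}")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def t(self) -> np.ndarray:
        """Sample times in seconds."""
        return self.t0 + np.arange(len(self.values)) / self.fs

    @property
    def duration(self) -> float:
        return (len(self.values) - 1) / self.fs

    def copy(self) -> "TimeSeries":
        return TimeSeries(self.values.copy(), self.fs, self.units, self.t0)


@dataclass
class RunRecord:
    """All channels of one ski run plus its metadata."""

    knee: TimeSeries
    acc_x: TimeSeries
    acc_y: TimeSeries
    acc_z: TimeSeries
    skier_id: str
    session_id: str
    discipline: str
    hip: Optional[TimeSeries] = None
    figure_spans: list = field(default_factory=list)  # (start_s, end_s, label)

    def __post_init__(self) -> None:
        if self.discipline not in DISCIPLINES:
            raise ValueError(
                f"unknown discipline {self.discipline!r}; expected one of {DISCIPLINES}"
            )
        chans = [self.knee, self.acc_x, self.acc_y, self.acc_z]
        if self.hip is not None:
            chans.append(self.hip)
        n = len(chans[0])
        fs = chans[0].fs
        for c in chans:
            if len(c) != n or not np.isclose(c.fs, fs):
                raise ValueError("all channels must share length and sample rate")

    @property
    def fs(self) -> float:
        return self.knee.fs

    @property
    def n_samples(self) -> int:
        return len(self.knee)


@dataclass
class CalibrationModel:
    """Affine raw-to-degrees map for one goniometer."""

    gain: float  # deg per raw unit
    offset: float  # deg
    residual_rmse: float  # deg

    def __post_init__(self) -> None:
        if self.gain == 0:
            raise ValueError("calibration gain must be nonzero")
        if self.residual_rmse < 0:
            raise ValueError("residual RMSE must be non-negative")


def fit_calibration(
    raw_values: Sequence[float], reference_angles_deg: Sequence[float]
) -> CalibrationModel:
    """Least-squares affine fit of reference angles against raw output.

    Posture order does not matter.  Raises on degenerate input (all raw
    values equal).
    """
    raw = np.asarray(raw_values, dtype=float)
    ref = np.asarray(reference_angles_deg, dtype=float)
    if raw.shape != ref.shape or raw.size < 2:
        raise ValueError("need at least two matched (raw, reference) pairs")
    if np.ptp(raw) == 0:
        raise ValueError("degenerate calibration: all raw values identical")
    gain, offset = np.polyfit(raw, ref, 1)
    resid = ref - (gain * raw + offset)
    return CalibrationModel(
        gain=float(gain),
        offset=float(offset),
        residual_rmse=float(np.sqrt(np.mean(resid**2))),
    )


def apply_calibration(ts: TimeSeries, cal: CalibrationModel) -> TimeSeries:
    """Map a raw-unit channel to degrees."""
    if ts.units != "raw":
        raise ValueError(f"expected raw units, got {ts.units!r}")
    return TimeSeries(cal.gain * ts.values + cal.offset, ts.fs, "deg", ts.t0)


def _metadata_path(path: Path) -> Path:
    return path.with_suffix(".meta.json")


def write_run(run: RunRecord, path: str | Path, metadata_path=None) -> None:
    """Write a run CSV and its sidecar metadata JSON."""
    path = Path(path)
    cols = {"time_s": run.knee.t, "knee": run.knee.values}
    if run.hip is not None:
        cols["hip"] = run.hip.values
    cols["acc_x"] = run.acc_x.values
    cols["acc_y"] = run.acc_y.values
    cols["acc_z"] = run.acc_z.values
    df = pd.DataFrame(cols)
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)
    meta = {
        "skier_id": run.skier_id,
        "session_id": run.session_id,
        "discipline": run.discipline,
        "figure_spans": [list(s) for s in run.figure_spans],
        "units": {"knee": run.knee.units, "acc": run.acc_x.units},
    }
    mpath = Path(metadata_path) if metadata_path else _metadata_path(path)
    mpath.write_text(json.dumps(meta, indent=1))


def read_run(path: str | Path, metadata=None) -> RunRecord:
    """Read a run CSV (+ metadata dict or sidecar JSON path) into a RunRecord.

    The sample rate is inferred from the time column, which must be strictly
    increasing and uniform within 1% of the median interval.
    """
    path = Path(path)
    if metadata is None:
        metadata = _metadata_path(path)
    if isinstance(metadata, (str, Path)):
        metadata = json.loads(Path(metadata).read_text())

    df = pd.read_csv(path, float_precision="round_trip")
    required = {"time_s", "knee", "acc_x", "acc_y", "acc_z"}
    if not required.issubset(df.columns):
        raise ValueError(f"run CSV must contain columns {sorted(required)}")

    t = df["time_s"].to_numpy(dtype=float)
    if len(t) < 2:
        raise ValueError("run must contain at least two samples")
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise ValueError("time column must be strictly increasing")
    med = float(np.median(dt))
    if np.max(np.abs(dt - med)) > 0.01 * med:
        raise ValueError("non-uniform sampling: time gaps exceed 1% of the median interval")
    fs = 1.0 / med
    t0 = float(t[0])

    units = metadata.get("units", {})
    angle_units = units.get("knee", "deg")
    acc_units = units.get("acc", "g")

    def chan(name: str, u: str) -> TimeSeries:
        return TimeSeries(df[name].to_numpy(dtype=float), fs, u, t0)

    hip = chan("hip", angle_units) if "hip" in df.columns else None
    return RunRecord(
        knee=chan("knee", angle_units),
        acc_x=chan("acc_x", acc_units),
        acc_y=chan("acc_y", acc_units),
        acc_z=chan("acc_z", acc_units),
        hip=hip,
        skier_id=str(metadata["skier_id"]),
        session_id=str(metadata["session_id"]),
        discipline=str(metadata["discipline"]),
        figure_spans=[tuple(s) for s in metadata.get("figure_spans", [])],
    )


def write_metrics(metrics: pd.DataFrame, path: str | Path) -> None:
    metrics.to_csv(path, index=False)


def read_metrics(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
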