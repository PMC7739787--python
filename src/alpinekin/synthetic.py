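"""Synthetic ski-run generator with exported ground truth.

Each half-cycle (one inside-leg or outside-leg phase) is a smooth keyframe
waveform: the knee starts at the switch angle, moves monotonically to the
leg's extremum, holds a quasi-isometric plateau for a controllable fraction
of the half-cycle, and returns to the switch angle.  Transitions use a
trapezoidal velocity profile (monotone piecewise-quadratic position) so the
realized quasi-isometric fraction tracks the design value closely.  On top
of the clean waveform the generator adds band-limited vibration noise
(>= 2 Hz) to the angle channels and Gaussian noise to the acceleration
channels, whose clean resultant has a strict local minimum exactly at every
turn switch.

Randomness is driven by one integer seed via ``numpy.random.default_rng``;
the draw order is: (1) half-cycle durations, (2) knee vibration noise,
(3) hip vibration noise, (4) acc_x, (5) acc_y, (6) acc_z noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Tuple

import numpy as np
from scipy import signal

from .io import RunRecord, TimeSeries

#: fraction of each transition spent ramping velocity up/down; small values
#: keep the sub-threshold shoulder around each plateau short.
RAMP_FRAC = 0.03

#: amplitude scaling of the first and last half-cycle (push-off / run-out),
#: so the first/last-cycle trimming rule has something meaningful to discard.
EDGE_SCALE = 0.6

#: quasi-isometric velocity threshold in deg/s used for ground-truth labels.
ISO_THRESHOLD = 20.0


@dataclass(frozen=True)
class DisciplineProfile:
    """Discipline-level waveform parameters.

    Angles are degrees of joint extension, durations are per half-cycle
    (one IL or OL phase) in seconds.
    """

    name: str
    turn_duration_mean: float  # s, per half-cycle
    turn_duration_cv: float  # fraction
    natural_freq: float  # Hz, dominant spectral component
    knee_ol_max: float  # deg
    knee_il_min: float  # deg
    knee_switch_angle: float  # deg, both legs at edge change
    hip_ol_max: float  # deg
    hip_il_min: float  # deg
    iso_plateau_frac_ol: float  # fraction of OL half-cycle held near-constant
    iso_plateau_frac_il: float
    vib_freq_band: Tuple[float, float] = (2.0, 15.0)  # Hz
    vib_amp: float = 1.5  # deg (noise SD)
    acc_turn_amp: float = 1.0  # g
    acc_noise_sd: float = 0.05  # g per axis

    def validate(self) -> None:
        numeric = {
            "turn_duration_mean": self.turn_duration_mean,
            "natural_freq": self.natural_freq,
            "knee_ol_max": self.knee_ol_max,
            "knee_il_min": self.knee_il_min,
            "knee_switch_angle": self.knee_switch_angle,
            "hip_ol_max": self.hip_ol_max,
            "hip_il_min": self.hip_il_min,
            "acc_turn_amp": self.acc_turn_amp,
        }
        for k, v in numeric.items():
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"profile field {k} must be finite and positive, got {v}")
        for k, v in (
            ("turn_duration_cv", self.turn_duration_cv),
            ("vib_amp", self.vib_amp),
            ("acc_noise_sd", self.acc_noise_sd),
        ):
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"profile field {k} must be finite and >= 0, got {v}")
        if not self.knee_il_min < self.knee_switch_angle < self.knee_ol_max:
            raise ValueError("require knee_il_min < knee_switch_angle < knee_ol_max")
        if not self.hip_il_min < self.hip_ol_max:
            raise ValueError("require hip_il_min < hip_ol_max")
        for k, p in (
            ("iso_plateau_frac_ol", self.iso_plateau_frac_ol),
            ("iso_plateau_frac_il", self.iso_plateau_frac_il),
        ):
            if not 0 <= p < 1:
                raise ValueError(f"{k} must lie in [0, 1), got {p}")
        lo, hi = self.vib_freq_band
        if lo < 2.0 or hi <= lo:
            raise ValueError("vib_freq_band must be ascending with lower bound >= 2 Hz")

    @property
    def hip_switch_angle(self) -> float:
        return 0.5 * (self.hip_ol_max + self.hip_il_min)


@dataclass
class GroundTruth:
    """Generator-side truth for testing downstream recovery."""

    switch_times: np.ndarray  # s, strictly increasing, n_turns + 1 entries
    leg_labels: List[str]  # per half-cycle, alternating IL/OL
    clean_angle: TimeSeries  # noise-free knee angle, deg
    clean_velocity: TimeSeries  # analytic knee velocity, deg/s
    phase_labels: np.ndarray  # per sample: ECC / ISO / CON from clean velocity
    clean_accr: TimeSeries = None  # noise-free resultant acceleration, g


def default_profiles() -> Dict[str, DisciplineProfile]:
    """The four discipline profiles used throughout the test-bench."""
    profiles = {
        "SL": DisciplineProfile(
            name="SL", turn_duration_mean=1.02, turn_duration_cv=0.10,
            natural_freq=0.54, knee_ol_max=129.0, knee_il_min=67.0,
            knee_switch_angle=100.0, hip_ol_max=126.0, hip_il_min=93.0,
            iso_plateau_frac_ol=0.11, iso_plateau_frac_il=0.19,
            acc_turn_amp=2.0,
        ),
        "GS": DisciplineProfile(
            name="GS", turn_duration_mean=1.47, turn_duration_cv=0.15,
            natural_freq=0.34, knee_ol_max=132.0, knee_il_min=64.0,
            knee_switch_angle=100.0, hip_ol_max=128.0, hip_il_min=90.0,
            iso_plateau_frac_ol=0.34, iso_plateau_frac_il=0.20,
            acc_turn_amp=1.2,
        ),
        "SG": DisciplineProfile(
            name="SG", turn_duration_mean=2.0, turn_duration_cv=0.18,
            natural_freq=0.25, knee_ol_max=127.0, knee_il_min=60.0,
            knee_switch_angle=95.0, hip_ol_max=106.0, hip_il_min=70.0,
            iso_plateau_frac_ol=0.42, iso_plateau_frac_il=0.28,
            acc_turn_amp=0.9,
        ),
        "DH": DisciplineProfile(
            name="DH", turn_duration_mean=2.5, turn_duration_cv=0.20,
            natural_freq=0.21, knee_ol_max=128.0, knee_il_min=58.0,
            knee_switch_angle=95.0, hip_ol_max=89.0, hip_il_min=66.0,
            iso_plateau_frac_ol=0.38, iso_plateau_frac_il=0.38,
            acc_turn_amp=0.7,
        ),
    }
    for p in profiles.values():
        p.validate()
    return profiles


def _ramp_pos(v: np.ndarray, eps: float | None = None) -> np.ndarray:
    """Position of a unit trapezoidal-velocity ramp: r(0)=0, r(1)=1, monotone."""
    eps = RAMP_FRAC if eps is None else eps
    v = np.asarray(v, dtype=float)
    area = 1.0 - eps
    out = np.where(
        v < eps,
        0.5 * v**2 / eps,
        np.where(v <= 1.0 - eps, 0.5 * eps + (v - eps), area - 0.5 * (1.0 - v) ** 2 / eps),
    )
    return out / area


def _ramp_vel(v: np.ndarray, eps: float | None = None) -> np.ndarray:
    """dr/dv of :func:`_ramp_pos`."""
    eps = RAMP_FRAC if eps is None else eps
    v = np.asarray(v, dtype=float)
    area = 1.0 - eps
    out = np.where(v < eps, v / eps, np.where(v <= 1.0 - eps, 1.0, (1.0 - v) / eps))
    return out / area


def _halfcycle_shape(u: np.ndarray, plateau_frac: float) -> Tuple[np.ndarray, np.ndarray]:
    """Unit half-cycle shape s(u) in [0,1] and its derivative ds/du.

    Rise over [0, u1], flat plateau over [u1, 1-u1], fall over [1-u1, 1]
    with u1 = (1 - plateau_frac) / 2.
    """
    u = np.asarray(u, dtype=float)
    u1 = (1.0 - plateau_frac) / 2.0
    s = np.ones_like(u)
    ds = np.zeros_like(u)
    rising = u < u1
    falling = u > 1.0 - u1
    s[rising] = _ramp_pos(u[rising] / u1)
    ds[rising] = _ramp_vel(u[rising] / u1) / u1
    s[falling] = _ramp_pos((1.0 - u[falling]) / u1)
    ds[falling] = -_ramp_vel((1.0 - u[falling]) / u1) / u1
    return s, ds


def _bandlimited_noise(rng: np.random.Generator, n: int, fs: float,
                       band: Tuple[float, float], std: float) -> np.ndarray:
    """White noise band-passed to ``band`` and rescaled to the target SD."""
    if std == 0:
        return np.zeros(n)
    lo, hi = band
    hi = min(hi, 0.49 * fs)
    white = rng.standard_normal(n)
    sos = signal.butter(4, [lo, hi], btype="band", fs=fs, output="sos")
    shaped = signal.sosfiltfilt(sos, white)
    s = shaped.std()
    return shaped * (std / s) if s > 0 else shaped


def classify_velocity(omega: np.ndarray, threshold: float = ISO_THRESHOLD) -> np.ndarray:
    """Label samples ECC / ISO / CON from signed angular velocity.

    The quasi-isometric window is the closed interval [-threshold, +threshold].
    """
    omega = np.asarray(omega, dtype=float)
    labels = np.full(omega.shape, "ISO", dtype="<U3")
    labels[omega < -threshold] = "ECC"
    labels[omega > threshold] = "CON"
    return labels


def simulate_run(
    profile: DisciplineProfile,
    n_turns: int,
    seed: int,
    fs: float = 148.15,
) -> Tuple[RunRecord, GroundTruth]:
    """Generate one run of ``n_turns`` half-cycles plus lead-in and run-out.

    The same seed always yields bit-identical output.  The first half-cycle
    is an outside-leg phase; legs alternate thereafter.
    """
    profile.validate()
    if n_turns < 4:
        raise ValueError("need at least 4 half-cycles")
    if fs < 50:
        raise ValueError("sample rate must be >= 50 Hz")

    rng = np.random.default_rng(seed)

    mean_t = profile.turn_duration_mean
    cv = profile.turn_duration_cv
    durations = rng.normal(mean_t, cv * mean_t, n_turns)
    # Half-cycles much shorter than the mean produce acceleration dips that a
    # 1 Hz low-pass cannot resolve from their neighbors, so the draw is
    # truncated asymmetrically around the mean.
    durations = np.clip(durations, (1.0 - cv) * mean_t, (1.0 + 2.0 * cv) * mean_t)
    durations *= mean_t / durations.mean()  # exact sample-mean duration

    lead = 1.2 * mean_t
    tail = 1.2 * mean_t
    switch_times = lead + np.concatenate([[0.0], np.cumsum(durations)])
    total = switch_times[-1] + tail
    n = int(np.floor(total * fs)) + 1
    t = np.arange(n) / fs

    legs = ["OL" if i % 2 == 0 else "IL" for i in range(n_turns)]

    knee = np.full(n, profile.knee_switch_angle)
    hip = np.full(n, profile.hip_switch_angle)
    vel = np.zeros(n)

    # Acceleration: a plateau at (1 + amp) g with one symmetric cosine dip to
    # 1 g centered at every switch.  Local symmetry around each switch keeps
    # the minima of the zero-phase-filtered resultant exactly at the switch
    # times even when neighboring half-cycles differ in duration.
    amp = profile.acc_turn_amp
    accz = np.full(n, 1.0 + amp)
    bounds = np.concatenate([[switch_times[0] - lead], switch_times, [switch_times[-1] + tail]])
    sigma = 0.22 * mean_t
    for i, s in enumerate(switch_times):
        depth = amp * (EDGE_SCALE if i in (0, len(switch_times) - 1) else 1.0)
        # Gaussian dip, symmetric around the switch; support capped below the
        # neighboring spans so adjacent dips never reach each other's center
        # and the clean minimum sits exactly at the switch time.
        radius = min(4.0 * sigma, 0.98 * (s - bounds[i]), 0.98 * (bounds[i + 2] - s))
        x = (t - s) / sigma
        m = np.abs(t - s) < radius
        rim = np.exp(-0.5 * (radius / sigma) ** 2)
        accz[m] -= depth * (np.exp(-0.5 * x[m] ** 2) - rim) / (1.0 - rim)

    # monotone ramps outside the outermost dips: no spurious minima in the
    # lead-in or run-out
    e0 = switch_times[0] - 4.0 * sigma
    e1 = switch_times[-1] + 4.0 * sigma
    accz += 0.5 * np.maximum(0.0, e0 - t) + 0.5 * np.maximum(0.0, t - e1)

    for i in range(n_turns):
        s0, s1 = switch_times[i], switch_times[i + 1]
        T = s1 - s0
        m = (t >= s0) & (t < s1)
        u = (t[m] - s0) / T
        scale = EDGE_SCALE if i in (0, n_turns - 1) else 1.0
        if legs[i] == "OL":
            amp_knee = profile.knee_ol_max - profile.knee_switch_angle
            amp_hip = profile.hip_ol_max - profile.hip_switch_angle
            plateau = profile.iso_plateau_frac_ol
        else:
            amp_knee = profile.knee_il_min - profile.knee_switch_angle
            amp_hip = profile.hip_il_min - profile.hip_switch_angle
            plateau = profile.iso_plateau_frac_il
        shape, dshape = _halfcycle_shape(u, plateau)
        knee[m] = profile.knee_switch_angle + scale * amp_knee * shape
        hip[m] = profile.hip_switch_angle + scale * amp_hip * shape
        vel[m] = scale * amp_knee * dshape / T

    clean_knee = knee.copy()
    clean_accr = accz.copy()  # x = y = 0 in the clean signal

    knee = knee + _bandlimited_noise(rng, n, fs, profile.vib_freq_band, profile.vib_amp)
    hip = hip + _bandlimited_noise(rng, n, fs, profile.vib_freq_band, profile.vib_amp)
    sd = profile.acc_noise_sd
    accx_n = rng.normal(0.0, sd, n) if sd > 0 else np.zeros(n)
    accy_n = rng.normal(0.0, sd, n) if sd > 0 else np.zeros(n)
    accz_n = rng.normal(0.0, sd, n) if sd > 0 else np.zeros(n)

    run = RunRecord(
        knee=TimeSeries(knee, fs, "deg"),
        hip=TimeSeries(hip, fs, "deg"),
        acc_x=TimeSeries(accx_n, fs, "g"),
        acc_y=TimeSeries(accy_n, fs, "g"),
        acc_z=TimeSeries(accz + accz_n, fs, "g"),
        skier_id="sim",
        session_id=f"sim-{profile.name}-{seed}",
        discipline=profile.name,
    )
    truth = GroundTruth(
        switch_times=switch_times,
        leg_labels=legs,
        clean_angle=TimeSeries(clean_knee, fs, "deg"),
        clean_velocity=TimeSeries(vel, fs, "deg/s"),
        phase_labels=classify_velocity(vel),
        clean_accr=TimeSeries(clean_accr, fs, "g"),
    )
    return run, truth


def sinusoid_phase_fractions(
    amplitude: float, freq: float, threshold: float = ISO_THRESHOLD
) -> Tuple[float, float, float]:
    """Closed-form (ecc%, iso%, con%) for a pure sinusoid angle trace.

    For theta(t) = A sin(2 pi f t) the velocity peaks at w_max = 2 pi f A and
    the fraction of time with |velocity| <= c is (2/pi) asin(min(1, c/w_max)).
    Flexion and extension split the remainder equally.
    """
    if amplitude <= 0 or freq <= 0:
        raise ValueError("amplitude and frequency must be positive")
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    w_max = 2 * np.pi * freq * amplitude
    iso = (2 / np.pi) * np.arcsin(min(1.0, threshold / w_max)) * 100.0
    ecc = con = (100.0 - iso) / 2.0
    return ecc, iso, con


def truth_iso_fraction(truth: GroundTruth, leg: str | None = None) -> float:
    """Fraction (%) of clean samples labeled ISO, optionally within one leg."""
    fs = truth.clean_velocity.fs
    t = truth.clean_velocity.t
    labels = truth.phase_labels
    if leg is None:
        mask = (t >= truth.switch_times[0]) & (t < truth.switch_times[-1])
    else:
        mask = np.zeros(len(t), dtype=bool)
        for i, lg in enumerate(truth.leg_labels):
            if lg == leg:
                mask |= (t >= truth.switch_times[i]) & (t < truth.switch_times[i + 1])
    return 100.0 * np.mean(labels[mask] == "ISO")
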