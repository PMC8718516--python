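"""Synthetic cohort generator for the four occupational-therapy actions.

Produces paired kinematic streams (a low-rate camera-like sensor with
jitter/spikes and a high-rate IMU-like sensor with drift), three-channel
burst-modulated sEMG, and full cohorts with per-record ground truth, so
that every downstream stage is testable without recorded data.

The four action templates are piecewise-cubic interpolations of
hand-chosen waypoints realizing the protocol's motion descriptions:

1. lift an object above the head (>45 deg) and lower it;
2. trembling lift with two intermediate lower-raise cycles before the
   final raise;
3. straight-arm lift to a modest (>20 deg) elevation;
4. lift, translate horizontally to the right, and put down.

Impairment severity (Lovett grade) attenuates movement amplitude,
adds tremor, slows execution, and perturbs the path with a smooth
random "waver"; only the monotonicity of this mapping is asserted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.interpolate import CubicSpline, PchipInterpolator

from otassess.emg import EMGRecording
from otassess.fusion import JointTrajectory

__all__ = [
    "ActionTemplate",
    "SeverityProfile",
    "SensorNoiseModel",
    "generate_action_trajectory",
    "generate_semg",
    "generate_cohort",
    "Cohort",
    "CohortRecord",
    "write_cohort",
]

ACTION_IDS = (1, 2, 3, 4)

# (u, x, y, z) waypoints per action; u is normalized time, coords meters.
_WAYPOINTS: dict[int, tuple[np.ndarray, np.ndarray]] = {}


def _wp(action_id, u, x, y, z):
    _WAYPOINTS[action_id] = (
        np.asarray(u, dtype=float),
        np.column_stack([x, y, z]).astype(float),
    )


_wp(
    1,
    [0.0, 0.20, 0.45, 0.60, 0.80, 1.0],
    [0.00, 0.05, 0.12, 0.10, 0.04, 0.00],
    [0.30, 0.38, 0.26, 0.26, 0.37, 0.30],
    [0.00, 0.18, 0.55, 0.55, 0.18, 0.00],
)
# two lower-raise cycles (interior z maxima at u=0.15 and u=0.42)
# before the final raise
_wp(
    2,
    [0.0, 0.15, 0.28, 0.42, 0.55, 0.72, 0.82, 1.0],
    [0.00, 0.04, 0.02, 0.06, 0.03, 0.08, 0.07, 0.00],
    [0.30, 0.36, 0.32, 0.38, 0.33, 0.40, 0.38, 0.30],
    [0.00, 0.25, 0.15, 0.35, 0.22, 0.55, 0.53, 0.00],
)
_wp(
    3,
    [0.0, 0.40, 0.60, 1.0],
    [0.00, 0.10, 0.08, 0.00],
    [0.35, 0.50, 0.48, 0.35],
    [0.00, 0.22, 0.22, 0.00],
)
# dominant horizontal (x) displacement in the middle third
_wp(
    4,
    [0.0, 0.25, 0.33, 0.50, 0.66, 0.78, 1.0],
    [0.00, 0.00, 0.02, 0.20, 0.38, 0.40, 0.40],
    [0.30, 0.36, 0.35, 0.33, 0.35, 0.36, 0.30],
    [0.00, 0.30, 0.30, 0.30, 0.30, 0.28, 0.00],
)

_DURATIONS_S = {1: 4.0, 2: 6.0, 3: 3.5, 4: 5.0}


@dataclass
class ActionTemplate:
    """Parametric reference motion for one action.

    ``waypoint_fn`` maps normalized time ``u`` in [0, 1] to a 3-D
    position in meters; it is continuous by construction (piecewise
    cubic through the waypoints).
    """

    action_id: int
    duration_s: float
    waypoint_fn: Callable[[np.ndarray], np.ndarray]

    @classmethod
    def standard(cls, action_id: int) -> "ActionTemplate":
        if action_id not in ACTION_IDS:
            raise ValueError(
                f"unknown action_id {action_id!r}; expected one of {ACTION_IDS}"
            )
        u, pts = _WAYPOINTS[action_id]
        interp = PchipInterpolator(u, pts, axis=0)

        def fn(uu):
            return interp(np.clip(uu, 0.0, 1.0))

        return cls(action_id, _DURATIONS_S[action_id], fn)


# grade -> (amplitude_scale, tremor_amp_m, tremor_hz, lag_scale, waver_amp_m)
_SEVERITY_TABLE = {
    5: (1.00, 0.000, 5.0, 1.00, 0.00),
    4: (0.85, 0.004, 5.0, 1.10, 0.03),
    3: (0.65, 0.008, 5.0, 1.25, 0.07),
    2: (0.45, 0.012, 4.5, 1.45, 0.11),
    1: (0.30, 0.016, 4.5, 1.70, 0.15),
    0: (0.05, 0.016, 4.0, 2.00, 0.18),
}


@dataclass(frozen=True)
class SeverityProfile:
    """Severity-dependent transformation of the reference motion.

    Grade 5 (healthy) is the identity: full amplitude, no tremor, no
    time dilation, no path waver.  Amplitude is non-increasing and
    tremor/waver non-decreasing as the grade drops.
    """

    lovett_grade: int
    amplitude_scale: float
    tremor_amp: float
    tremor_hz: float
    lag_scale: float
    waver_amp: float = 0.0

    def __post_init__(self) -> None:
        if not 0 <= self.lovett_grade <= 5:
            raise ValueError("lovett_grade must be in 0..5")
        if not 0 < self.amplitude_scale <= 1:
            raise ValueError("amplitude_scale must be in (0, 1]")
        if self.tremor_amp < 0 or self.waver_amp < 0:
            raise ValueError("tremor_amp and waver_amp must be non-negative")
        if self.lag_scale < 1:
            raise ValueError("lag_scale must be >= 1")

    @classmethod
    def from_grade(cls, grade: int) -> "SeverityProfile":
        if grade not in _SEVERITY_TABLE:
            raise ValueError(f"unknown Lovett grade {grade!r}")
        amp, trem, hz, lag, waver = _SEVERITY_TABLE[grade]
        return cls(grade, amp, trem, hz, lag, waver)


@dataclass(frozen=True)
class SensorNoiseModel:
    """Additive noise model for one kinematic sensor.

    ``jitter_sd`` white noise per axis (m), ``spike_prob`` per-sample
    probability of an outlier of scale ``spike_sd`` (m), ``drift_sd``
    random-walk increment scale (m per sqrt s), ``ts_jitter_sd``
    timestamp jitter (s, truncated to keep timestamps monotone).
    """

    jitter_sd: float = 0.0
    spike_prob: float = 0.0
    spike_sd: float = 0.0
    drift_sd: float = 0.0
    rate_hz: float = 30.0
    ts_jitter_sd: float = 0.0

    def __post_init__(self) -> None:
        for name in ("jitter_sd", "spike_prob", "spike_sd", "drift_sd", "ts_jitter_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.rate_hz <= 0:
            raise ValueError("rate_hz must be positive")

    @classmethod
    def kinect_like(cls, rate_hz: float = 30.0) -> "SensorNoiseModel":
        return cls(
            jitter_sd=0.004,
            spike_prob=0.01,
            spike_sd=0.03,
            drift_sd=0.0,
            rate_hz=rate_hz,
            ts_jitter_sd=0.002,
        )

    @classmethod
    def imu_like(cls, rate_hz: float = 100.0) -> "SensorNoiseModel":
        return cls(
            jitter_sd=0.001,
            spike_prob=0.0,
            spike_sd=0.0,
            drift_sd=0.003,
            rate_hz=rate_hz,
            ts_jitter_sd=0.0005,
        )

    @classmethod
    def noiseless(cls, rate_hz: float) -> "SensorNoiseModel":
        return cls(rate_hz=rate_hz)


def _latent_motion(
    template: ActionTemplate, severity: SeverityProfile, rng: np.random.Generator
) -> tuple[Callable[[np.ndarray], np.ndarray], float]:
    """Severity-transformed latent motion shared by both sensors.

    Returns a function of absolute time plus the dilated duration.
    """
    duration = template.duration_s * severity.lag_scale
    n_knots = 7
    knots = np.linspace(0.0, 1.0, n_knots)
    offsets = rng.normal(0.0, severity.waver_amp, size=(n_knots, 3))
    offsets[0] = 0.0
    offsets[-1] = 0.0
    waver = CubicSpline(knots, offsets, axis=0, bc_type="clamped")
    phases = rng.uniform(0.0, 2 * np.pi, size=3)
    tremor_axis = np.array([0.5, 0.5, 1.0])  # predominantly vertical

    def fn(t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        u = np.clip(t / duration, 0.0, 1.0)
        pos = severity.amplitude_scale * template.waypoint_fn(u)
        pos = pos + waver(u)
        trem = severity.tremor_amp * tremor_axis[None, :] * np.sin(
            2 * np.pi * severity.tremor_hz * t[:, None] + phases[None, :]
        )
        return pos + trem

    return fn, duration


def _sensor_stream(
    latent: Callable[[np.ndarray], np.ndarray],
    duration: float,
    noise: SensorNoiseModel,
    rng: np.random.Generator,
    sensor_id: str,
) -> JointTrajectory:
    dt = 1.0 / noise.rate_hz
    n = int(np.floor(duration * noise.rate_hz)) + 1
    t = np.arange(n) * dt
    if noise.ts_jitter_sd > 0:
        jit = rng.normal(0.0, noise.ts_jitter_sd, size=n)
        t = t + np.clip(jit, -0.4 * dt, 0.4 * dt)
    pos = latent(t)
    if noise.jitter_sd > 0:
        pos = pos + rng.normal(0.0, noise.jitter_sd, size=(n, 3))
    if noise.spike_prob > 0 and noise.spike_sd > 0:
        mask = rng.random(n) < noise.spike_prob
        pos = pos + mask[:, None] * rng.normal(0.0, noise.spike_sd, size=(n, 3))
    if noise.drift_sd > 0:
        steps = rng.normal(0.0, noise.drift_sd * np.sqrt(dt), size=(n, 3))
        pos = pos + np.cumsum(steps, axis=0)
    return JointTrajectory(sensor_id, t, pos)


def generate_action_trajectory(
    action_id: int,
    severity: SeverityProfile,
    noise_a: SensorNoiseModel,
    noise_b: SensorNoiseModel,
    seed: int,
) -> tuple[JointTrajectory, JointTrajectory]:
    """Generate one action repetition as seen by two sensors.

    Both streams sample the same latent severity-transformed template at
    their own rates, each corrupted by its own noise model, on a common
    clock origin.
    """
    template = ActionTemplate.standard(action_id)
    rng = np.random.default_rng(seed)
    latent, duration = _latent_motion(template, severity, rng)
    rng_a, rng_b = rng.spawn(2)
    s_a = _sensor_stream(latent, duration, noise_a, rng_a, "kinect")
    s_b = _sensor_stream(latent, duration, noise_b, rng_b, "imu")
    return s_a, s_b


# ---------------------------------------------------------------------------
# sEMG generation

# per-action, per-channel envelope weights (forelimb, biceps, deltoid)
_CHANNEL_WEIGHT = {
    1: (0.7, 1.0, 0.9),
    2: (0.9, 0.8, 1.0),
    3: (1.0, 0.9, 0.4),
    4: (0.6, 0.7, 1.0),
}

_BURST_S = {1: 2.5, 2: 4.0, 3: 2.0, 4: 3.0}


def _trapezoid(u: np.ndarray, ramp: float = 0.08) -> np.ndarray:
    up = np.clip(u / ramp, 0.0, 1.0)
    down = np.clip((1.0 - u) / ramp, 0.0, 1.0)
    return np.minimum(up, down) * ((u >= 0) & (u <= 1))


def _action_modulation(action_id: int, ch: int, u: np.ndarray) -> np.ndarray:
    """Temporal envelope shape inside one burst, distinct per action."""
    # floors are kept high so the min x length optimum spans the burst
    if action_id == 1:
        # single sustained effort, channel-dependent peak position
        peak = (0.35, 0.5, 0.65)[ch]
        return 0.45 + 0.55 * np.exp(-(((u - peak) / 0.30) ** 2))
    if action_id == 2:
        # three sub-efforts (lower-raise cycles then the final raise)
        return 0.40 + 0.60 * 0.5 * (1.0 + np.cos(6 * np.pi * u + np.pi))
    if action_id == 3:
        # short symmetric effort
        return 0.45 + 0.55 * np.sin(np.pi * np.clip(u, 0, 1)) ** 2
    # action 4: lift hump then translation hump, deltoid lags biceps
    shift = (0.0, -0.06, 0.08)[ch]
    return 0.40 + 0.60 * 0.5 * (1.0 + np.cos(4 * np.pi * (u - shift) + np.pi))


def _bandlimited_noise(
    n: int, rate_hz: float, rng: np.random.Generator
) -> np.ndarray:
    x = rng.standard_normal(n)
    high = min(450.0, 0.45 * rate_hz)
    sos = sps.butter(4, [20.0, high], btype="bandpass", fs=rate_hz, output="sos")
    y = sps.sosfiltfilt(sos, x)
    return y / y.std()


def generate_semg(
    action_id: int,
    severity: SeverityProfile,
    rate_hz: float = 1000.0,
    seed: int = 0,
    n_bursts: int = 1,
    rest_s: float = 2.0,
    lead_s: float = 0.5,
) -> tuple[EMGRecording, list[tuple[int, int]]]:
    """Generate burst-modulated 3-channel sEMG for one action.

    Each of ``n_bursts`` repetitions is an action-specific envelope
    (amplitude-modulated band-limited noise) separated by ``rest_s`` of
    low-level baseline.  Returns the recording and the ground-truth
    burst support as half-open sample intervals.
    """
    if action_id not in ACTION_IDS:
        raise ValueError(
            f"unknown action_id {action_id!r}; expected one of {ACTION_IDS}"
        )
    if rate_hz < 200:
        raise ValueError("rate_hz too low for band-limited sEMG (need >= 200)")
    if n_bursts < 1:
        raise ValueError("n_bursts must be >= 1")
    rng = np.random.default_rng(seed)
    burst_s = _BURST_S[action_id] * severity.lag_scale
    total_s = lead_s + n_bursts * burst_s + (n_bursts - 1) * rest_s + lead_s
    n = int(round(total_s * rate_hz))
    t = np.arange(n) / rate_hz

    base_amp = 1.0 * (0.6 + 0.4 * severity.amplitude_scale)  # mV
    weights = _CHANNEL_WEIGHT[action_id]
    envelope = np.zeros((n, 3))
    intervals: list[tuple[int, int]] = []
    for k in range(n_bursts):
        start_s = lead_s + k * (burst_s + rest_s)
        u = (t - start_s) / burst_s
        trap = _trapezoid(u)
        for c in range(3):
            envelope[:, c] += (
                base_amp * weights[c] * trap * _action_modulation(action_id, c, u)
            )
        i0 = int(round(start_s * rate_hz))
        i1 = min(n, int(round((start_s + burst_s) * rate_hz)))
        intervals.append((i0, i1))

    baseline_sd = 0.03 * base_amp
    channels = np.empty((n, 3))
    for c in range(3):
        carrier = _bandlimited_noise(n, rate_hz, rng)
        baseline = baseline_sd * _bandlimited_noise(n, rate_hz, rng)
        channels[:, c] = envelope[:, c] * carrier + baseline
    return EMGRecording(rate_hz, channels), intervals


# ---------------------------------------------------------------------------
# Cohorts


@dataclass
class CohortRecord:
    participant_id: int
    grade: int
    action_id: int
    rep: int
    trajectory_a: JointTrajectory
    trajectory_b: JointTrajectory
    emg: EMGRecording
    emg_intervals: list[tuple[int, int]]


@dataclass
class Cohort:
    records: list[CohortRecord]
    grades: list[int]
    seed: int

    def __len__(self) -> int:
        return len(self.records)


def generate_cohort(
    n_participants: int,
    grades: list[int],
    reps_per_action: int = 15,
    seed: int = 0,
    emg_rate_hz: float = 1000.0,
    noise_a: SensorNoiseModel | None = None,
    noise_b: SensorNoiseModel | None = None,
) -> Cohort:
    """Generate a labeled cohort: ``reps_per_action x 4`` records per
    participant, balanced across actions by construction."""
    if len(grades) != n_participants:
        raise ValueError("grades must have one entry per participant")
    if noise_a is None:
        noise_a = SensorNoiseModel.kinect_like()
    if noise_b is None:
        noise_b = SensorNoiseModel.imu_like()
    master = np.random.default_rng(seed)
    records: list[CohortRecord] = []
    for pid in range(n_participants):
        severity = SeverityProfile.from_grade(grades[pid])
        for action_id in ACTION_IDS:
            for rep in range(reps_per_action):
                s_traj, s_emg = master.integers(0, 2**31, size=2)
                tr_a, tr_b = generate_action_trajectory(
                    action_id, severity, noise_a, noise_b, int(s_traj)
                )
                emg, ivs = generate_semg(
                    action_id, severity, emg_rate_hz, int(s_emg)
                )
                records.append(
                    CohortRecord(
                        participant_id=pid,
                        grade=grades[pid],
                        action_id=action_id,
                        rep=rep,
                        trajectory_a=tr_a,
                        trajectory_b=tr_b,
                        emg=emg,
                        emg_intervals=ivs,
                    )
                )
    return Cohort(records=records, grades=list(grades), seed=seed)


def write_cohort(cohort: Cohort, outdir: str | Path) -> Path:
    """Write a cohort to a directory of CSV files plus a manifest and a
    ground-truth JSON of burst intervals."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    truth: dict[str, list[list[int]]] = {}
    for rec in cohort.records:
        stem = f"p{rec.participant_id:02d}_a{rec.action_id}_r{rec.rep:02d}"
        f_a = outdir / f"{stem}_kinect.csv"
        f_b = outdir / f"{stem}_imu.csv"
        f_e = outdir / f"{stem}_emg.csv"
        rec.trajectory_a.to_csv(f_a)
        rec.trajectory_b.to_csv(f_b)
        rec.emg.to_csv(f_e)
        truth[stem] = [list(iv) for iv in rec.emg_intervals]
        rows.append(
            {
                "participant_id": rec.participant_id,
                "action_id": rec.action_id,
                "rep": rec.rep,
                "grade": rec.grade,
                "kinect_csv": f_a.name,
                "imu_csv": f_b.name,
                "emg_csv": f_e.name,
            }
        )
    pd.DataFrame(rows).to_csv(outdir / "manifest.csv", index=False)
    with open(outdir / "ground_truth.json", "w") as fh:
        json.dump(truth, fh, indent=1)
    return outdir
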