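"""Synchronization and per-axis Kalman fusion of two joint-coordinate streams.

The two streams come from a depth-camera skeleton tracker (low rate, jitter
and occasional spikes) and an IMU-derived position estimate (high rate,
slow drift).  Fusion is a scalar recursion applied independently per axis.

Two fusion modes are provided:

``standard``
    Per-sample inverse-variance fusion: the IMU sample ``b`` acts as the
    prediction source with variance ``p0 + Z`` and the camera sample ``a``
    as the measurement with variance ``A``.  Because ``b`` is a fresh,
    independent reading at every step (not a propagated state), its
    variance does not accumulate, the gain is constant, and the fused
    error variance ``(p0+Z)·A / (p0+Z+A)`` never exceeds either sensor's.

``literal``
    A faithful transcription of the published pseudocode, with its
    square-root gain and ``x = a + K·(a - b)`` update, kept for audit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "JointTrajectory",
    "FusedTrajectory",
    "synchronize_streams",
    "estimate_variance",
    "kalman_fuse",
    "fuse_trajectories",
]


@dataclass
class JointTrajectory:
    """One joint's timestamped 3-D coordinate series from a single sensor.

    Parameters
    ----------
    sensor_id
        Free-form label identifying the originating sensor.
    timestamps
        Strictly increasing sample times in seconds, shape ``(n,)``.
    coords
        Positions in meters, shape ``(n, 3)``.
    """

    sensor_id: str
    timestamps: np.ndarray
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.timestamps.ndim != 1:
            raise ValueError("timestamps must be 1-D")
        if self.coords.shape != (self.timestamps.size, 3):
            raise ValueError(
                f"coords shape {self.coords.shape} does not match "
                f"{self.timestamps.size} timestamps"
            )
        if not np.all(np.isfinite(self.timestamps)) or not np.all(
            np.isfinite(self.coords)
        ):
            raise ValueError("non-finite values in trajectory")
        diffs = np.diff(self.timestamps)
        bad = np.nonzero(diffs <= 0)[0]
        if bad.size:
            raise ValueError(
                f"timestamps not strictly increasing at index {bad[0] + 1}"
            )

    def __len__(self) -> int:
        return self.timestamps.size

    @property
    def duration(self) -> float:
        return float(self.timestamps[-1] - self.timestamps[0])

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            {
                "timestamp_s": self.timestamps,
                "x_m": self.coords[:, 0],
                "y_m": self.coords[:, 1],
                "z_m": self.coords[:, 2],
            }
        )
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, sensor_id: str | None = None) -> "JointTrajectory":
        df = pd.read_csv(path)
        required = {"timestamp_s", "x_m", "y_m", "z_m"}
        if not required.issubset(df.columns):
            raise ValueError(f"{path}: missing columns {required - set(df.columns)}")
        return cls(
            sensor_id=sensor_id or Path(path).stem,
            timestamps=df["timestamp_s"].to_numpy(),
            coords=df[["x_m", "y_m", "z_m"]].to_numpy(),
        )


@dataclass
class FusedTrajectory:
    """Per-axis Kalman-fused coordinate series on the common resampled grid."""

    timestamps: np.ndarray
    coords: np.ndarray
    gain_trace: np.ndarray = field(default=None)  # (n, 3) per-step gain

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (self.timestamps.size, 3):
            raise ValueError("coords shape does not match timestamps")
        if self.gain_trace is not None:
            self.gain_trace = np.asarray(self.gain_trace, dtype=float)

    def __len__(self) -> int:
        return self.timestamps.size

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            {
                "timestamp_s": self.timestamps,
                "x_m": self.coords[:, 0],
                "y_m": self.coords[:, 1],
                "z_m": self.coords[:, 2],
            }
        )
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "FusedTrajectory":
        df = pd.read_csv(path)
        return cls(
            timestamps=df["timestamp_s"].to_numpy(),
            coords=df[["x_m", "y_m", "z_m"]].to_numpy(),
        )


def synchronize_streams(
    s1: JointTrajectory,
    s2: JointTrajectory,
    target_rate_hz: float,
    offset_s: float = 0.0,
    min_overlap_s: float = 0.0,
) -> tuple[JointTrajectory, JointTrajectory]:
    """Resample both streams onto the identical uniform grid over their overlap.

    Both streams are linearly interpolated onto a grid of spacing
    ``1/target_rate_hz`` starting at the beginning of the overlapping time
    support; samples outside the overlap are discarded.

    Parameters
    ----------
    offset_s
        Constant clock offset added to ``s2``'s timestamps before
        alignment (stands in for manual fine-tuning).
    min_overlap_s
        Reject pairs whose overlap is shorter than this.
    """
    if target_rate_hz <= 0:
        raise ValueError("target_rate_hz must be positive")
    t2 = s2.timestamps + offset_s
    t_start = max(s1.timestamps[0], t2[0])
    t_end = min(s1.timestamps[-1], t2[-1])
    overlap = t_end - t_start
    if overlap <= 0:
        raise ValueError(
            f"streams have no temporal overlap "
            f"({s1.sensor_id}: [{s1.timestamps[0]:.3f}, {s1.timestamps[-1]:.3f}] s, "
            f"{s2.sensor_id}: [{t2[0]:.3f}, {t2[-1]:.3f}] s)"
        )
    if overlap < min_overlap_s:
        raise ValueError(
            f"overlap {overlap:.3f} s shorter than required {min_overlap_s:.3f} s"
        )
    n = int(np.floor(overlap * target_rate_hz)) + 1
    grid = t_start + np.arange(n) / target_rate_hz

    def _interp(traj_t: np.ndarray, coords: np.ndarray) -> np.ndarray:
        out = np.empty((n, 3))
        for ax in range(3):
            out[:, ax] = np.interp(grid, traj_t, coords[:, ax])
        return out

    r1 = JointTrajectory(s1.sensor_id, grid, _interp(s1.timestamps, s1.coords))
    r2 = JointTrajectory(s2.sensor_id, grid, _interp(t2, s2.coords))
    return r1, r2


def estimate_variance(s: JointTrajectory, detrend_window: int) -> np.ndarray:
    """Per-axis noise variance after moving-average detrending.

    The raw variance of a moving limb conflates motion with sensor noise,
    so the slow component is removed with a centered moving average of
    ``detrend_window`` samples and the variance of the residual is
    returned, shape ``(3,)``.
    """
    if detrend_window < 1:
        raise ValueError("detrend_window must be >= 1")
    n = len(s)
    if n < 2 * detrend_window:
        raise ValueError(
            f"need at least {2 * detrend_window} samples, got {n}"
        )
    resid = s.coords - _moving_average(s.coords, detrend_window)
    return resid.var(axis=0)


def _moving_average(x: np.ndarray, window: int) -> np.ndarray:
    """Centered moving mean with edge-truncated windows, along axis 0."""
    n = x.shape[0]
    half_lo = (window - 1) // 2
    half_hi = window // 2
    csum = np.cumsum(np.concatenate([np.zeros((1,) + x.shape[1:]), x]), axis=0)
    lo = np.clip(np.arange(n) - half_lo, 0, n)
    hi = np.clip(np.arange(n) + half_hi + 1, 0, n)
    counts = (hi - lo).astype(float)
    shape = (n,) + (1,) * (x.ndim - 1)
    return (csum[hi] - csum[lo]) / counts.reshape(shape)


def kalman_fuse(
    a_series: np.ndarray,
    b_series: np.ndarray,
    A: float | np.ndarray,
    Z: float | np.ndarray,
    p0: float | np.ndarray = 0.0,
    mode: str = "standard",
) -> tuple[np.ndarray, np.ndarray]:
    """Fuse two synchronized measurement series with a scalar recursion.

    Operates element-wise per axis: inputs of shape ``(n,)`` or ``(n, k)``
    are fused column by column.  ``A`` is the variance of stream ``a``
    (camera), ``Z`` of stream ``b`` (IMU); scalars or per-column arrays.

    Returns
    -------
    fused, gain : ndarray
        Fused series and the per-step gain trace, same shape as input.
    """
    a = np.asarray(a_series, dtype=float)
    b = np.asarray(b_series, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: a {a.shape} vs b {b.shape}")
    if mode not in ("standard", "literal"):
        raise ValueError(f"unknown mode {mode!r}")
    squeeze = a.ndim == 1
    if squeeze:
        a = a[:, None]
        b = b[:, None]
    ncols = a.shape[1]
    A = np.broadcast_to(np.asarray(A, dtype=float), (ncols,)).copy()
    Z = np.broadcast_to(np.asarray(Z, dtype=float), (ncols,)).copy()
    p0 = np.broadcast_to(np.asarray(p0, dtype=float), (ncols,)).copy()
    if np.any(A < 0) or np.any(Z < 0) or np.any(p0 < 0):
        raise ValueError("A, Z and p0 must be non-negative")

    if mode == "standard":
        # b is a fresh independent reading each step: prediction variance
        # p0 + Z does not propagate, so the gain is constant.
        Pp = p0 + Z
        with np.errstate(invalid="ignore"):
            K = np.where(Pp + A > 0, Pp / (Pp + A), 1.0)
        fused = b + K[None, :] * (a - b)
        gain = np.broadcast_to(K, a.shape).copy()
    else:
        fused = np.empty_like(a)
        gain = np.empty_like(a)
        p = p0.copy()
        for k in range(a.shape[0]):
            Pp = np.sqrt(p + Z)
            Pp2 = Pp**2
            with np.errstate(invalid="ignore"):
                K = np.where(Pp2 + A > 0, np.sqrt(Pp2 / (Pp2 + A)), 1.0)
            fused[k] = a[k] + K * (a[k] - b[k])
            PK = np.sqrt((1.0 - K) * Pp2)
            p = PK**2
            gain[k] = K
    if squeeze:
        return fused[:, 0], gain[:, 0]
    return fused, gain


def fuse_trajectories(
    s_a: JointTrajectory,
    s_b: JointTrajectory,
    mode: str = "standard",
    A: np.ndarray | float | None = None,
    Z: np.ndarray | float | None = None,
    p0: float = 0.0,
    detrend_window: int | None = None,
) -> FusedTrajectory:
    """Fuse two *synchronized* trajectories into a :class:`FusedTrajectory`.

    Variances ``A`` (stream a) and ``Z`` (stream b) are estimated from the
    streams themselves via :func:`estimate_variance` when not given;
    ``detrend_window`` defaults to half a second at the stream rate.
    """
    if len(s_a) != len(s_b):
        raise ValueError("streams must be synchronized to equal length")
    if not np.allclose(s_a.timestamps, s_b.timestamps):
        raise ValueError("streams must share the same time grid")
    if A is None or Z is None:
        if detrend_window is None:
            rate = 1.0 / float(np.median(np.diff(s_a.timestamps)))
            detrend_window = max(3, int(round(0.5 * rate)))
        if A is None:
            A = estimate_variance(s_a, detrend_window)
        if Z is None:
            Z = estimate_variance(s_b, detrend_window)
    fused, gain = kalman_fuse(s_a.coords, s_b.coords, A, Z, p0, mode)
    return FusedTrajectory(s_a.timestamps.copy(), fused, gain)
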