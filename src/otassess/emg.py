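"""Surface-EMG processing: filtering, integrated-EMG envelope, and
automatic burst segmentation via a recursive min-value x length search.

The segmentation recursion scores every window it visits by the product
of the window's minimum envelope value and its length, recursing on the
sub-windows left and right of that minimum.  The interval with the
globally maximal score is the detected movement burst (this is the
largest-rectangle-in-histogram search); accepted bursts are zeroed out
and the search repeated to enumerate all repetitions in a recording.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps

__all__ = [
    "EMGRecording",
    "IEMGEnvelope",
    "ActivityInterval",
    "bandpass_filter",
    "compute_iemg",
    "best_interval",
    "segment_bursts",
    "extract_segment",
]

CHANNEL_NAMES = ("forelimb", "biceps", "deltoid")


@dataclass
class EMGRecording:
    """Multi-channel raw sEMG with sampling rate.

    ``channels`` is an ``(n, 3)`` array of amplitudes (mV); the three
    columns are the forelimb muscle group, biceps brachii and deltoid.
    """

    rate_hz: float
    channels: np.ndarray
    channel_names: tuple[str, ...] = CHANNEL_NAMES

    def __post_init__(self) -> None:
        self.channels = np.asarray(self.channels, dtype=float)
        if self.rate_hz <= 0:
            raise ValueError("rate_hz must be positive")
        if self.channels.ndim != 2:
            raise ValueError("channels must be 2-D (samples x channels)")
        if len(self.channel_names) != self.channels.shape[1]:
            raise ValueError("channel_names length mismatch")

    def __len__(self) -> int:
        return self.channels.shape[0]

    @property
    def n_channels(self) -> int:
        return self.channels.shape[1]

    def to_csv(self, path: str | Path) -> None:
        n = len(self)
        df = pd.DataFrame({"timestamp_s": np.arange(n) / self.rate_hz})
        for i in range(self.n_channels):
            df[f"ch{i + 1}"] = self.channels[:, i]
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, rate_hz: float | None = None) -> "EMGRecording":
        df = pd.read_csv(path)
        ch_cols = [c for c in df.columns if c.startswith("ch")]
        if not ch_cols:
            raise ValueError(f"{path}: no channel columns (ch1, ch2, ...)")
        if rate_hz is None:
            ts = df["timestamp_s"].to_numpy()
            if ts.size < 2:
                raise ValueError(f"{path}: cannot infer rate from <2 samples")
            rate_hz = 1.0 / float(np.median(np.diff(ts)))
        names = CHANNEL_NAMES[: len(ch_cols)] if len(ch_cols) <= 3 else tuple(ch_cols)
        return cls(rate_hz=rate_hz, channels=df[ch_cols].to_numpy(), channel_names=names)


@dataclass
class IEMGEnvelope:
    """Windowed mean-absolute-amplitude envelope of an sEMG channel (or
    a channel sum); same length as the input signal."""

    rate_hz: float
    values: np.ndarray
    window_samples: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("envelope values must be 1-D")
        if np.any(self.values < 0):
            raise ValueError("envelope values must be non-negative")

    def __len__(self) -> int:
        return self.values.size


@dataclass
class ActivityInterval:
    """Half-open sample interval [start, end) with its min x length score."""

    start: int
    end: int
    score: float

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if self.score < 0:
            raise ValueError("score must be non-negative")

    @property
    def length(self) -> int:
        return self.end - self.start

    def duration_s(self, rate_hz: float) -> float:
        return self.length / rate_hz

    def iou(self, other: "ActivityInterval") -> float:
        inter = max(0, min(self.end, other.end) - max(self.start, other.start))
        union = max(self.end, other.end) - min(self.start, other.start)
        return inter / union if union else 0.0


def bandpass_filter(
    rec: EMGRecording,
    low_hz: float = 20.0,
    high_hz: float = 450.0,
    notch_hz: float | None = 50.0,
    order: int = 4,
) -> EMGRecording:
    """Zero-phase Butterworth band-pass with optional mains notch."""
    nyq = rec.rate_hz / 2.0
    if not (0 < low_hz < high_hz < nyq):
        raise ValueError(
            f"band [{low_hz}, {high_hz}] Hz invalid for Nyquist {nyq} Hz"
        )
    sos = sps.butter(order, [low_hz, high_hz], btype="bandpass", fs=rec.rate_hz, output="sos")
    out = sps.sosfiltfilt(sos, rec.channels, axis=0)
    if notch_hz is not None:
        if not (0 < notch_hz < nyq):
            raise ValueError(f"notch {notch_hz} Hz exceeds Nyquist {nyq} Hz")
        b, a = sps.iirnotch(notch_hz, Q=30.0, fs=rec.rate_hz)
        out = sps.filtfilt(b, a, out, axis=0)
    return EMGRecording(rec.rate_hz, out, rec.channel_names)


def _windowed_abs_mean(x: np.ndarray, window: int) -> np.ndarray:
    """Centered moving mean of |x| with edge-truncated windows."""
    ax = np.abs(x)
    n = ax.size
    half_lo = (window - 1) // 2
    half_hi = window // 2
    csum = np.concatenate([[0.0], np.cumsum(ax)])
    lo = np.clip(np.arange(n) - half_lo, 0, n)
    hi = np.clip(np.arange(n) + half_hi + 1, 0, n)
    return (csum[hi] - csum[lo]) / (hi - lo)


def compute_iemg(
    rec: EMGRecording,
    window_s: float = 0.1,
    channel: int | None = None,
) -> IEMGEnvelope | list[IEMGEnvelope]:
    """Integrated-EMG envelope: centered moving mean of the absolute
    signal over a ``window_s`` window, truncated at the edges.

    Returns one envelope per channel, or a single envelope when
    ``channel`` is given.
    """
    window = int(round(window_s * rec.rate_hz))
    if window < 1:
        raise ValueError("window_s times rate must be at least one sample")
    if channel is not None:
        vals = _windowed_abs_mean(rec.channels[:, channel], window)
        return IEMGEnvelope(rec.rate_hz, vals, window)
    return [
        IEMGEnvelope(rec.rate_hz, _windowed_abs_mean(rec.channels[:, c], window), window)
        for c in range(rec.n_channels)
    ]


def summed_envelope(rec: EMGRecording, window_s: float = 0.1) -> IEMGEnvelope:
    """Channel-summed iEMG envelope used for burst segmentation."""
    envs = compute_iemg(rec, window_s)
    vals = np.sum([e.values for e in envs], axis=0)
    return IEMGEnvelope(rec.rate_hz, vals, envs[0].window_samples)


def best_interval(
    values,
) -> tuple[ActivityInterval, list[ActivityInterval]]:
    """Find the contiguous interval maximizing (minimum value x length).

    Recursion: over the current window find the minimum ``a`` at index
    ``ID`` and window length ``L``; score the whole window ``a * L``;
    recurse on the sub-windows left and right of ``ID`` (the minimum's
    own index is excluded from both children, the only terminating
    reading).  Returns the best-scoring interval (ties: leftmost, then
    shortest) and every candidate visited.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or v.size == 0:
        raise ValueError("values must be a non-empty 1-D array")
    if np.any(v < 0):
        raise ValueError("values must be non-negative")
    candidates: list[ActivityInterval] = []
    stack = [(0, v.size)]
    while stack:
        lo, hi = stack.pop()
        if lo >= hi:
            continue
        seg = v[lo:hi]
        idx = int(np.argmin(seg))
        a = float(seg[idx])
        candidates.append(ActivityInterval(lo, hi, a * (hi - lo)))
        mid = lo + idx
        if mid > lo:
            stack.append((lo, mid))
        if mid + 1 < hi:
            stack.append((mid + 1, hi))
    best = max(
        candidates,
        key=lambda iv: (iv.score, -iv.start, -(iv.end - iv.start)),
    )
    return best, candidates


def segment_bursts(
    env: IEMGEnvelope,
    threshold_frac: float = 0.2,
    min_duration_s: float = 0.3,
    max_bursts: int = 1000,
) -> list[ActivityInterval]:
    """Enumerate movement bursts in an iEMG envelope.

    One pass of the :func:`best_interval` recursion visits a candidate
    window for every sub-interval between successive envelope minima; a
    candidate is acceptable when its minimum envelope level
    (score / length) reaches ``threshold_frac`` of the global envelope
    maximum and it lasts at least ``min_duration_s``.  Acceptable
    candidates are then selected greedily by score, skipping any that
    overlap an already-accepted burst (windows spanning several bursts
    fail the level threshold because of the low inter-burst baseline).
    Each accepted interval is finally widened to the contiguous
    above-threshold region containing it — the detected burst support.
    Output intervals are disjoint and sorted by start.
    """
    if len(env) == 0:
        return []
    global_max = float(env.values.max())
    if global_max <= 0:
        return []
    level_thr = threshold_frac * global_max
    min_len = max(1, int(round(min_duration_s * env.rate_hz)))
    _, candidates = best_interval(env.values)
    acceptable = [
        c
        for c in candidates
        if c.length >= min_len and c.score / c.length >= level_thr
    ]
    acceptable.sort(key=lambda iv: (-iv.score, iv.start, iv.end - iv.start))
    accepted: list[ActivityInterval] = []
    for cand in acceptable:
        if len(accepted) >= max_bursts:
            break
        if any(
            cand.start < acc.end and acc.start < cand.end for acc in accepted
        ):
            continue
        accepted.append(cand)
    accepted.sort(key=lambda iv: iv.start)

    # widen each accepted interval to its contiguous above-threshold support
    above = env.values >= level_thr
    widened: list[ActivityInterval] = []
    for j, iv in enumerate(accepted):
        start, end = iv.start, iv.end
        lo_bound = widened[-1].end if widened else 0
        hi_bound = accepted[j + 1].start if j + 1 < len(accepted) else len(env)
        while start > lo_bound and above[start - 1]:
            start -= 1
        while end < hi_bound and above[end]:
            end += 1
        length = end - start
        widened.append(
            ActivityInterval(start, end, float(env.values[start:end].min()) * length)
        )
    return widened


def extract_segment(
    rec: EMGRecording,
    iv: ActivityInterval,
    target_len: int = 200,
    normalize: bool = True,
) -> np.ndarray:
    """Resample one burst to a fixed-length classifier input.

    The segment ``rec.channels[start:end]`` is linearly interpolated at
    positions ``i * L / target_len`` (so a segment of exactly
    ``target_len`` samples passes through unchanged) and optionally
    z-normalized per channel.  Returns ``(target_len, n_channels)``.
    """
    if iv.end > len(rec) or iv.start < 0:
        raise ValueError(
            f"interval [{iv.start}, {iv.end}) outside recording of {len(rec)}"
        )
    L = iv.length
    if L < 2:
        raise ValueError("degenerate interval: need at least 2 samples")
    seg = rec.channels[iv.start : iv.end]
    pos = np.arange(target_len) * (L / target_len)
    out = np.empty((target_len, rec.n_channels))
    src_idx = np.arange(L, dtype=float)
    for c in range(rec.n_channels):
        out[:, c] = np.interp(pos, src_idx, seg[:, c])
    if normalize:
        mu = out.mean(axis=0)
        sd = out.std(axis=0)
        sd[sd == 0] = 1.0
        out = (out - mu) / sd
    return out
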