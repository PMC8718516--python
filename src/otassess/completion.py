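"""Movement-completion scoring: Pearson correlation, DTW, and the 0-3 rubric.

A patient's fused trajectory is warped against healthy reference motion
with dynamic time warping (to absorb uneven segmentation), correlated
per axis, and the mean correlation is mapped onto an ordinal completion
score:

====================  =====
correlation r         score
====================  =====
r >= 0.8              3
0.5 <= r < 0.8        2
0.3 <= r < 0.5        1
r < 0.3               0
====================  =====
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from otassess.fusion import FusedTrajectory

__all__ = [
    "AssessmentRecord",
    "ReferenceLibrary",
    "pearson_cc",
    "dtw_distance",
    "align_by_dtw",
    "completion_score",
    "assess_action",
    "strength_correlation",
]

ACTION_IDS = (1, 2, 3, 4)


@dataclass
class AssessmentRecord:
    """Per-action assessment outcome."""

    action_id: int
    cc: float
    dtw_distance: float
    score: int


@dataclass
class ReferenceLibrary:
    """Healthy-subject reference trajectories keyed by action id (1-4)."""

    references: dict[int, list[FusedTrajectory]] = field(default_factory=dict)

    def add(self, action_id: int, traj: FusedTrajectory) -> None:
        self.references.setdefault(int(action_id), []).append(traj)

    def get(self, action_id: int) -> list[FusedTrajectory]:
        refs = self.references.get(int(action_id), [])
        if not refs:
            raise KeyError(f"no reference trajectories for action {action_id}")
        return refs

    def validate(self) -> None:
        missing = [a for a in ACTION_IDS if not self.references.get(a)]
        if missing:
            raise ValueError(f"reference library missing actions {missing}")


def _as2d(x) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    if arr.ndim != 2:
        raise ValueError("series must be 1-D or 2-D (samples x axes)")
    return arr


def pearson_cc(x1, x2) -> float:
    """Pearson correlation coefficient of two equal-length series.

    ``cov(x1, x2) / sqrt(var(x1) var(x2))``.  For multi-axis input
    (``n x 3``), the coefficient is computed per axis and averaged.

    Raises
    ------
    ValueError
        If lengths differ, are shorter than 3 samples, or either series
        has zero variance on some axis (undefined correlation).
    """
    a = _as2d(x1)
    b = _as2d(x2)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    if a.shape[0] < 3:
        raise ValueError("need at least 3 samples")
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    va = (a**2).mean(axis=0)
    vb = (b**2).mean(axis=0)
    if np.any(va == 0) or np.any(vb == 0):
        bad = list(np.nonzero((va == 0) | (vb == 0))[0])
        raise ValueError(
            f"undefined correlation: zero variance on axis/axes {bad}"
        )
    r = (a * b).mean(axis=0) / np.sqrt(va * vb)
    return float(r.mean())


def _local_cost(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise local cost: |a-b| in 1-D, Euclidean distance in k-D."""
    diff = a[:, None, :] - b[None, :, :]
    if a.shape[1] == 1:
        return np.abs(diff[:, :, 0])
    return np.sqrt((diff**2).sum(axis=2))


def _dtw_matrix(cost: np.ndarray) -> np.ndarray:
    n, m = cost.shape
    D = np.full((n + 1, m + 1), np.inf)
    D[0, 0] = 0.0
    for i in range(1, n + 1):
        row = D[i]
        prev = D[i - 1]
        ci = cost[i - 1]
        for j in range(1, m + 1):
            row[j] = ci[j - 1] + min(prev[j], row[j - 1], prev[j - 1])
    return D[1:, 1:]


def _dtw_path(D: np.ndarray, cost: np.ndarray) -> list[tuple[int, int]]:
    i, j = D.shape[0] - 1, D.shape[1] - 1
    path = [(i, j)]
    while i > 0 or j > 0:
        if i == 0:
            j -= 1
        elif j == 0:
            i -= 1
        else:
            candidates = (
                (D[i - 1, j - 1], i - 1, j - 1),
                (D[i - 1, j], i - 1, j),
                (D[i, j - 1], i, j - 1),
            )
            _, i, j = min(candidates, key=lambda c: c[0])
        path.append((i, j))
    path.reverse()
    return path


def dtw_distance(x, y, return_path: bool = False):
    """Dynamic-time-warping distance between two series.

    Classic dynamic program with steps {(1,0), (0,1), (1,1)}, local cost
    ``|x_i - y_j|`` (1-D) or Euclidean distance (multi-axis), endpoints
    matched, cumulative cost returned un-normalized.

    Returns
    -------
    float, or (float, list of (i, j)) when ``return_path`` is true.
    """
    a = _as2d(x)
    b = _as2d(y)
    if a.shape[0] == 0 or b.shape[0] == 0:
        raise ValueError("empty input series")
    if a.shape[1] != b.shape[1]:
        raise ValueError("series dimensionality mismatch")
    cost = _local_cost(a, b)
    D = _dtw_matrix(cost)
    dist = float(D[-1, -1])
    if return_path:
        return dist, _dtw_path(D, cost)
    return dist


def align_by_dtw(x, y) -> tuple[np.ndarray, np.ndarray]:
    """Expand both series along the optimal warping path.

    Output series have equal length ``>= max(len(x), len(y))``; identical
    inputs come back unchanged.
    """
    a = _as2d(x)
    b = _as2d(y)
    _, path = dtw_distance(a, b, return_path=True)
    idx_a = np.array([p[0] for p in path])
    idx_b = np.array([p[1] for p in path])
    wa = a[idx_a]
    wb = b[idx_b]
    if np.asarray(x).ndim == 1:
        return wa[:, 0], wb[:, 0]
    return wa, wb


def completion_score(r: float, use_abs: bool = False) -> int:
    """Map a correlation coefficient onto the 0-3 completion rubric.

    With ``use_abs`` the magnitude |r| is thresholded instead of the
    signed value (the rubric's bottom band is phrased in terms of
    magnitude; the signed mapping is the default).
    """
    r = float(r)
    if not np.isfinite(r):
        raise ValueError(f"non-finite correlation: {r}")
    v = abs(r) if use_abs else r
    if v >= 0.8:
        return 3
    if v >= 0.5:
        return 2
    if v >= 0.3:
        return 1
    return 0


def assess_action(
    patient: FusedTrajectory,
    refs: ReferenceLibrary,
    action_id: int,
    use_abs: bool = False,
) -> AssessmentRecord:
    """Assess one action: DTW-align against each reference, average the
    correlations, attach the DTW distance to the nearest reference and
    the mapped completion score."""
    ref_list = refs.get(action_id)
    ccs = []
    dists = []
    for ref in ref_list:
        wr, wp = align_by_dtw(ref.coords, patient.coords)
        ccs.append(pearson_cc(wr, wp))
        dists.append(dtw_distance(ref.coords, patient.coords))
    cc = float(np.mean(ccs))
    return AssessmentRecord(
        action_id=int(action_id),
        cc=cc,
        dtw_distance=float(min(dists)),
        score=completion_score(cc, use_abs=use_abs),
    )


def strength_correlation(mean_ccs, grades) -> float:
    """Correlation between per-patient mean completion CCs and their
    muscle-strength grades."""
    cc = np.asarray(mean_ccs, dtype=float)
    g = np.asarray(grades, dtype=float)
    if cc.shape != g.shape or cc.ndim != 1:
        raise ValueError("mean_ccs and grades must be equal-length 1-D")
    if cc.size < 3:
        raise ValueError("need at least 3 patients")
    if np.all(g == g[0]):
        raise ValueError("grades are all equal: correlation undefined")
    return pearson_cc(cc, g)
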