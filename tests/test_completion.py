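import functools

import numpy as np
import pytest

from otassess import pipeline
from otassess.completion import (
    ReferenceLibrary,
    align_by_dtw,
    assess_action,
    completion_score,
    dtw_distance,
    pearson_cc,
    strength_correlation,
)
from otassess.fusion import FusedTrajectory
from otassess.synthetic import (
    SensorNoiseModel,
    SeverityProfile,
    generate_action_trajectory,
)

# ---------------------------------------------------------------------------
# oracles


def dtw_brute_force(x, y):
    """Exhaustive recursion over all admissible monotone warping paths."""
    x = tuple(np.atleast_1d(x))
    y = tuple(np.atleast_1d(y))

    @functools.lru_cache(maxsize=None)
    def rec(i, j):
        c = abs(x[i] - y[j])
        if i == 0 and j == 0:
            return c
        best = np.inf
        if i > 0:
            best = min(best, rec(i - 1, j))
        if j > 0:
            best = min(best, rec(i, j - 1))
        if i > 0 and j > 0:
            best = min(best, rec(i - 1, j - 1))
        return c + best

    return rec(len(x) - 1, len(y) - 1)


# two fixed 8-sample sequences; expected value frozen from the direct
# covariance / sqrt(var*var) formula computed independently
PEARSON_X1 = np.array([1.0, 2.0, 3.0, 5.0, 4.0, 6.0, 7.0, 9.0])
PEARSON_X2 = np.array([2.0, 1.0, 4.0, 4.0, 5.0, 7.0, 6.0, 8.0])
PEARSON_EXPECTED = 0.9165706857373312

# printed per-patient, per-action correlation table and the rubric scores
# its own mapping implies (patient 6 / action 3 = 0.83 maps to 3; the
# summary prose saying "2 throughout" contradicts the printed table)
TABLE5_CCS = {
    1: (0.67, 0.39, 0.84, 0.78),
    2: (0.60, 0.35, 0.61, 0.70),
    3: (0.67, 0.58, 0.71, 0.58),
    4: (0.80, 0.90, 0.90, 0.96),
    5: (0.67, 0.72, 0.69, 0.56),
    6: (0.68, 0.64, 0.83, 0.77),
    7: (0.60, 0.57, 0.70, 0.61),
    8: (0.68, 0.46, 0.65, 0.79),
    9: (0.72, 0.58, 0.71, 0.50),
}


# ---------------------------------------------------------------------------
# pearson_cc


def test_pearson_self_is_one():
    x = np.array([0.0, 1.0, 2.0, 5.0, 3.0])
    assert pearson_cc(x, x) == pytest.approx(1.0)


def test_pearson_negation_is_minus_one():
    x = np.array([0.0, 1.0, 2.0, 5.0, 3.0])
    assert pearson_cc(x, -x) == pytest.approx(-1.0)


def test_pearson_frozen_oracle():
    assert pearson_cc(PEARSON_X1, PEARSON_X2) == pytest.approx(
        PEARSON_EXPECTED, abs=1e-12
    )


def test_pearson_zero_variance_rejected():
    with pytest.raises(ValueError, match="zero variance"):
        pearson_cc(np.ones(5), np.arange(5.0))


def test_pearson_length_mismatch_rejected():
    with pytest.raises(ValueError, match="mismatch"):
        pearson_cc(np.arange(5.0), np.arange(6.0))


def test_pearson_multiaxis_is_mean_of_axes():
    rng = np.random.default_rng(0)
    a = rng.normal(size=(30, 3))
    b = rng.normal(size=(30, 3))
    per_axis = [pearson_cc(a[:, i], b[:, i]) for i in range(3)]
    assert pearson_cc(a, b) == pytest.approx(np.mean(per_axis))


# ---------------------------------------------------------------------------
# dtw_distance


def test_dtw_self_zero():
    x = np.array([1.0, 3.0, 2.0, 5.0])
    assert dtw_distance(x, x) == 0.0


def test_dtw_small_example_matches_brute_force():
    x = np.array([0.0, 1.0, 2.0])
    y = np.array([0.0, 1.0, 1.0, 2.0])
    assert dtw_distance(x, y) == pytest.approx(dtw_brute_force(x, y))


def test_dtw_symmetry_random_pairs():
    rng = np.random.default_rng(1)
    for _ in range(50):
        x = rng.normal(size=rng.integers(2, 12))
        y = rng.normal(size=rng.integers(2, 12))
        assert dtw_distance(x, y) == pytest.approx(dtw_distance(y, x))


def test_dtw_matches_exhaustive_battery():
    rng = np.random.default_rng(2)
    for _ in range(200):
        x = rng.integers(0, 5, size=rng.integers(1, 7)).astype(float)
        y = rng.integers(0, 5, size=rng.integers(1, 7)).astype(float)
        assert dtw_distance(x, y) == pytest.approx(dtw_brute_force(x, y))


def test_dtw_empty_rejected():
    with pytest.raises(ValueError, match="empty"):
        dtw_distance(np.array([]), np.array([1.0]))


def test_dtw_path_is_monotone_contiguous_endpoint_matched():
    rng = np.random.default_rng(3)
    x = rng.normal(size=15)
    y = rng.normal(size=9)
    _, path = dtw_distance(x, y, return_path=True)
    assert path[0] == (0, 0)
    assert path[-1] == (14, 8)
    for (i0, j0), (i1, j1) in zip(path, path[1:]):
        assert (i1 - i0, j1 - j0) in {(1, 0), (0, 1), (1, 1)}


# ---------------------------------------------------------------------------
# align_by_dtw


def test_align_identity_unchanged():
    x = np.array([0.0, 1.0, 2.0, 1.0])
    wa, wb = align_by_dtw(x, x)
    np.testing.assert_array_equal(wa, x)
    np.testing.assert_array_equal(wb, x)


def test_align_equal_lengths_at_least_max():
    x = np.arange(5.0)
    y = np.array([0.0, 0.0, 1.0, 2.0, 3.0, 4.0, 4.0])
    wa, wb = align_by_dtw(x, y)
    assert len(wa) == len(wb) >= max(len(x), len(y))


def test_align_improves_cc_on_shifted_pairs():
    rng = np.random.default_rng(4)
    wins = 0
    for _ in range(100):
        n = 60
        t = np.linspace(0, 1, n)
        shift = rng.uniform(0.05, 0.2)
        x = np.sin(2 * np.pi * (t + 0.1)) + 0.01 * rng.normal(size=n)
        m = int(n * (1 + rng.uniform(0, 0.3)))
        ty = np.linspace(0, 1, m)
        y = np.sin(2 * np.pi * (ty + 0.1 + shift)) + 0.01 * rng.normal(size=m)
        wa, wb = align_by_dtw(x, y)
        cc_warped = pearson_cc(wa, wb)
        y_resampled = np.interp(t, ty, y)
        cc_resampled = pearson_cc(x, y_resampled)
        if cc_warped >= cc_resampled:
            wins += 1
    assert wins > 50  # majority vote


# ---------------------------------------------------------------------------
# completion_score


@pytest.mark.parametrize(
    "r,expected",
    [
        (0.96, 3),
        (0.39, 1),
        (0.80, 3),
        (0.50, 2),
        (0.30, 1),
        (0.29, 0),
        (0.67, 2),
        (-0.5, 0),
    ],
)
def test_completion_score_values(r, expected):
    assert completion_score(r) == expected


def test_completion_score_abs_option():
    assert completion_score(-0.9, use_abs=True) == 3
    assert completion_score(-0.9, use_abs=False) == 0


def test_completion_score_nonfinite_rejected():
    with pytest.raises(ValueError):
        completion_score(float("nan"))


def test_completion_score_monotone_grid():
    grid = np.arange(0.3, 1.0001, 0.001)
    scores = [completion_score(r) for r in grid]
    assert all(s2 >= s1 for s1, s2 in zip(scores, scores[1:]))
    for r, s in zip(grid, scores):
        if r >= 0.8:
            assert s == 3
        elif r >= 0.5:
            assert s == 2
        else:
            assert s == 1


def test_table5_scores_reproduced():
    scores = {p: tuple(completion_score(r) for r in ccs) for p, ccs in TABLE5_CCS.items()}
    for p in (1, 2, 8):
        assert scores[p][1] == 1  # action 2
    assert scores[4] == (3, 3, 3, 3)
    for p in (3, 5, 7, 9):
        assert scores[p] == (2, 2, 2, 2)
    # patient 6: 2 on actions 1, 2, 4; the 0.83 on action 3 maps to 3
    assert scores[6][0] == scores[6][1] == scores[6][3] == 2
    assert scores[6][2] == 3


# ---------------------------------------------------------------------------
# assess_action / strength_correlation


def _fused(coords, rate=30.0):
    coords = np.asarray(coords, dtype=float)
    return FusedTrajectory(np.arange(coords.shape[0]) / rate, coords)


def test_assess_identity_perfect():
    rng = np.random.default_rng(5)
    coords = rng.normal(size=(50, 3)).cumsum(axis=0)
    refs = ReferenceLibrary()
    refs.add(2, _fused(coords))
    rec = assess_action(_fused(coords.copy()), refs, 2)
    assert rec.cc == pytest.approx(1.0)
    assert rec.score == 3
    assert rec.dtw_distance == 0.0


def test_assess_missing_reference_rejected():
    refs = ReferenceLibrary()
    with pytest.raises(KeyError):
        assess_action(_fused(np.random.default_rng(0).normal(size=(10, 3))), refs, 1)


def test_assess_grade3_below_identity(reference_library):
    na = SensorNoiseModel.kinect_like()
    nb = SensorNoiseModel.imu_like()
    a, b = generate_action_trajectory(1, SeverityProfile.from_grade(3), na, nb, 99)
    fused = pipeline.fuse_streams(a, b)
    rec = assess_action(fused, reference_library, 1)
    assert rec.cc < 1.0
    assert rec.score <= 3


def test_assess_time_reversal_degrades(reference_library):
    # action 4 is temporally asymmetric (lift, then translate right),
    # so a reversed stream cannot correlate like the forward one
    na = SensorNoiseModel.kinect_like()
    nb = SensorNoiseModel.imu_like()
    a, b = generate_action_trajectory(4, SeverityProfile.from_grade(5), na, nb, 123)
    fused = pipeline.fuse_streams(a, b)
    forward = assess_action(fused, reference_library, 4)
    rev = FusedTrajectory(fused.timestamps, fused.coords[::-1])
    backward = assess_action(rev, reference_library, 4)
    assert backward.cc < forward.cc - 0.2


def test_strength_correlation_monotone_positive():
    assert strength_correlation([0.4, 0.6, 0.9], [3, 4, 5]) > 0


def test_strength_correlation_equal_grades_rejected():
    with pytest.raises(ValueError, match="equal"):
        strength_correlation([0.4, 0.6, 0.9], [4, 4, 4])


def test_strength_correlation_needs_three():
    with pytest.raises(ValueError):
        strength_correlation([0.4, 0.6], [3, 4])
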