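"""Kinematic feature computation against independent hand/loop oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from safefall.errors import ConfigurationError, DataError
from safefall.features import (
    FEATURE_SETS,
    angle_to_origin,
    angular_rate,
    compute_features,
    nose_hip_ratio,
    read_features,
    select_features,
    write_features,
)
from safefall.io_keypoints import KeypointFrame, KeypointSequence


class TestAngleToOrigin:
    @pytest.mark.parametrize(
        "x, y, expected",
        [
            (1.0, 1.0, 0.7853981634),
            (1.0, 0.0, 0.0),
            (0.3, 0.4, 0.9272952180),  # arctan(4/3)
        ],
    )
    def test_reference_values(self, x, y, expected):
        assert angle_to_origin(x, y) == pytest.approx(expected, abs=1e-9)

    def test_limit_at_vanishing_x(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="safefall.features"):
            assert angle_to_origin(0.0, 0.4) == pytest.approx(math.pi / 2)
            assert angle_to_origin(1e-12, -0.4) == pytest.approx(-math.pi / 2)
        assert caplog.records


class TestAngularRate:
    def test_two_point_arithmetic(self):
        out = angular_rate([0.5, 0.6], [0.00, 0.05])
        assert out == pytest.approx([0.0, 2.0])

    def test_constant_angles_give_zero(self):
        out = angular_rate([0.3] * 7, np.arange(7) / 18)
        assert np.all(out == 0.0)

    def test_single_frame_convention(self):
        assert angular_rate([0.4], [0.0]) == pytest.approx([0.0])

    def test_non_increasing_times_rejected(self):
        with pytest.raises(DataError):
            angular_rate([0.1, 0.2], [0.1, 0.1])

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_matches_pairwise_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 10
        angles = rng.normal(size=n)
        times = np.cumsum(rng.uniform(0.02, 0.08, size=n))
        out = angular_rate(angles, times)
        expected = [0.0] + [
            (angles[k] - angles[k - 1]) / (times[k] - times[k - 1])
            for k in range(1, n)
        ]
        assert out == pytest.approx(expected, abs=1e-12)


class TestNoseHipRatio:
    @pytest.mark.parametrize(
        "n_y, lh_y, expected",
        [(0.5, 0.5, 1.0), (0.8, 0.4, 2.0), (0.2, 0.5, 0.4)],
    )
    def test_values(self, n_y, lh_y, expected):
        assert nose_hip_ratio(n_y, lh_y) == pytest.approx(expected)

    def test_standing_posture_below_one(self):
        # y grows toward the floor: a standing nose is above the hip
        assert nose_hip_ratio(0.2, 0.5) < 1.0

    def test_zero_hip_rejected(self):
        with pytest.raises(DataError):
            nose_hip_ratio(0.2, 0.0)


def _seq(points, dt=0.05, activity=7):
    """points: list of (N, LSh, LH) xy pairs."""
    frames = []
    for k, (n, lsh, lh) in enumerate(points):
        frames.append(
            KeypointFrame(
                t=k * dt, subject_id="S1", trial_id="T1", activity_id=activity,
                N_x=n[0], N_y=n[1], N_z=2.0,
                LSh_x=lsh[0], LSh_y=lsh[1], LSh_z=2.0,
                LH_x=lh[0], LH_y=lh[1], LH_z=2.0,
            )
        )
    return KeypointSequence(frames=frames)


class TestComputeFeatures:
    def test_single_frame_rates_are_zero(self, labels):
        rows = compute_features(_seq([((0.5, 0.2), (0.5, 0.3), (0.5, 0.6))]), labels)
        assert len(rows) == 1
        assert rows[0].dw_N == rows[0].dw_LSh == rows[0].dw_LH == 0.0

    def test_three_frame_hand_computation(self, labels):
        pts = [
            ((0.50, 0.20), (0.50, 0.30), (0.50, 0.60)),
            ((0.55, 0.25), (0.52, 0.32), (0.50, 0.60)),
            ((0.60, 0.35), (0.55, 0.38), (0.51, 0.61)),
        ]
        rows = compute_features(_seq(pts, dt=0.05), labels)
        # step-by-step hand computation of angle, rate and ratio
        a_n = [math.atan(y / x) for (x, y), _, _ in pts]
        a_lh = [math.atan(y / x) for _, _, (x, y) in pts]
        assert rows[1].dw_N == pytest.approx((a_n[1] - a_n[0]) / 0.05, rel=1e-12)
        assert rows[2].dw_N == pytest.approx((a_n[2] - a_n[1]) / 0.05, rel=1e-12)
        assert rows[2].dw_LH == pytest.approx((a_lh[2] - a_lh[1]) / 0.05, rel=1e-12)
        assert rows[0].R == pytest.approx(0.2 / 0.6, rel=1e-12)
        assert rows[2].R == pytest.approx(0.35 / 0.61, rel=1e-12)

    def test_row_count_matches_frames(self, labels):
        pts = [((0.5, 0.2), (0.5, 0.3), (0.5, 0.6))] * 9
        assert len(compute_features(_seq(pts), labels)) == 9

    def test_empty_sequence_gives_empty_list(self, labels):
        assert compute_features(KeypointSequence(frames=[]), labels) == []

    def test_unknown_activity_rejected(self):
        with pytest.raises(DataError):
            compute_features(_seq([((0.5, 0.2), (0.5, 0.3), (0.5, 0.6))]), {8: 0})

    def test_deterministic_bitwise(self, labels):
        rng = np.random.default_rng(5)
        pts = [
            (tuple(rng.uniform(0.2, 0.9, 2)), tuple(rng.uniform(0.2, 0.9, 2)),
             tuple(rng.uniform(0.2, 0.9, 2)))
            for _ in range(20)
        ]
        r1 = compute_features(_seq(pts), labels)
        r2 = compute_features(_seq(pts), labels)
        assert r1 == r2

    def test_matches_naive_per_frame_loop_oracle(self, labels):
        """100 random frames vs a literal re-implementation of the three
        per-frame formulas."""
        rng = np.random.default_rng(42)
        pts, times = [], []
        t = 0.0
        for _ in range(100):
            t += rng.uniform(0.04, 0.07)
            times.append(t)
            pts.append(
                (tuple(rng.uniform(0.1, 1.0, 2)), tuple(rng.uniform(0.1, 1.0, 2)),
                 tuple(rng.uniform(0.1, 1.0, 2)))
            )
        frames = [
            KeypointFrame(
                t=times[k], subject_id="S1", trial_id="T1", activity_id=1,
                N_x=pts[k][0][0], N_y=pts[k][0][1], N_z=0.0,
                LSh_x=pts[k][1][0], LSh_y=pts[k][1][1], LSh_z=0.0,
                LH_x=pts[k][2][0], LH_y=pts[k][2][1], LH_z=0.0,
            )
            for k in range(100)
        ]
        rows = compute_features(KeypointSequence(frames=frames), labels)
        prev = None
        for k, row in enumerate(rows):
            (nx, ny), (sx, sy), (hx, hy) = pts[k]
            an, asx, ah = math.atan(ny / nx), math.atan(sy / sx), math.atan(hy / hx)
            if k == 0:
                exp = (0.0, 0.0, 0.0)
            else:
                dt = times[k] - times[k - 1]
                exp = ((an - prev[0]) / dt, (asx - prev[1]) / dt, (ah - prev[2]) / dt)
            assert abs(row.dw_N - exp[0]) < 1e-12
            assert abs(row.dw_LSh - exp[1]) < 1e-12
            assert abs(row.dw_LH - exp[2]) < 1e-12
            assert abs(row.R - ny / hy) < 1e-12
            assert abs(row.A_N - an) < 1e-12
            prev = (an, asx, ah)

    def test_ratio_crosses_one_exactly_at_equal_heights(self, labels):
        pts = [
            ((0.5, 0.30), (0.5, 0.4), (0.5, 0.6)),
            ((0.5, 0.60), (0.5, 0.6), (0.5, 0.6)),
            ((0.5, 0.75), (0.5, 0.7), (0.5, 0.6)),
        ]
        rows = compute_features(_seq(pts), labels)
        assert rows[0].R < 1.0
        assert rows[1].R == pytest.approx(1.0, abs=1e-12)
        assert rows[2].R > 1.0


class TestSelectFeatures:
    @pytest.fixture()
    def rows(self, feature_rows_factory, noiseless_cfg):
        return feature_rows_factory("bend_intentional", noiseless_cfg, seed=1)

    @pytest.mark.parametrize("name, m", [("4p", 4), ("5p", 5), ("6p", 6)])
    def test_column_counts(self, rows, name, m):
        assert FEATURE_SETS[name].m == m
        assert select_features(rows, name).shape == (len(rows), m)

    def test_5p_equals_6p_without_ratio_column(self, rows):
        five = select_features(rows, "5p")
        six = select_features(rows, "6p")
        assert np.array_equal(five, six[:, :5])

    def test_4p_column_order(self, rows):
        four = select_features(rows, "4p")
        assert np.array_equal(four[:, 0], [r.N_x for r in rows])
        assert np.array_equal(four[:, 2], [r.dw_N for r in rows])
        assert np.array_equal(four[:, 3], [r.R for r in rows])

    def test_unknown_set_rejected(self, rows):
        with pytest.raises(ConfigurationError):
            select_features(rows, "7p")


def test_feature_csv_round_trip(tmp_path, feature_rows_factory, noiseless_cfg):
    rows = feature_rows_factory("fall_forward", noiseless_cfg, seed=2)
    p = write_features(rows, tmp_path / "feat.csv")
    back = read_features(p)
    assert len(back) == len(rows)
    for a, b in zip(rows, back):
        for col in ("t", "N_x", "N_y", "dw_N", "dw_LSh", "dw_LH", "R"):
            assert getattr(b, col) == pytest.approx(getattr(a, col), rel=1e-8)
        assert (b.subject_id, b.trial_id, b.label) == (a.subject_id, a.trial_id, a.label)
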