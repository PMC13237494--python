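import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from quadturn.gait_analysis import (
    classify_stability,
    debounce_events,
    duty_factors,
    footfall_diagram,
    menger_curvature,
    stride_curvatures,
)


def circumcircle_oracle(p1, p2, p3):
    """Curvature magnitude via an explicit circumcenter solve."""
    A = 2 * np.array([
        [p2[0] - p1[0], p2[1] - p1[1]],
        [p3[0] - p1[0], p3[1] - p1[1]],
    ])
    b = np.array([
        p2 @ p2 - p1 @ p1,
        p3 @ p3 - p1 @ p1,
    ])
    center = np.linalg.solve(A, b)
    return 1.0 / np.hypot(*(np.asarray(p1) - center))


def synthetic_log(period=1.0, duty=0.7, n=6, phases=(0.0, 0.5, 0.25, 0.75)):
    rows = []
    for limb, ph in zip([1, 2, 3, 4], phases):
        for k in range(n):
            t0 = (k + ph) * period
            rows.append({"t": t0, "limb": limb, "kind": "touchdown",
                         "x": 0.0, "y": 0.0, "com_x": 0.0, "com_y": 0.0})
            rows.append({"t": t0 + duty * period, "limb": limb,
                         "kind": "liftoff_extension",
                         "x": 0.0, "y": 0.0, "com_x": 0.0, "com_y": 0.0})
    return pd.DataFrame(rows).sort_values("t").reset_index(drop=True)


class TestMengerCurvature:
    def test_clockwise_unit_triple(self):
        k = menger_curvature((0, 0), (1, 1), (2, 0))
        assert k == pytest.approx(-1.0)

    def test_collinear_is_zero(self):
        assert menger_curvature((0, 0), (1, 0), (2, 0)) == 0.0

    def test_circle_radius_four_counter_clockwise(self):
        ang = [0.2, 1.1, 2.5]
        pts = [(4 * math.cos(a), 4 * math.sin(a)) for a in ang]
        assert menger_curvature(*pts) == pytest.approx(0.25)

    def test_coincident_points_rejected(self):
        with pytest.raises(ValueError):
            menger_curvature((1, 1), (1, 1), (2, 0))

    @given(st.lists(st.floats(-20, 20), min_size=6, max_size=6))
    @settings(max_examples=200, deadline=None)
    def test_matches_circumcenter_oracle(self, coords):
        pts = np.array(coords).reshape(3, 2)
        u, v = pts[1] - pts[0], pts[2] - pts[0]
        if abs(u[0] * v[1] - u[1] * v[0]) < 1e-3:  # skip degenerate triples
            return
        k = menger_curvature(*pts)
        assert abs(k) == pytest.approx(circumcircle_oracle(*pts), abs=1e-10)

    @given(st.lists(st.floats(-20, 20), min_size=6, max_size=6))
    @settings(max_examples=100, deadline=None)
    def test_sign_flips_under_reflection(self, coords):
        pts = np.array(coords).reshape(3, 2)
        u, v = pts[1] - pts[0], pts[2] - pts[0]
        if abs(u[0] * v[1] - u[1] * v[0]) < 1e-3:
            return
        mirrored = pts * np.array([1, -1])
        assert menger_curvature(*pts) == pytest.approx(
            -menger_curvature(*mirrored), rel=1e-12
        )


class TestStrideCurvatures:
    def test_straight_line_touchdowns(self):
        pts = np.c_[np.arange(20.0), np.arange(20.0) * 2.0, np.zeros(20)]
        records, kappa = stride_curvatures(pts, n_discard=5)
        assert kappa == pytest.approx(0.0, abs=1e-12)
        assert len(records) == 18

    def test_left_handed_circle_of_radius_ten(self):
        th = np.linspace(0, 2.2, 18)
        pts = np.c_[th, 10 * np.cos(th), 10 * np.sin(th)]
        _, kappa = stride_curvatures(pts, n_discard=3)
        assert kappa == pytest.approx(0.1)

    def test_spiral_transient_converges_to_limit_circle(self):
        # radius decays toward 8 cm; median after discards is the limit
        th = np.linspace(0, 6.0, 40)
        r = 8.0 + 6.0 * np.exp(-2.0 * th)
        pts = np.c_[th, r * np.cos(th), r * np.sin(th)]
        _, kappa = stride_curvatures(pts, n_discard=10)
        assert kappa == pytest.approx(1 / 8.0, rel=0.01)

    def test_too_few_touchdowns(self):
        pts = np.zeros((7, 3))
        pts[:, 0] = np.arange(7)
        with pytest.raises(ValueError, match="insufficient_strides"):
            stride_curvatures(pts, n_discard=10)


class TestDutyFactors:
    def test_symmetric_log_unit_ratios(self):
        # window spans whole cycles of every limb and has prior events
        ev = synthetic_log(duty=0.7)
        duty, fore, hind = duty_factors(ev, (1.0, 5.0))
        for v in duty.values():
            assert v == pytest.approx(0.7)
        assert fore == pytest.approx(1.0)
        assert hind == pytest.approx(1.0)

    def test_asymmetric_fore_ratio(self):
        ev = synthetic_log(duty=0.6)
        inner = synthetic_log(duty=0.75)
        ev.loc[ev["limb"] == 1, "t"] = inner[inner["limb"] == 1]["t"].to_numpy()
        ev.loc[ev["limb"] == 1, "kind"] = inner[inner["limb"] == 1]["kind"].to_numpy()
        duty, fore, _ = duty_factors(ev, (1.0, 5.0))
        assert fore == pytest.approx(0.75 / 0.6)

    def test_turn_direction_resolves_inner_side(self):
        ev = synthetic_log(duty=0.6)
        inner = synthetic_log(duty=0.75)
        ev.loc[ev["limb"] == 1, "t"] = inner[inner["limb"] == 1]["t"].to_numpy()
        _, fore_left, _ = duty_factors(ev, (1.0, 5.0), turn="left")
        _, fore_right, _ = duty_factors(ev, (1.0, 5.0), turn="right")
        assert fore_left == pytest.approx(1 / fore_right)

    def test_incomplete_cycles_rejected(self):
        ev = synthetic_log(n=2)
        with pytest.raises(ValueError):
            duty_factors(ev, (0.0, 2.0))


class TestFootfallDiagram:
    def test_symmetric_log_no_left_swing_overlap(self):
        ev = synthetic_log(duty=0.7, phases=(0.0, 0.5, 0.5, 0.0))
        table, overlap = footfall_diagram(ev, (1.0, 5.0))
        assert overlap == 0.0
        assert list(table["limb"].unique()) == ["RH", "LH", "RF", "LF"]

    def test_synchronous_left_limbs_overlap_fully_in_swing(self):
        ev = synthetic_log(duty=0.6, phases=(0.0, 0.5, 0.0, 0.5))
        _, overlap = footfall_diagram(ev, (1.0, 5.0))
        assert overlap == pytest.approx(0.4, abs=0.01)

    def test_empty_window_empty_table(self):
        ev = synthetic_log()
        table, overlap = footfall_diagram(ev.iloc[0:0], (0.0, 1.0))
        # with no events every limb is one full-window stance interval
        assert (table["phase"] == "stance").all()
        assert overlap == 0.0


class TestDebounce:
    def test_bounce_pair_removed(self):
        ev = synthetic_log()
        bounce = pd.DataFrame([
            {"t": 2.71, "limb": 1, "kind": "touchdown",
             "x": 0, "y": 0, "com_x": 0, "com_y": 0},
            {"t": 2.715, "limb": 1, "kind": "liftoff_unload",
             "x": 0, "y": 0, "com_x": 0, "com_y": 0},
        ])
        noisy = pd.concat([ev, bounce]).sort_values("t")
        clean = debounce_events(noisy, window=0.02)
        assert len(clean) == len(ev)
        # the raw-event duty factor is itself nearly immune to the bounce
        duty, fore, hind = duty_factors(noisy, (1.0, 5.0))
        assert fore == pytest.approx(1.0, abs=0.005)

    def test_real_transitions_preserved(self):
        ev = synthetic_log()
        clean = debounce_events(ev, window=0.02)
        pd.testing.assert_frame_equal(
            clean.reset_index(drop=True)[["t", "limb", "kind"]],
            ev.reset_index(drop=True)[["t", "limb", "kind"]],
        )


class TestClassifyStability:
    def test_abnormal_termination_is_unstable(self):
        stab, mode = classify_stability("support_lost")
        assert stab == "unstable" and mode == "support_lost"

    def test_tight_curvatures_stable(self):
        stab, mode = classify_stability("completed", [0.1, 0.101, 0.099, 0.1])
        assert stab == "stable" and mode is None

    def test_scattered_curvatures_non_convergent(self):
        stab, mode = classify_stability("completed", [0.1, 0.25, -0.05, 0.3])
        assert stab == "unstable" and mode == "non_convergent"

    def test_near_zero_curvature_noise_tolerated(self):
        # straight walking: tiny absolute scatter must not trip the CV test
        stab, _ = classify_stability("completed", [1e-4, -1e-4, 5e-5, -2e-5])
        assert stab == "stable"

    def test_order_independent(self):
        vals = [0.1, 0.12, 0.11, 0.09, 0.1]
        assert classify_stability("completed", vals) == classify_stability(
            "completed", list(reversed(vals))
        )
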