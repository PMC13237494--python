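import math

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from quadturn.body_mechanics import BodyState, LimbId, PawState
from quadturn.load_solver import (
    TwoLimbGeometry,
    com_height_rate,
    pendulum_force,
    solve_four_limb,
    solve_loads,
    solve_three_limb,
    solve_two_limb,
    two_limb_geometry,
)

MG = 25.0 * 1000.0


def make_paws(contacts, phases):
    paws = []
    for limb, c, ph in zip(LimbId, contacts, phases):
        paws.append(PawState(limb=limb, phase=ph, contact=np.array(c, dtype=float)))
    return paws


class TestDispatch:
    def test_rectangle_four_limb_even_split(self, params):
        state = BodyState(rc=np.zeros(2))
        paws = make_paws([(5, 1), (5, -1), (-5, 1), (-5, -1)], ["stance"] * 4)
        dist = solve_loads(state, paws, params)
        assert dist.mode == "four"
        np.testing.assert_allclose(dist.loads, MG / 4)
        assert dist.admissible

    def test_com_on_hind_line_unloads_the_fore_pair(self, params):
        state = BodyState(rc=np.zeros(2))
        paws = make_paws([(5, 1), (5, -1), (0, 1), (0, -1)], ["stance"] * 4)
        dist = solve_loads(state, paws, params)
        np.testing.assert_allclose(dist.loads[:2], 0.0, atol=1e-9)
        np.testing.assert_allclose(dist.loads[2:], MG / 2, atol=1e-6)

    def test_single_stance_limb_is_degenerate(self, params):
        state = BodyState()
        paws = make_paws([(5, 1)] * 4, ["stance", "swing", "swing", "swing"])
        dist = solve_loads(state, paws, params)
        assert dist.mode == "degenerate"
        assert not dist.admissible

    def test_swing_limbs_carry_exactly_zero(self, params):
        state = BodyState(rc=np.array([1.0, 0.0]))
        paws = make_paws(
            [(5, 1), (5, -1), (0, 1), (0, -1)],
            ["stance", "swing", "stance", "stance"],
        )
        dist = solve_loads(state, paws, params)
        assert dist.loads[1] == 0.0
        assert dist.mode == "three"


class TestThreeLimb:
    def test_equilateral_centroid_shares_equally(self, params):
        ang = np.array([0.0, 2 * math.pi / 3, 4 * math.pi / 3])
        contacts = np.c_[np.cos(ang), np.sin(ang)]
        dist = solve_three_limb(contacts, contacts.mean(axis=0), params)
        np.testing.assert_allclose(dist.loads, MG / 3, rtol=1e-12)

    def test_com_on_edge_zeroes_the_opposite_limb(self, params):
        contacts = np.array([[0, 0], [4, 0], [0, 6]], dtype=float)
        com = np.array([2.0, 3.0])  # midpoint of the edge (4,0)-(0,6)
        dist = solve_three_limb(contacts, com, params)
        assert dist.loads[0] == pytest.approx(0.0, abs=1e-9)

    def test_matches_barycentric_oracle(self, params, rng):
        """Loads are the barycentric coordinates of the COM scaled by mg."""
        for _ in range(300):
            contacts = rng.uniform(-6, 6, size=(3, 2))
            if abs(np.linalg.det(np.c_[contacts[1:] - contacts[0]])) < 0.5:
                continue
            w = rng.dirichlet(np.ones(3))
            com = w @ contacts
            A = np.vstack([contacts.T, np.ones(3)])
            oracle = np.linalg.solve(A, np.array([*com, 1.0])) * MG
            dist = solve_three_limb(contacts, com, params)
            np.testing.assert_allclose(dist.loads, oracle, rtol=1e-9, atol=1e-6)
            assert dist.admissible

    def test_collinear_contacts_degenerate(self, params):
        contacts = np.array([[0, 0], [1, 0], [2, 0]], dtype=float)
        dist = solve_three_limb(contacts, np.array([1.0, 0.0]), params)
        assert dist.mode == "degenerate"


class TestFourLimb:
    def test_shifted_com_loads_the_near_pair_more(self, params):
        contacts = np.array([[5, 1], [5, -1], [-5, 1], [-5, -1]], dtype=float)
        dist = solve_four_limb(contacts, np.array([2.5, 0.0]), params)
        assert dist.loads[0] > dist.loads[2]
        assert dist.admissible

    def test_matches_minimum_norm_oracle(self, params, rng):
        """KKT closed form equals the lstsq minimum-norm solution."""
        checked = 0
        while checked < 300:
            contacts = rng.uniform(-6, 6, size=(4, 2))
            w = rng.dirichlet(np.ones(4))
            com = w @ contacts
            A = np.vstack([(contacts - com).T, np.ones(4)])
            if np.linalg.matrix_rank(A) < 3:
                continue
            oracle = np.linalg.lstsq(A, np.array([0, 0, MG]), rcond=None)[0]
            dist = solve_four_limb(contacts, com, params)
            np.testing.assert_allclose(dist.loads, oracle, rtol=1e-8, atol=1e-6)
            checked += 1

    def test_balance_residuals_tiny(self, params, rng):
        for _ in range(100):
            contacts = rng.uniform(-6, 6, size=(4, 2))
            com = rng.dirichlet(np.ones(4)) @ contacts
            dist = solve_four_limb(contacts, com, params)
            if dist.mode == "degenerate":
                continue
            lever = contacts - com
            assert abs(dist.total - MG) < 1e-8 * MG
            assert abs(dist.loads @ lever[:, 0]) < 1e-8 * MG
            assert abs(dist.loads @ lever[:, 1]) < 1e-8 * MG

    def test_com_outside_hull_inadmissible(self, params):
        contacts = np.array([[5, 1], [5, -1], [-5, 1], [-5, -1]], dtype=float)
        dist = solve_four_limb(contacts, np.array([7.0, 0.0]), params)
        assert (dist.loads < 0).any()
        assert not dist.admissible

    def test_vanishing_load_converges_to_three_limb_solution(self, params):
        """Continuity at the four/three-limb mode boundary."""
        contacts = np.array([[4, 1], [5, -2], [-4, 2], [-5, -1]], dtype=float)

        def last_load(x):
            return solve_four_limb(contacts, np.array([x, 0.0]), params).loads[3]

        lo, hi = 0.0, 3.9
        assert last_load(lo) > 0 > last_load(hi)
        for _ in range(80):
            mid = (lo + hi) / 2
            if last_load(mid) > 0:
                lo = mid
            else:
                hi = mid
        com = np.array([(lo + hi) / 2, 0.0])
        four = solve_four_limb(contacts, com, params)
        three = solve_three_limb(contacts[:3], com, params)
        np.testing.assert_allclose(four.loads[:3], three.loads, atol=1e-6)


class TestTwoLimb:
    @staticmethod
    def geom(p_a, p_b, com, vc, hc=3.0):
        state = BodyState(rc=np.asarray(com, float), vc=np.asarray(vc, float), hc=hc)
        a = PawState(LimbId.RF, contact=np.asarray(p_a, float))
        b = PawState(LimbId.LH, contact=np.asarray(p_b, float))
        return two_limb_geometry(state, a, b)

    def test_symmetric_lever_arms_split_half_weight(self, params):
        g = self.geom((0, 2), (0, -2), (0, 0), (0, 0))
        dist = solve_two_limb(g, params)
        np.testing.assert_allclose(dist.loads, MG / 2)

    def test_lever_rule_two_to_one(self, params):
        # COM projection twice as far from paw a as from paw b
        g = self.geom((0, 2), (0, -1), (0, 0), (0, 0))
        dist = solve_two_limb(g, params)
        assert dist.loads[1] == pytest.approx(2 * dist.loads[0])
        assert dist.loads[0] == pytest.approx(MG / 3)

    def test_centripetal_speed_cancels_total_load(self, params):
        vp = math.sqrt(params.grav * params.H)
        g = self.geom((0, 2), (0, -2), (0, 0), (vp, 0))
        dist = solve_two_limb(g, params)
        assert dist.total == pytest.approx(0.0, abs=1e-6)

    def test_equations_hold_exactly_off_axis(self, params, rng):
        for _ in range(50):
            pa, pb = rng.uniform(-4, 4, size=(2, 2))
            if np.hypot(*(pb - pa)) < 0.5:
                continue
            com = rng.uniform(-3, 3, size=2)
            vc = rng.uniform(-10, 10, size=2)
            g = self.geom(pa, pb, com, vc, hc=2.5)
            dist = solve_two_limb(g, params)
            total = params.m * params.grav * math.cos(g.phi) - params.m * g.vp**2 / params.H
            assert dist.total == pytest.approx(total, rel=1e-12)
            assert dist.loads[0] * g.s2 == pytest.approx(dist.loads[1] * g.s3, abs=1e-6)

    def test_total_load_decreases_with_tilt(self, params):
        totals = []
        for z in [0.0, 0.5, 1.0, 1.5]:
            g = self.geom((0, 2), (0, -2), (z, 0), (0, 0))
            totals.append(solve_two_limb(g, params).total)
        assert all(b < a for a, b in zip(totals, totals[1:]))


class TestPendulumAndHeight:
    def test_pendulum_magnitude_and_direction(self, params):
        g = TestTwoLimb.geom((0, 2), (0, -2), (0.6, 0.0), (0, 0))
        f = pendulum_force(g, params)
        assert np.hypot(*f) == pytest.approx(25 * 1000 * 0.6 / 3.0)
        # points from the support line (the y-axis) toward the COM (+x)
        assert f[0] > 0 and f[1] == pytest.approx(0.0, abs=1e-12)

    def test_pendulum_zero_above_line(self, params):
        g = TestTwoLimb.geom((0, 2), (0, -2), (0.0, 0.5), (0, 0))
        np.testing.assert_allclose(pendulum_force(g, params), [0, 0], atol=1e-12)

    def test_height_rate_examples(self):
        assert com_height_rate(0.0, 3.0, 5.0) == 0.0
        assert com_height_rate(1.0, 3.0, 3.0) == pytest.approx(-1.0)
        with pytest.raises(ValueError):
            com_height_rate(1.0, 0.0, 1.0)

    def test_height_flow_preserves_pendulum_arm(self):
        """Integrating dz/dt = vp, dhc/dt = -(z/hc) vp keeps R constant."""

        def rhs(t, y):
            z, hc = y
            vp = 2.0 * math.cos(3 * t)
            return [vp, com_height_rate(z, hc, vp)]

        sol = solve_ivp(rhs, (0, 1.0), [0.5, 3.0], rtol=1e-10, atol=1e-12,
                        dense_output=True)
        R0 = math.hypot(0.5, 3.0)
        R = np.hypot(sol.y[0], sol.y[1])
        np.testing.assert_allclose(R, R0, rtol=1e-8)
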