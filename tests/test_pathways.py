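"""Potential fields, steepest-descent growth and cubic smoothing."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import acnsim as a
from acnsim.pathways import (
    NEIGHBOR_OFFSETS,
    GrowthError,
    Pathway,
    SplitRequired,
    TrappedPathwayError,
    network_from_json,
    network_to_json,
)


class TestRootPotential:
    def test_zero_at_root_and_hand_value(self):
        root = (40, 40)
        assert a.root_potential(root, root, 100.0) == 0.0
        # distance 16: (16^2)^(1/4) = 4, times alpha = 100
        assert a.root_potential((56, 40), root, 100.0) == pytest.approx(400.0)

    def test_radial_symmetry(self):
        root = (10, 20)
        v1 = a.root_potential((10 + 5, 20), root, 100.0)
        v2 = a.root_potential((10, 20 - 5), root, 100.0)
        v3 = a.root_potential((10 + 3, 20 + 4), root, 100.0)
        assert v1 == pytest.approx(v2) == pytest.approx(v3)

    def test_strictly_increasing_along_rays(self):
        root = (0, 0)
        for direction in [(1, 0), (0, 1), (1, 1), (2, 1)]:
            pts = np.array([(k * direction[0], k * direction[1]) for k in range(1, 30)])
            vals = a.root_potential(pts, root, 50.0)
            assert np.all(np.diff(vals) > 0)

    def test_rejects_nonpositive_alpha(self):
        with pytest.raises(ValueError):
            a.root_potential((0, 0), (1, 1), -1.0)


class TestPathwayPotential:
    PW = Pathway(1, [(5, 5)], ("root", None))

    def test_hand_value_single_point(self):
        # beta * (d^2)^(gamma/2) = -20 * 4^(-1/2) = -10 at distance 2
        assert a.pathway_potential((7, 5), self.PW, -20.0, -1.0) == pytest.approx(-10.0)

    def test_negative_and_decaying(self):
        near = a.pathway_potential((7, 5), self.PW, -20.0, -1.0)
        far = a.pathway_potential((55, 5), self.PW, -20.0, -1.0)
        assert near < far < 0.0

    def test_two_points_at_same_distance_double(self):
        pw2 = Pathway(1, [(5, 5), (9, 5)], ("root", None))
        single = a.pathway_potential((7, 9), Pathway(1, [(5, 5)], ("root", None)), -20.0, -1.0)
        # (7, 9) is at distance sqrt(20) from both (5,5) and (9,5)
        both = a.pathway_potential((7, 9), pw2, -20.0, -1.0)
        assert both == pytest.approx(2 * single)

    def test_finite_on_the_pathway_itself(self):
        v = a.pathway_potential((5, 5), self.PW, -20.0, -1.0)
        assert np.isfinite(v) and v < 0


class TestTotalPotential:
    def test_no_pathways_equals_root_potential(self, small_domain):
        root = (0, 0)
        field = a.total_potential(small_domain, root, [], a.PotentialParams())
        ys, xs = np.mgrid[0:64, 0:64]
        expected = a.root_potential(
            np.stack([xs, ys], axis=-1), root, 100.0
        )
        np.testing.assert_allclose(field.values, expected)

    def test_pathway_lowers_field_everywhere_and_adds_linearly(self, small_domain):
        root = (0, 0)
        params = a.PotentialParams()
        pw = Pathway(1, [(30, 30), (29, 29)], ("root", None))
        base = a.total_potential(small_domain, root, [], params)
        with_pw = a.total_potential(small_domain, root, [pw], params)
        assert np.all(with_pw.values < base.values)
        # additivity: total minus root field is exactly the pathway term
        diff = with_pw.values - base.values
        pw2 = a.total_potential(small_domain, root, [pw, pw], params)
        np.testing.assert_allclose(pw2.values, base.values + 2 * diff, rtol=1e-12)


class TestSteepestDescent:
    def test_moves_toward_root_on_pure_root_field(self, small_domain):
        root = (10, 30)
        field = a.total_potential(small_domain, root, [], a.PotentialParams())
        nxt = a.steepest_descent_step(field, (20, 30))
        assert nxt == (19, 30)

    def test_matches_brute_force_neighbor_minimum(self, small_domain, rng):
        values = rng.random((64, 64))
        field = a.PotentialField(small_domain, values)
        for _ in range(50):
            cx, cy = int(rng.integers(1, 63)), int(rng.integers(1, 63))
            # oracle: enumerate the 8 neighbors in the documented order
            best, best_v = None, np.inf
            for dx, dy in NEIGHBOR_OFFSETS:
                v = values[cy + dy, cx + dx]
                if v < best_v:
                    best, best_v = (cx + dx, cy + dy), v
            if best_v <= values[cy, cx]:
                assert a.steepest_descent_step(field, (cx, cy)) == best
            else:
                with pytest.raises(TrappedPathwayError):
                    a.steepest_descent_step(field, (cx, cy))

    def test_tie_breaks_by_fixed_order(self, small_domain):
        values = np.full((64, 64), 5.0)
        values[30, 33] = 1.0  # E of (32, 30)
        values[29, 33] = 1.0  # NE of (32, 30): same value, E must win
        field = a.PotentialField(small_domain, values)
        assert a.steepest_descent_step(field, (32, 30)) == (33, 30)

    def test_trapped_at_local_minimum(self, small_domain):
        values = np.full((64, 64), 5.0)
        values[30, 32] = 0.0
        field = a.PotentialField(small_domain, values)
        with pytest.raises(TrappedPathwayError):
            a.steepest_descent_step(field, (32, 30))

    def test_excludes_previous_point(self, small_domain):
        values = np.full((64, 64), 5.0)
        values[30, 31] = 0.0  # W neighbor is lowest but is the previous point
        values[30, 33] = 2.0
        field = a.PotentialField(small_domain, values)
        assert a.steepest_descent_step(field, (32, 30), previous=(31, 30)) == (33, 30)


class TestGrowPathway:
    def test_reaches_root_without_existing_pathways(self, small_domain):
        root = (0, 32)
        field = a.total_potential(small_domain, root, [], a.PotentialParams())
        pw = a.grow_pathway(field, (40, 32), root, [])
        assert pw.terminus == ("root", None)
        assert pw.points[-1] == root
        pw.validate()

    def test_potential_nonincreasing_along_pathway(self, small_domain):
        root = (0, 32)
        field = a.total_potential(small_domain, root, [], a.PotentialParams())
        pw = a.grow_pathway(field, (50, 10), root, [])
        vals = [field.values[y, x] for x, y in pw.points]
        assert np.all(np.diff(vals) <= 1e-12)

    def test_attaches_to_adjacent_existing_pathway(self, small_domain):
        root = (0, 32)
        params = a.PotentialParams()
        field = a.total_potential(small_domain, root, [], params)
        first = a.grow_pathway(field, (40, 32), root, [], label=1)
        field2 = a.total_potential(small_domain, root, [first], params)
        # start one pixel off a mid point of the first pathway
        mid = first.points[len(first.points) // 2]
        start = (mid[0] + 1, mid[1] + 1)
        second = a.grow_pathway(field2, start, root, [first], label=2)
        assert second.terminus[0] == "attached"
        assert second.terminus[1][0] == 1

    def test_start_at_root_rejected(self, small_domain):
        root = (0, 32)
        field = a.total_potential(small_domain, root, [], a.PotentialParams())
        with pytest.raises(ValueError):
            a.grow_pathway(field, root, root, [])

    def test_step_budget_raises_growth_error(self, small_domain):
        root = (0, 32)
        field = a.total_potential(small_domain, root, [], a.PotentialParams())
        with pytest.raises(GrowthError):
            a.grow_pathway(field, (60, 60), root, [], max_steps=3)


class TestBuildNetwork:
    def test_single_endpoint_reaches_root(self, small_domain):
        net = a.build_network(small_domain, 1, seed=5)
        assert len(net.pathways) == 1
        assert net.pathways[0].terminus == ("root", None)

    @pytest.mark.parametrize("seed", range(8))
    def test_every_pathway_terminates_at_root_or_earlier(self, small_domain, seed):
        net = a.build_network(small_domain, 4, seed=seed)
        assert net.domain.on_boundary(net.root)
        for pw in net.pathways:
            pw.validate()
            kind, info = pw.terminus
            if kind == "root":
                assert pw.points[-1] == net.root
            else:
                assert kind == "attached"
                assert info[0] < pw.label

    def test_end_points_respect_margin(self, small_domain):
        net = a.build_network(small_domain, 4, seed=1, margin=10)
        for x, y in net.end_points:
            assert 10 <= x < 54 and 10 <= y < 54

    def test_same_seed_bit_identical(self, small_domain):
        n1 = a.build_network(small_domain, 4, seed=9)
        n2 = a.build_network(small_domain, 4, seed=9)
        assert network_to_json(n1) == network_to_json(n2)

    def test_json_round_trip(self, network):
        restored = network_from_json(network_to_json(network))
        assert restored.root == network.root
        assert [p.points for p in restored.pathways] == [
            p.points for p in network.pathways
        ]
        for c1, c2 in zip(restored.smoothed, network.smoothed):
            np.testing.assert_allclose(c1, c2)


class TestFitCubic:
    def test_line_through_origin(self):
        pts = [(0, 0), (1, 1), (2, 2), (3, 3)]
        fit = a.fit_cubic(pts, "y_of_x")
        assert fit.coeffs == pytest.approx((0.0, 1.0, 0.0, 0.0), abs=1e-12)

    def test_exact_cubic(self):
        pts = [(0, 0), (1, 1), (2, 8), (3, 27)]
        fit = a.fit_cubic(pts, "y_of_x")
        assert fit.coeffs == pytest.approx((0.0, 0.0, 0.0, 1.0), abs=1e-10)

    def test_vertical_segment_as_x_of_y(self):
        pts = [(7, 0), (7, 1), (7, 2), (7, 3)]
        fit = a.fit_cubic(pts, "x_of_y")
        assert fit.coeffs == pytest.approx((7.0, 0.0, 0.0, 0.0), abs=1e-12)

    def test_duplicate_independent_values_raise(self):
        with pytest.raises(ValueError):
            a.fit_cubic([(0, 0), (0, 1), (2, 8), (3, 27)], "y_of_x")

    @settings(max_examples=50, deadline=None)
    @given(
        xs=st.lists(
            st.integers(min_value=-20, max_value=20),
            min_size=4, max_size=4, unique=True,
        ),
        ys=st.lists(
            st.integers(min_value=-30, max_value=30), min_size=4, max_size=4
        ),
    )
    def test_interpolates_control_points(self, xs, ys):
        """Oracle: evaluating the fitted polynomial at the control abscissae
        must reproduce the control ordinates to solver tolerance."""
        pts = np.array(sorted(zip(xs, ys)), dtype=float)
        fit = a.fit_cubic(pts, "y_of_x")
        np.testing.assert_allclose(fit(pts[:, 0]), pts[:, 1], atol=1e-9)


class TestChooseParametrization:
    def test_monotone_y_oscillating_x(self):
        pts = [(0, 0), (2, 1), (1, 2), (3, 3), (2, 4)]
        assert a.choose_parametrization(pts) == "x_of_y"

    def test_monotone_x_oscillating_y(self):
        pts = [(0, 0), (1, 2), (2, 1), (3, 3), (4, 2)]
        assert a.choose_parametrization(pts) == "y_of_x"

    def test_both_monotone_prefers_larger_span(self):
        pts = [(0, 0), (1, 3), (2, 6), (3, 9)]  # y span 9 > x span 3
        assert a.choose_parametrization(pts) == "x_of_y"

    def test_s_shape_requires_split(self):
        pts = [(0, 0), (2, 1), (1, 2), (3, 3), (1, 2.5), (0, 1)]
        with pytest.raises(SplitRequired):
            a.choose_parametrization(pts)

    def test_short_branch_rejected(self):
        with pytest.raises(ValueError):
            a.choose_parametrization([(0, 0), (1, 1), (2, 2)])


class TestSmoothPathway:
    STRAIGHT = Pathway(1, [(10, y) for y in range(10, 40)], ("root", None))

    def test_zero_shift_on_straight_pathway_is_collinear(self):
        curve = a.smooth_pathway(self.STRAIGHT, shift=0.0)
        np.testing.assert_allclose(curve[:, 0], 10.0, atol=1e-9)

    def test_endpoints_preserved(self, network):
        for pw in network.pathways:
            if len(pw.points) < 4:
                continue
            curve = a.smooth_pathway(pw, shift=1.0)
            np.testing.assert_allclose(curve[0], pw.points[0])
            np.testing.assert_allclose(curve[-1], pw.points[-1])

    def test_opposite_shifts_mirror_about_chord(self):
        plus = a.smooth_pathway(self.STRAIGHT, shift=2.0)
        minus = a.smooth_pathway(self.STRAIGHT, shift=-2.0)
        # chord is x = 10; mirrored curves satisfy x+ - 10 = 10 - x-
        np.testing.assert_allclose(plus[:, 0] - 10.0, 10.0 - minus[:, 0], atol=1e-9)
        np.testing.assert_allclose(plus[:, 1], minus[:, 1], atol=1e-9)

    def test_requires_four_points(self):
        with pytest.raises(ValueError):
            a.smooth_pathway(Pathway(1, [(0, 0), (1, 1), (2, 2)], ("root", None)))
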