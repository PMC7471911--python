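"""Spline material models: error statistic, fitting, node selection, evaluation.

The independent oracles are scipy's natural CubicSpline and PchipInterpolator
— this module's own fits never go through scipy.interpolate.
"""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.interpolate import BarycentricInterpolator, CubicSpline, PchipInterpolator

import reamsim as rs
from reamsim.spline import _pchip_slopes


class TestApproximationError:
    def test_single_sample(self):
        err, loc = rs.approximation_error([800.0], [600.0])
        assert err == pytest.approx(25.0)
        assert loc == 0

    def test_identity_is_zero(self):
        v = np.linspace(10, 100, 20)
        err, _ = rs.approximation_error(v, v)
        assert err == 0.0

    def test_elementwise_maximum_and_location(self):
        err, loc = rs.approximation_error([100.0, 200.0], [90.0, 190.0])
        assert err == pytest.approx(10.0)
        assert loc == 0

    def test_floor_excludes_near_zero_samples(self):
        # the 0.1 N sample is 0.01% of max: huge relative error, but excluded
        v = np.array([0.1, 1000.0])
        va = np.array([5.0, 990.0])
        err, loc = rs.approximation_error(v, va)
        assert err == pytest.approx(1.0)
        assert loc == 1

    def test_all_below_floor_is_error(self):
        with pytest.raises(rs.ValidationError):
            rs.approximation_error([0.0, 0.0], [1.0, 1.0])


class TestCubicSplineFit:
    def test_closed_form_natural_spline(self):
        # three nodes, natural closure: interior curvature M1 = -3, s(0.5) = 0.6875
        model = rs.fit_cubic_spline([0.0, 1.0, 2.0], [0.0, 1.0, 0.0])
        assert rs.evaluate(model, 0.5) == pytest.approx(0.6875, abs=1e-12)

    def test_linear_data_reproduced(self):
        x = np.linspace(0, 1, 7)
        model = rs.fit_cubic_spline(x, 3.0 * x + 1.0)
        d = np.linspace(0, 1, 200)
        np.testing.assert_allclose(rs.evaluate(model, d), 3.0 * d + 1.0, atol=1e-12)

    def test_oracle_equivalence_random_nodes(self):
        # independent textbook implementation: scipy's natural cubic spline
        rng = np.random.default_rng(7)
        for _ in range(100):
            n = int(rng.integers(3, 16))
            x = np.unique(rng.uniform(0, 1, n))
            if len(x) < 3:
                continue
            y = rng.normal(0, 100, len(x))
            model = rs.fit_cubic_spline(x, y)
            d = np.linspace(x[0], x[-1], 257)
            ref = CubicSpline(x, y, bc_type="natural")(d)
            scale = max(np.max(np.abs(ref)), 1e-12)
            assert np.max(np.abs(rs.evaluate(model, d) - ref)) / scale < 1e-8

    def test_c2_continuity_at_interior_knots(self):
        x = np.array([0.0, 0.2, 0.45, 0.7, 1.0])
        y = np.array([0.0, 5.0, -2.0, 8.0, 3.0])
        model = rs.fit_cubic_spline(x, y)
        a, b, c, const = model.coefficients.T
        h = np.diff(x)
        for i in range(len(x) - 2):
            left_val = ((a[i] * h[i] + b[i]) * h[i] + c[i]) * h[i] + const[i]
            assert left_val == pytest.approx(const[i + 1], rel=1e-10)
            left_d1 = (3 * a[i] * h[i] + 2 * b[i]) * h[i] + c[i]
            assert left_d1 == pytest.approx(c[i + 1], rel=1e-8, abs=1e-8)
            left_d2 = 6 * a[i] * h[i] + 2 * b[i]
            assert left_d2 == pytest.approx(2 * b[i + 1], rel=1e-8, abs=1e-8)

    def test_duplicate_knots_rejected(self):
        with pytest.raises(rs.ValidationError):
            rs.fit_cubic_spline([0.0, 0.5, 0.5, 1.0], [0, 1, 2, 3])


class TestHermiteSplineFit:
    def test_zero_slope_midpoint(self):
        model = rs.fit_hermite_spline([0.0, 1.0], [0.0, 1.0], slopes=[0.0, 0.0])
        assert rs.evaluate(model, 0.5) == pytest.approx(0.5, abs=1e-14)

    def test_slope_estimation_matches_pchip_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            n = int(rng.integers(2, 14))
            x = np.unique(rng.uniform(0, 1, n))
            if len(x) < 2:
                continue
            y = rng.normal(0, 10, len(x))
            ours = _pchip_slopes(x, y)
            theirs = PchipInterpolator(x, y).derivative()(x)
            np.testing.assert_allclose(ours, theirs, rtol=1e-10, atol=1e-10)

    def test_monotone_data_no_overshoot(self):
        x = np.array([0.0, 0.1, 0.3, 0.35, 0.7, 1.0])
        y = np.array([0.0, 0.5, 0.6, 4.0, 4.2, 9.0])  # monotone, uneven
        model = rs.fit_hermite_spline(x, y)
        dense = rs.evaluate(model, np.linspace(0, 1, 2001))
        assert dense.min() >= y[0] - 1e-12
        assert dense.max() <= y[-1] + 1e-12

    def test_knot_interpolation(self):
        x = np.linspace(0, 1, 9)
        y = np.sin(5 * x)
        model = rs.fit_hermite_spline(x, y)
        np.testing.assert_allclose(rs.evaluate(model, x), y, atol=1e-13)


@pytest.fixture(scope="module")
def eval_model():
    x = np.linspace(0, 1, 12)
    return rs.fit_hermite_spline(x, 500 * x ** 2.2 + 50 * np.sin(8 * x))


class TestEvaluate:
    def test_knot_values_exact(self, eval_model):
        np.testing.assert_allclose(rs.evaluate(eval_model, eval_model.knots),
                                   eval_model.node_values, atol=1e-12)

    def test_out_of_domain_clamps(self, eval_model):
        assert rs.evaluate(eval_model, -0.5) == eval_model.node_values[0]
        assert rs.evaluate(eval_model, 7.3) == eval_model.node_values[-1]

    def test_batch_equals_scalar(self, eval_model):
        rng = np.random.default_rng(0)
        d = rng.uniform(-0.2, 1.2, 10_000)
        batch = rs.evaluate(eval_model, d)
        sample = rng.choice(len(d), 100, replace=False)
        for i in sample:
            assert batch[i] == rs.evaluate(eval_model, float(d[i]))


class TestSelectNodes:
    def test_straight_line_needs_only_endpoints(self):
        curve = rs.MaterialCurve(np.linspace(0, 1, 50),
                                 np.linspace(10, 200, 50), "force", "line")
        for kind in ("cubic", "hermite"):
            sel = rs.select_nodes(curve, desired_max_error=1.0, kind=kind)
            assert len(sel.node_indices) == 2
            assert sel.achieved_max_error_percent == pytest.approx(0.0, abs=1e-9)

    def test_nodes_cluster_at_sharp_bend(self):
        g = np.linspace(0, 1, 201)
        y = np.where(g < 0.5, 100.0 + 10 * g, 100.0 + 10 * g + 500 * (g - 0.5) ** 2)
        curve = rs.MaterialCurve(g, y, "force", "bend")
        sel = rs.select_nodes(curve, desired_max_error=0.5, kind="hermite")
        interior = sel.node_indices[1:-1]
        right_half = np.sum(g[interior] >= 0.45)
        assert right_half > len(interior) - right_half

    def test_tighter_tolerance_never_fewer_nodes(self, filtered_short_curve):
        loose = rs.select_nodes(filtered_short_curve, 20.0, kind="hermite")
        tight = rs.select_nodes(filtered_short_curve, 5.0, kind="hermite")
        assert len(tight.node_indices) >= len(loose.node_indices)
        assert loose.achieved_max_error_percent <= 20.0
        assert tight.achieved_max_error_percent <= 5.0

    def test_threshold_history_strictly_decreasing(self, filtered_short_curve):
        sel = rs.select_nodes(filtered_short_curve, 5.0, kind="hermite")
        assert np.all(np.diff(sel.threshold_history) < 0) or len(sel.threshold_history) == 1

    def test_endpoints_always_included(self, filtered_short_curve):
        sel = rs.select_nodes(filtered_short_curve, 10.0, kind="cubic")
        assert sel.node_indices[0] == 0
        assert sel.node_indices[-1] == len(filtered_short_curve.value) - 1


class TestCompareAndScale:
    def test_smooth_curve_both_near_zero(self):
        g = np.linspace(0, 1, 101)
        y = 100.0 + 50.0 * g  # a line: both interpolants reproduce it
        report = rs.compare_models(rs.MaterialCurve(g, y, "force", "s"), 6)
        assert report["cubic"]["max_error_percent"] < 1e-8
        assert report["hermite"]["max_error_percent"] < 1e-8

    def test_comparison_is_deterministic(self, filtered_short_curve):
        a = rs.compare_models(filtered_short_curve, 12)
        b = rs.compare_models(filtered_short_curve, 12)
        assert a["cubic"]["max_error_percent"] == b["cubic"]["max_error_percent"]
        assert a["hermite"]["max_error_percent"] == b["hermite"]["max_error_percent"]
        np.testing.assert_array_equal(a["node_indices"], b["node_indices"])

    def test_scale_identity(self):
        model = rs.fit_hermite_spline([0, 0.5, 1], [0, 100, 400])
        same = rs.scale_hardness(model, 1.0)
        d = np.linspace(0, 1, 50)
        np.testing.assert_array_equal(rs.evaluate(same, d), rs.evaluate(model, d))

    def test_scale_doubles_everywhere(self):
        model = rs.fit_cubic_spline([0, 0.3, 0.8, 1], [0, 50, 300, 400])
        double = rs.scale_hardness(model, 2.0)
        d = np.linspace(0, 1, 101)
        np.testing.assert_allclose(rs.evaluate(double, d), 2 * rs.evaluate(model, d),
                                   rtol=1e-12)

    def test_scale_out_of_range(self):
        model = rs.fit_hermite_spline([0, 1], [0, 1])
        with pytest.raises(rs.ParameterError):
            rs.scale_hardness(model, 99.0)

    def test_scaled_model_bounded_by_envelope_maximum(self, filtered_short_curve):
        model = rs.fit_hermite_spline(
            filtered_short_curve.normalized_displacement[::40],
            filtered_short_curve.value[::40])
        env = rs.compute_envelopes([filtered_short_curve], 256)
        dense = rs.evaluate(model, env.grid)
        scale = float(env.maximum.max() / dense.max())
        if 0.1 <= scale <= 10.0:
            scaled = rs.scale_hardness(model, scale)
            assert np.max(rs.evaluate(scaled, env.grid)) <= env.maximum.max() * (1 + 1e-9)


def test_runge_fixture_piecewise_beats_global_lagrange():
    """A step-like curve on 11 equispaced nodes: the single degree-10
    polynomial oscillates near the boundary, the piecewise cubic does not."""
    g = np.linspace(0, 1, 401)
    y = 100.0 / (1.0 + np.exp(-40 * (g - 0.5)))  # sharp but smooth step
    nodes = np.linspace(0, 1, 11)
    node_vals = 100.0 / (1.0 + np.exp(-40 * (nodes - 0.5)))
    lagrange = BarycentricInterpolator(nodes, node_vals)(g)
    piecewise = rs.evaluate(rs.fit_cubic_spline(nodes, node_vals), g)
    assert np.max(np.abs(piecewise - y)) < np.max(np.abs(lagrange - y))


@given(st.integers(0, 2 ** 31 - 1), st.integers(3, 20))
def test_knot_interpolation_property(seed, n):
    """Both fits interpolate their node values exactly, for any node set."""
    rng = np.random.default_rng(seed)
    x = np.unique(rng.uniform(0, 1, n))
    if len(x) < 2:
        return
    y = rng.normal(0, 500, len(x))
    for fit in (rs.fit_cubic_spline, rs.fit_hermite_spline):
        model = fit(x, y)
        np.testing.assert_allclose(rs.evaluate(model, x), y, atol=1e-9 * max(1, np.max(np.abs(y))))
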