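"""Basis, normalisation, convolution, dispersion and shift operators."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad

from aifx import (
    ImpulseResponse,
    InjectionProfile,
    KnotVector,
    SampledCurve,
    basis_eval,
    convolve_with_injection,
    disperse,
    ir_eval,
    make_knots,
    normalize_ir,
    shift,
)
from aifx.ir_model import (
    basis_first_moments,
    basis_injection_matrix,
    basis_integrals,
    make_grid,
)


class TestMakeKnots:
    def test_geometric_ladder_matches_construction(self):
        kv = make_knots(5400.0, K=12, first_knot=5.0)
        assert kv.knots.size == 13
        assert kv.knots[0] == 0.0
        assert kv.knots[1] == pytest.approx(5.0)
        assert kv.t_end == pytest.approx(1.2 * 5400.0)
        # geometric spacing between the non-zero knots
        ratios = kv.knots[2:] / kv.knots[1:-1]
        assert np.allclose(ratios, ratios[0])

    @pytest.mark.parametrize("K,first", [(2, 5.0), (5, 0.0), (5, 600.0)])
    def test_invalid_inputs_rejected(self, K, first):
        with pytest.raises(ValueError):
            make_knots(500.0, K=K, first_knot=first)

    @given(st.integers(3, 20), st.floats(0.5, 50.0))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_strictly_increasing_for_any_valid_input(self, K, first):
        kv = make_knots(600.0, K=K, first_knot=first)
        assert np.all(np.diff(kv.knots) > 0)


class TestBasis:
    def test_plateau_ramp_endpoints(self, knots_small):
        # B_k is 1 on the plateau, 0.5 at the ramp midpoint, 0 at t_k
        assert basis_eval(knots_small, 2, 0.0) == 1.0
        assert basis_eval(knots_small, 2, 9.99) == pytest.approx(1.0)
        assert basis_eval(knots_small, 2, 20.0) == pytest.approx(0.5)
        assert basis_eval(knots_small, 2, 30.0) == 0.0
        assert basis_eval(knots_small, 2, -1.0) == 0.0

    def test_integral_closed_form_vs_quadrature(self, knots_small):
        m0 = basis_integrals(knots_small)
        m1 = basis_first_moments(knots_small)
        for k in range(1, knots_small.K + 1):
            q0, _ = quad(lambda t: float(basis_eval(knots_small, k, t)), 0,
                         knots_small.t_end, limit=200)
            q1, _ = quad(lambda t: t * float(basis_eval(knots_small, k, t)), 0,
                         knots_small.t_end, limit=200)
            a, b = knots_small.knots[k - 1], knots_small.knots[k]
            assert m0[k - 1] == pytest.approx((a + b) / 2.0, rel=1e-12)
            assert m0[k - 1] == pytest.approx(q0, rel=1e-9)
            assert m1[k - 1] == pytest.approx(q1, rel=1e-9)


class TestImpulseResponse:
    def test_single_coefficient_reproduces_basis(self, knots_small):
        ir = ImpulseResponse(knots_small, np.array([0.0, 1.0, 0.0]))
        t = np.linspace(0, 60, 101)
        assert np.allclose(ir_eval(ir, t),
                           basis_eval(knots_small, 2, t))

    def test_zero_coefficients_give_zero_curve(self, knots_small):
        ir = ImpulseResponse(knots_small, np.zeros(3))
        assert np.all(ir_eval(ir, np.linspace(0, 100, 50)) == 0.0)

    @given(theta=st.lists(st.floats(0.0, 10.0), min_size=3, max_size=3))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_nonnegative_theta_gives_monotone_response(self, theta):
        knots_small = KnotVector(np.array([0.0, 10.0, 30.0, 80.0]))
        ir = ImpulseResponse(knots_small, np.array(theta))
        vals = ir_eval(ir, np.linspace(0, 100, 200))
        assert np.all(np.diff(vals) <= 1e-12)

    def test_negative_theta_rejected(self, knots_small):
        with pytest.raises(ValueError):
            ImpulseResponse(knots_small, np.array([1.0, -0.5, 0.0]))


class TestNormalize:
    def test_unit_integral_and_idempotence(self, decaying_ir):
        n = normalize_ir(decaying_ir)
        assert n.integral == pytest.approx(1.0, abs=1e-10)
        again = normalize_ir(n)
        assert np.allclose(again.theta, n.theta, rtol=1e-14)

    def test_closed_form_matches_grid_quadrature(self, decaying_ir):
        n = normalize_ir(decaying_ir)
        grid = np.linspace(0, n.knots.t_end, 200001)
        num = np.trapezoid(ir_eval(n, grid), grid)
        assert num == pytest.approx(1.0, rel=1e-6)

    def test_zero_response_rejected(self, knots_small):
        with pytest.raises(ValueError):
            normalize_ir(ImpulseResponse(knots_small, np.zeros(3)))


class TestConvolution:
    def test_zero_at_time_origin(self, knots_small, square60):
        ir = ImpulseResponse(knots_small, np.array([1.0, 0.5, 0.2]))
        assert convolve_with_injection(ir, square60, np.array([0.0]))[0] == 0.0

    def test_bolus_is_identity(self, knots_small, bolus):
        ir = ImpulseResponse(knots_small, np.array([1.0, 0.5, 0.2]))
        t = np.linspace(0, 100, 81)
        assert np.allclose(convolve_with_injection(ir, bolus, t), ir_eval(ir, t))

    def test_square_total_mass_fubini(self, knots_small):
        # for a unit-height square of duration d, int (B_k * C_I) = d * int B_k
        d = 20.0
        inj = InjectionProfile("square", duration=d, height=1.0)
        grid = np.linspace(0, 300, 300001)
        for k in (1, 2, 3):
            vals = convolve_with_injection((knots_small, k), inj, grid)
            a, b = knots_small.knots[k - 1], knots_small.knots[k]
            assert np.trapezoid(vals, grid) == pytest.approx(
                d * (a + b) / 2.0, rel=1e-6)

    def test_closed_form_matches_adaptive_quadrature(self, knots_small, square60):
        rng = np.random.default_rng(7)
        ts = rng.uniform(0.0, 150.0, 50)
        d = square60.duration
        for k in (1, 3):
            a, b = knots_small.knots[k - 1], knots_small.knots[k]
            closed = convolve_with_injection((knots_small, k), square60, ts)
            for t, c in zip(ts, closed):
                # integrand is piecewise polynomial; give quad its breakpoints
                brk = sorted({p for p in (t - b, t - a, t, d)
                              if 0.0 < p < max(t, 1e-9)})
                ref, _ = quad(
                    lambda s: float(basis_eval(knots_small, k, t - s))
                    * float(square60.eval_on(np.array([s]))[0]),
                    0.0, max(t, 1e-9), points=brk or None, limit=300)
                assert c == pytest.approx(ref, rel=1e-5, abs=1e-8)

    def test_linearity_in_theta(self, knots_small, square60):
        rng = np.random.default_rng(3)
        th = rng.uniform(0, 2, 3)
        t = np.linspace(0, 120, 61)
        whole = convolve_with_injection(
            ImpulseResponse(knots_small, th), square60, t)
        parts = sum(
            th[k - 1] * convolve_with_injection((knots_small, k), square60, t)
            for k in (1, 2, 3))
        assert np.allclose(whole, parts, rtol=1e-10, atol=1e-12)

    def test_measured_profile_matches_square(self, knots_small):
        # a measured profile tracing a square must reproduce the closed form
        tt = np.linspace(0, 200, 4001)
        sq = InjectionProfile("square", duration=30.0, height=1.0)
        meas = InjectionProfile(
            "measured",
            samples=np.column_stack([tt, sq.eval_on(tt)]))
        t = np.linspace(0, 150, 31)
        a = convolve_with_injection((knots_small, 2), sq, t)
        b = convolve_with_injection((knots_small, 2), meas, t)
        assert np.allclose(a, b, atol=2e-2 * max(a.max(), 1.0))


class TestDisperse:
    def test_step_input_closed_form(self):
        grid = np.arange(0, 100, 0.1)
        out = disperse(SampledCurve(grid, np.ones_like(grid)), 7.0)
        assert np.allclose(out.values, 1.0 - np.exp(-grid / 7.0), atol=1e-12)

    def test_vanishing_phi_is_identity(self):
        grid = np.arange(0, 30, 0.05)
        vals = np.exp(-((grid - 10.0) / 3.0) ** 2)
        out = disperse(SampledCurve(grid, vals), 1e-6)
        assert np.abs(out.values - vals).max() <= 1e-3

    def test_mass_preservation(self):
        grid = np.arange(0, 600, 0.1)
        vals = np.where(grid < 20, 1.0, 0.0)
        out = disperse(SampledCurve(grid, vals), 9.0)
        assert np.trapezoid(out.values, grid) == pytest.approx(
            np.trapezoid(vals, grid), rel=5e-3)

    def test_nonpositive_phi_rejected(self):
        grid = np.arange(0, 10, 0.1)
        with pytest.raises(ValueError):
            disperse(SampledCurve(grid, np.ones_like(grid)), 0.0)


class TestShift:
    def test_zero_shift_identity(self):
        grid = np.arange(0, 50, 0.5)
        c = SampledCurve(grid, np.sin(grid / 5.0) ** 2)
        assert np.allclose(shift(c, 0.0).values, c.values)

    def test_one_grid_step(self):
        grid = np.arange(0, 50, 0.5)
        c = SampledCurve(grid, np.arange(grid.size, dtype=float))
        out = shift(c, 0.5)
        assert np.allclose(out.values[1:], c.values[:-1])
        assert out.values[0] == 0.0

    def test_composition(self):
        grid = np.arange(0, 80, 0.25)
        c = SampledCurve(grid, np.exp(-((grid - 20.0) / 6.0) ** 2))
        ab = shift(shift(c, 3.3), 4.4)
        once = shift(c, 7.7)
        assert np.abs(ab.values - once.values).max() <= 5e-3


def test_sampled_curve_requires_uniform_grid():
    with pytest.raises(ValueError):
        SampledCurve(np.array([0.0, 1.0, 3.0]), np.zeros(3))


def test_basis_injection_matrix_columns_match_convolution(knots_small, square5):
    grid = make_grid(200.0, step=0.05, pad=0.0)
    mat = basis_injection_matrix(knots_small, square5, grid)
    for k in (1, 2, 3):
        direct = convolve_with_injection((knots_small, k), square5, grid)
        assert np.allclose(mat[:, k - 1], direct, atol=1e-12)
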