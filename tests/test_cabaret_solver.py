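"""CABARET scheme operators against hand-evaluated and analytic oracles."""

import numpy as np
import pytest

import emboflow as ef
from emboflow.cabaret_solver import (Grid1D, StageFields, boundary_flux,
                                     cfl_timestep, discrete_pressure,
                                     full_step, flux_variable_update,
                                     half_step, interior_fluxes,
                                     mixture_flow, run_prescribed, run_stage)
from emboflow.model_core import MMHG

from conftest import make_unit_model


def unit_fields(u, U, J=None):
    u = np.asarray(u, float)
    U = np.asarray(U, float)
    return StageFields(u=u, U=U, A_int=np.ones_like(u), A_half=np.ones_like(U))


class TestCflTimestep:
    def test_direct_arithmetic(self, linear_flux):
        # r=0.5, h=0.01, max speed 2 -> tau = 0.0025
        grid = Grid1D(J=100, L=1.0)
        model = make_unit_model()
        fields = unit_fields(np.full(101, 0.5), np.full(100, 0.5))
        tau = cfl_timestep(fields, 2.0, linear_flux, model, 0.5, grid)
        assert tau == pytest.approx(0.0025)

    def test_speed_proportional_to_flow(self, linear_flux):
        grid = Grid1D(J=10, L=1.0)
        model = make_unit_model()
        fields = unit_fields(np.full(11, 0.5), np.full(10, 0.5))
        t1 = cfl_timestep(fields, 1.0, linear_flux, model, 0.5, grid)
        t2 = cfl_timestep(fields, 2.0, linear_flux, model, 0.5, grid)
        assert t2 == pytest.approx(0.5 * t1)

    def test_zero_speed_raises(self, quadratic_flux):
        # f'(1) = 0 for the mobility-ratio flux: uniform blood is degenerate
        grid = Grid1D(J=10, L=1.0)
        model = make_unit_model()
        fields = unit_fields(np.ones(11), np.ones(10))
        with pytest.raises(ValueError):
            cfl_timestep(fields, 1.0, quadratic_flux, model, 0.5, grid)


class TestMixtureFlow:
    def test_sum_and_no_injection(self):
        model = make_unit_model(qbar=lambda s: 3.0)
        assert mixture_flow(2.0, 0.5, model) == pytest.approx(5.0)
        assert mixture_flow(0.0, 0.5, model) == pytest.approx(3.0)

    def test_symmetric_doubling(self):
        model = make_unit_model(qbar=lambda s: 1.7)
        assert mixture_flow(1.7, 0.2, model) == pytest.approx(2 * 1.7)


class TestDiscretePressure:
    def test_uniform_saturation_closed_form(self, fixture_K):
        # S = 1, constant A: the quadrature telescopes to the Darcy drop
        model, ff = fixture_K
        grid = Grid1D(J=64, L=model.L)
        A = model.area(grid.x_half)
        fields = StageFields(u=np.ones(65), U=np.ones(64),
                             A_int=model.area(grid.x_nodes), A_half=A)
        Q = 1.3
        p = discrete_pressure(fields, Q, model, ff, grid)
        exact = model.p2(1.0) + Q * model.eta_b * model.L / (model.K * A[0]) / MMHG
        assert p == pytest.approx(exact, rel=1e-12)

    def test_vanishing_flow_leaves_outlet_pressure(self, fixture_K):
        model, ff = fixture_K
        grid = Grid1D(J=16, L=model.L)
        fields = StageFields(u=np.ones(17), U=np.full(16, 0.7),
                             A_int=model.area(grid.x_nodes),
                             A_half=model.area(grid.x_half))
        p = discrete_pressure(fields, 1e-300, model, ff, grid)
        assert p == pytest.approx(model.p2(0.7), rel=1e-9)

    def test_darcy_term_scales_inversely_with_permeability(self, quadratic_flux):
        m1 = make_unit_model(alpha_b=2.0, K=1e-6)
        m2 = make_unit_model(alpha_b=2.0, K=5e-7)
        grid = Grid1D(J=8, L=1.0)
        fields = unit_fields(np.full(9, 0.8), np.full(8, 0.8))
        d1 = discrete_pressure(fields, 1.0, m1, quadratic_flux, grid) - m1.p2(0.8)
        d2 = discrete_pressure(fields, 1.0, m2, quadratic_flux, grid) - m2.p2(0.8)
        assert d2 == pytest.approx(2.0 * d1, rel=1e-12)


class TestHalfStep:
    def test_uniform_state_unchanged(self, quadratic_flux):
        fields = unit_fields(np.full(5, 0.4), np.full(4, 0.4))
        out = half_step(fields, 1.0, 0.1, quadratic_flux, np.ones(4), 0.25)
        assert np.allclose(out, 0.4, atol=1e-15)

    def test_hand_evaluated_two_point_difference(self, linear_flux):
        # m=A=Q=1, h=0.5, tau=0.25, f=S, u=[1,.5,0], U=[.75,.25]
        fields = unit_fields([1.0, 0.5, 0.0], [0.75, 0.25])
        out = half_step(fields, 1.0, 0.25, linear_flux, np.ones(2), 0.5)
        assert out == pytest.approx([0.875, 0.375])

    def test_linear_in_tau(self, linear_flux):
        fields = unit_fields([1.0, 0.5, 0.0], [0.75, 0.25])
        d1 = half_step(fields, 1.0, 0.25, linear_flux, np.ones(2), 0.5) - fields.U
        d2 = half_step(fields, 1.0, 0.50, linear_flux, np.ones(2), 0.5) - fields.U
        assert np.allclose(d2, 2.0 * d1)


class TestBoundaryFlux:
    @pytest.mark.parametrize("qe_mult,expected", [(0.0, 1.0), (1.0, 0.5), (3.0, 0.25)])
    def test_flow_ratio(self, qe_mult, expected):
        model = make_unit_model(qbar=lambda s: 2.0)
        grid = Grid1D(J=4, L=1.0)
        fields = unit_fields(np.ones(5), np.full(4, 0.5))
        f0, Vbar = boundary_flux(qe_mult * 2.0, fields.U, fields, model,
                                 np.ones(4), grid)
        assert Vbar == pytest.approx(0.5)
        assert f0 == pytest.approx(expected)


# hand-evaluated one-step oracle, J=4, linear flux, c = tau*Q/(m A h) = 0.5
HAND_u = np.array([0.0, 0.25, 0.75, 1.0, 1.0])
HAND_U = np.array([0.125, 0.5, 0.875, 1.0])
HAND_TAU, HAND_H = 0.125, 0.25
HAND_UHALF = np.array([0.0625, 0.375, 0.8125, 1.0])
HAND_FLUXES = np.array([0.1875, 0.625, 0.9375, 1.0])
HAND_UNEW = np.array([0.03125, 0.28125, 0.71875, 0.96875])  # with inlet flux 0


class TestInteriorFluxes:
    def test_constant_state_preserved(self, quadratic_flux):
        fields = unit_fields(np.full(6, 0.6), np.full(5, 0.6))
        Uh = np.full(5, 0.6)
        out = interior_fluxes(fields, Uh, 1.0, 0.05, quadratic_flux,
                              np.ones(6), 0.2)
        assert np.allclose(out, float(quadratic_flux.f(0.6)), atol=1e-14)

    def test_two_sided_limiter_clamps(self, linear_flux):
        # extrapolation far above the local bracket is pulled back to its max
        fields = unit_fields([0.0, 0.2, 0.2], [0.2, 0.2])
        Uh = np.array([0.9, 0.2])  # exaggerated half-layer value at j=1
        out = interior_fluxes(fields, Uh, 1.0, 0.05, linear_flux,
                              np.ones(3), 0.5)
        assert out[0] == pytest.approx(max(0.2, 0.2))  # clamped to bracket max

    def test_hand_evaluated_riemann_step(self, linear_flux):
        fields = unit_fields(HAND_u, HAND_U)
        Uh = half_step(fields, 1.0, HAND_TAU, linear_flux, np.ones(4), HAND_H)
        assert Uh == pytest.approx(HAND_UHALF, abs=1e-15)
        out = interior_fluxes(fields, Uh, 1.0, HAND_TAU, linear_flux,
                              np.ones(5), HAND_H)
        assert out == pytest.approx(HAND_FLUXES, abs=1e-15)

    def test_matches_independent_transcription(self, quadratic_flux):
        # scalar transcription of the published flux formulas, evaluated
        # pointwise, vs the vectorized implementation
        rng = np.random.default_rng(5)
        u = np.sort(rng.random(9))
        U = np.sort(rng.random(8))
        fields = unit_fields(u, U)
        tau, h, Q = 0.02, 0.125, 1.3
        mA = np.ones(9)
        Uh = half_step(fields, Q, tau, quadratic_flux, np.ones(8), h)
        got = interior_fluxes(fields, Uh, Q, tau, quadratic_flux, mA, h)

        f = lambda s: float(quadratic_flux.f(min(max(s, 0.0), 1.0)))
        expected = []
        for j in range(1, 9):
            ubar1 = 2.0 * Uh[j - 1] - u[j - 1]
            fb = f(0.5 * (u[j] + ubar1))
            lo, hi = sorted((f(U[j - 1]), f(u[j])))
            fb = min(max(fb, lo), hi)
            if j >= 2:
                s0, s1, s2, s3 = f(U[j - 2]), f(u[j - 1]), f(U[j - 1]), f(u[j])
                phi = mA[j - 1] * (U[j - 1] - u[j - 1]) / ((tau / h) * Q)
                if s0 <= s1 <= s2 <= s3:
                    fb = min(fb, s1 + phi)
                elif s0 >= s1 >= s2 >= s3:
                    fb = max(fb, s1 + phi)
            expected.append(fb)
        assert got == pytest.approx(expected, abs=1e-14)


class TestFullStep:
    def test_equal_fluxes_no_change(self):
        fields = unit_fields(np.full(5, 0.3), np.full(4, 0.3))
        out = full_step(fields, np.full(5, 0.77), 1.0, 0.1, np.ones(4), 0.25)
        assert np.allclose(out, 0.3)

    def test_pure_blood_equilibrium(self, quadratic_flux):
        fields = unit_fields(np.ones(5), np.ones(4))
        fh = np.concatenate(([1.0], interior_fluxes(
            fields, fields.U.copy(), 1.0, 0.1, quadratic_flux, np.ones(5), 0.25)))
        out = full_step(fields, fh, 1.0, 0.1, np.ones(4), 0.25)
        assert np.allclose(out, 1.0, atol=1e-15)

    def test_hand_evaluated_update(self, linear_flux):
        fields = unit_fields(HAND_u, HAND_U)
        fh = np.concatenate(([0.0], HAND_FLUXES))
        out = full_step(fields, fh, 1.0, HAND_TAU, np.ones(4), HAND_H)
        assert out == pytest.approx(HAND_UNEW, abs=1e-15)


class TestFluxVariableUpdate:
    def test_uniform_state_unchanged(self, quadratic_flux):
        c = 0.45
        fields = unit_fields(np.full(5, c), np.full(4, c))
        fc = float(quadratic_flux.f(c))
        out = flux_variable_update(fields, np.full(4, c), np.full(5, fc), fc,
                                   quadratic_flux)
        assert np.allclose(out, c, atol=1e-11)

    def test_pure_blood_boundary(self, quadratic_flux):
        fields = unit_fields(np.ones(5), np.ones(4))
        out = flux_variable_update(fields, np.ones(4), np.ones(5), 1.0,
                                   quadratic_flux)
        assert out[0] == 1.0

    def test_extrapolation_clamped_to_neighbour_bracket(self, linear_flux):
        fields = unit_fields([0.1, 0.9, 0.9], [0.5, 0.9])
        U_new = np.array([0.5, 0.9])
        # large half-layer flux drives the extrapolation above the bracket
        fh = np.array([0.1, 0.95, 0.9])
        out = flux_variable_update(fields, U_new, fh, 0.1, linear_flux)
        assert out[1] == pytest.approx(0.9)  # clamped into [0.5, 0.9]


class TestRunStage:
    def test_no_injection_is_equilibrium(self, fixture_K):
        model, ff = fixture_K
        grid = Grid1D(J=40, L=model.L)
        plan = ef.ControlPlan([ef.StageControl(0.0, 1.0, 1.0)], epsilon=0.1)
        res = run_stage(model, ff, plan, 0, model.area(grid.x_nodes),
                        model.area(grid.x_half), grid, r=0.5)
        assert np.all(res.fields.u == 1.0) and np.all(res.fields.U == 1.0)
        assert res.min_S_outlet == 1.0
        assert np.ptp(res.trace.p1) == 0.0

    def test_determinism_bit_identical(self, fixture_K):
        model, ff = fixture_K
        grid = Grid1D(J=30, L=model.L)
        plan = ef.ControlPlan([ef.StageControl(1.5, 0.5, 1.0)], epsilon=0.1)
        runs = [run_stage(model, ff, plan, 0, model.area(grid.x_nodes),
                          model.area(grid.x_half), grid, r=0.5)
                for _ in range(2)]
        assert np.array_equal(runs[0].fields.u, runs[1].fields.u)
        assert np.array_equal(runs[0].trace.p1, runs[1].trace.p1)
        assert np.array_equal(runs[0].trace.t, runs[1].trace.t)

    def test_step_cap_raises(self, fixture_K):
        model, ff = fixture_K
        grid = Grid1D(J=30, L=model.L)
        plan = ef.ControlPlan([ef.StageControl(2.0, 0.5, 2.0)], epsilon=0.1)
        with pytest.raises(RuntimeError):
            run_stage(model, ff, plan, 0, model.area(grid.x_nodes),
                      model.area(grid.x_half), grid, r=0.5, max_steps=5)

    def test_range_preserved_during_injection(self, fixture_K):
        model, ff = fixture_K
        grid = Grid1D(J=30, L=model.L)
        plan = ef.ControlPlan([ef.StageControl(1.5, 0.3, 0.7)], epsilon=0.1)
        res = run_stage(model, ff, plan, 0, model.area(grid.x_nodes),
                        model.area(grid.x_half), grid, r=0.5)
        assert res.fields.u.min() >= 0.0 and res.fields.u.max() <= 1.0
        assert res.fields.U.min() >= 0.0 and res.fields.U.max() <= 1.0
        # records land exactly on the control breakpoints
        for bp in (0.3, 1.0, 1.1):
            assert np.min(np.abs(res.trace.t - bp)) < 1e-12


class TestLinearAdvectionExactness:
    def test_translation_at_unit_courant(self, linear_flux):
        grid = Grid1D(J=50, L=1.0)
        G = lambda y: 0.2 + 0.6 / (1.0 + np.exp(-(np.asarray(y) + 0.2) / 0.05))
        x = grid.x_nodes
        tau = grid.h
        u0 = G(x)
        U0 = 0.5 * (u0[:-1] + u0[1:])
        inflow = lambda t: float(G(-t))
        inflow_half = lambda th: 0.5 * (float(G(-(th - 0.5 * tau)))
                                        + float(G(-(th + 0.5 * tau))))
        fields, t, hist = run_prescribed(
            grid, linear_flux, Q=1.0, inflow=inflow, u0=u0, U0=U0, r=1.0,
            n_steps=60, record_fields=True, inflow_half=inflow_half)
        for tn, u, U in hist:
            assert np.max(np.abs(u - G(x - tn))) <= 1e-12
            assert np.max(np.abs(U - 0.5 * (G(x[:-1] - tn) + G(x[1:] - tn)))) <= 1e-12
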