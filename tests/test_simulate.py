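"""Integrator tests: grids, RK4 accuracy, interventions, summaries."""

import math

import numpy as np
import pytest

from cytotriad import (
    BolusEvent,
    CytokineState,
    DEFAULT_INITIAL_STATE,
    InterventionSchedule,
    ParameterModulation,
    ParameterSet,
    build_time_grid,
    nondimensionalize,
    rhs,
    rk4_integrate,
    run_scenario,
    summarize_trajectory,
)
from cytotriad.fixtures import FixtureSpec, generate_fixture
from cytotriad.simulate import Trajectory


class TestTimeGrid:
    def test_breakpoints_are_nodes(self):
        grid = build_time_grid(72, 0.01, [18, 24])
        assert 18.0 in grid and 24.0 in grid
        assert grid[0] == 0.0 and grid[-1] == 72.0
        assert np.all(np.diff(grid) > 0)
        assert np.max(np.diff(grid)) <= 0.01 + 1e-12

    def test_step_shrinks_to_fit(self):
        # ceil(1 / 0.3) = 4 equal steps of 0.25
        np.testing.assert_allclose(build_time_grid(1, 0.3, []),
                                   [0, 0.25, 0.5, 0.75, 1.0])

    def test_breakpoint_outside_range(self):
        with pytest.raises(ValueError, match="breakpoint"):
            build_time_grid(72, 0.01, [80])


class TestRK4:
    def test_pure_decay_matches_closed_form(self):
        fx = generate_fixture(FixtureSpec("pure_decay"))
        tr = rk4_integrate(fx.parameters, CytokineState(0, 1, 1, 1), 1.0, 0.001)
        np.testing.assert_allclose(tr.states[-1], fx.solution((1, 1, 1), 1.0),
                                   atol=1e-9)

    def test_requires_t0_zero(self, params):
        with pytest.raises(ValueError, match="t = 0"):
            rk4_integrate(params, CytokineState(1.0, 1, 1, 1), 10.0)

    def test_states_nonnegative(self, params, initial_state):
        tr = rk4_integrate(params, initial_state, 72.0, 0.01)
        assert np.all(tr.states >= 0)

    def test_redundant_breakpoints_do_not_change_solution(self, params, initial_state):
        base = rk4_integrate(params, initial_state, 40.0, 0.01)
        redundant = rk4_integrate(params, initial_state, 40.0, 0.01,
                                  breakpoints=[7.0, 18.0, 23.456])
        # compare at the shared endpoint and the delay node
        np.testing.assert_allclose(redundant.states[-1], base.states[-1],
                                   atol=1e-10)
        i_base = int(np.argmin(np.abs(base.times - 18.0)))
        i_red = int(np.argmin(np.abs(redundant.times - 18.0)))
        np.testing.assert_allclose(redundant.states[i_red], base.states[i_base],
                                   atol=1e-10)

    def test_misaligned_grid_error_is_order_dt(self, params, initial_state):
        """A uniform grid that straddles the delay switch loses accuracy only
        at O(dt) relative to the breakpoint-aligned integration."""
        dt = 0.7  # 18 / 0.7 is not an integer: the gate flips mid-step
        aligned = rk4_integrate(params, initial_state, 35.0, dt)

        def naive(dt):
            n = round(35.0 / dt)
            ts = np.linspace(0, 35.0, n + 1)
            y = np.array(DEFAULT_INITIAL_STATE)
            for t0, t1 in zip(ts[:-1], ts[1:]):
                h = t1 - t0

                def f(t, y):
                    return rhs(CytokineState(t, *np.maximum(y, 0)), params).as_array()

                k1 = f(t0, y)
                k2 = f(t0 + h / 2, y + h / 2 * k1)
                k3 = f(t0 + h / 2, y + h / 2 * k2)
                k4 = f(t1, y + h * k3)
                y = y + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
            return y

        gap = np.max(np.abs(naive(0.7) - aligned.states[-1]))
        assert gap < 0.7  # O(dt), not catastrophic

    def test_nondimensional_consistency(self, params, initial_state):
        """Integrating the rescaled (dimensionless) system and mapping back
        reproduces the dimensional trajectory within integrator tolerance."""
        p = params
        K, bT, g = p.hill_K, p.beta_T, p.gamma_T10
        p_nd = ParameterSet(
            alpha_T=p.alpha_T / (K * bT), alpha_6=p.alpha_6 / (K * bT),
            alpha_10=g * p.alpha_10 / (K * bT),
            k_T6=p.k_T6 / bT, k_6T=p.k_6T / bT,
            k_10T=g * p.k_10T / bT, k_106=g * p.k_106 / bT,
            gamma_T10=K / bT, gamma_610=(K / bT) * (p.gamma_610 / g),
            beta_T=1.0, beta_6=p.beta_6 / bT, beta_10=p.beta_10 / bT,
            hill_n=p.hill_n, hill_K=1.0, t_delay=bT * p.t_delay)
        form0 = nondimensionalize(p, initial_state)
        s0_nd = CytokineState(0.0, form0.C_tilde_T, form0.C_tilde_6,
                              form0.C_tilde_10)
        t_end, dt = 30.0, 0.005
        tr = rk4_integrate(p, initial_state, t_end, dt)
        tr_nd = rk4_integrate(p_nd, s0_nd, bT * t_end, bT * dt)
        back = tr_nd.states * np.array([K, K, K / g])
        assert tr.states.shape == back.shape
        np.testing.assert_allclose(back, tr.states, atol=1e-7)


class TestInterventions:
    def test_zero_bolus_is_identity(self, params, initial_state):
        schedule = InterventionSchedule(boluses=(BolusEvent(24.0, "C_10", 0.0),))
        with_bolus = rk4_integrate(params, initial_state, 72.0, 0.01, schedule)
        base = rk4_integrate(params, initial_state, 72.0, 0.01,
                             breakpoints=[24.0])
        np.testing.assert_array_equal(with_bolus.states, base.states)

    def test_bolus_recorded_pre_jump(self, params):
        tr = run_scenario("il10_bolus", params, t_end=30.0, dt=0.01)
        i24 = int(np.argmin(np.abs(tr.times - 24.0)))
        c10 = tr.species("C_10")
        assert tr.times[i24] == 24.0
        assert c10[i24 + 1] - c10[i24] > 0.049  # the +0.05 jump, minus one step of decay

    def test_tnf_inhibition_halves_basal_production(self, params, initial_state):
        tr = run_scenario("tnf_inhibition", params, t_end=30.0, dt=0.01)
        direct = rk4_integrate(params.replace(alpha_T=0.01), initial_state,
                               30.0, 0.01)
        np.testing.assert_array_equal(tr.states, direct.states)

    def test_il10_knockout_closed_form(self, params):
        tr = run_scenario("il10_knockout", params, t_end=30.0, dt=0.01)
        expected = 0.01 * np.exp(-params.beta_10 * tr.times)
        np.testing.assert_allclose(tr.species("C_10"), expected, atol=1e-10)

    def test_unknown_scenario(self):
        with pytest.raises(ValueError, match="unknown scenario"):
            run_scenario("nonsense")

    def test_modulation_window(self, params, initial_state):
        """A modulation of beta_T applies only inside its window."""
        schedule = InterventionSchedule(
            modulations=(ParameterModulation("alpha_T", 0.0, 5.0, 10.0),))
        tr = rk4_integrate(params, initial_state, 15.0, 0.01, schedule)
        base = rk4_integrate(params, initial_state, 15.0, 0.01,
                             breakpoints=[5.0, 10.0])
        i5 = int(np.argmin(np.abs(tr.times - 5.0)))
        i10 = int(np.argmin(np.abs(tr.times - 10.0)))
        np.testing.assert_array_equal(tr.states[:i5 + 1], base.states[:i5 + 1])
        assert np.all(tr.species("C_T")[i5 + 1:i10 + 1]
                      < base.species("C_T")[i5 + 1:i10 + 1])


class TestSummary:
    def test_decaying_peak_at_zero(self, params, initial_state):
        tr = rk4_integrate(params, initial_state, 10.0, 0.01)
        summary = summarize_trajectory(tr)
        assert summary.C_T.peak_time == 0.0
        assert summary.C_T.peak_value == pytest.approx(0.1)

    def test_constant_trajectory_resolves_immediately(self, params):
        times = np.linspace(0, 10, 11)
        states = np.ones((11, 3)) * 0.5
        tr = Trajectory(times=times, states=states, parameters=params)
        assert summarize_trajectory(tr).resolution_time == 0.0

    def test_pure_decay_resolution_time_analytic(self):
        fx = generate_fixture(FixtureSpec("pure_decay"))
        tr = rk4_integrate(fx.parameters, CytokineState(0, 1.0, 0.0, 0.0),
                           72.0, 0.01)
        summary = summarize_trajectory(tr, resolution_fraction=0.05)
        # first grid node with exp(-1.8 t) <= 1.05 exp(-1.8 * 72)
        t_star = 72.0 + math.log(1.05) / -1.8
        expected = tr.times[np.searchsorted(tr.times, t_star - 1e-9)]
        assert summary.resolution_time == pytest.approx(expected, abs=1e-9)
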