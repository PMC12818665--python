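"""Steady-state, Jacobian and closed-form solution tests."""

import numpy as np
import pytest

from cytotriad import (
    CytokineState,
    LinearSubsystem,
    ParameterSet,
    assemble_jacobian,
    classify_stability,
    closed_form_linear_solution,
    enumerate_equilibria,
    rhs,
    solve_pro_subsystem_at_C10,
)

PRINTED_STATE = CytokineState(0.0, 0.623, 0.512, 1.837)


class TestProSubsystem:
    def test_reference_solution_at_basal_il10(self, params):
        # C_10 = alpha_10 / beta_10; hand linear solve gives D = 1.9832584
        sol = solve_pro_subsystem_at_C10(params, 0.005 / 0.35)
        assert sol.C_T == pytest.approx(0.0143790, abs=1e-7)
        assert sol.C_6 == pytest.approx(0.0131170, abs=1e-7)
        assert not sol.nonphysical

    def test_decoupled_limit(self, params):
        p = params.replace(alpha_6=0.0, k_6T=0.0)
        sol = solve_pro_subsystem_at_C10(p, 0.5)
        assert sol.C_6 == 0.0
        assert sol.C_T == pytest.approx(
            p.alpha_T / (p.beta_T + p.gamma_T10 * 0.5))

    def test_singular_subsystem(self, params):
        # k_T6 * k_6T = beta_T * beta_6 at C_10 = 0 makes D = 0
        p = params.replace(k_T6=1.8, k_6T=1.2, gamma_T10=0.0, gamma_610=0.0)
        with pytest.raises(ValueError, match="singular"):
            solve_pro_subsystem_at_C10(p, 0.0)

    def test_monotone_decreasing_in_il10(self, params):
        grid = np.linspace(0.0, 1.0, 101)
        ct = np.array([solve_pro_subsystem_at_C10(params, c).C_T for c in grid])
        c6 = np.array([solve_pro_subsystem_at_C10(params, c).C_6 for c in grid])
        assert np.all(np.diff(ct) < 0)
        assert np.all(np.diff(c6) < 0)


class TestEnumerate:
    def test_reference_post_delay_equilibrium(self, params):
        points = enumerate_equilibria(params, regime="post_delay")
        assert len(points) == 1
        pt = points[0]
        assert pt.state.C_T == pytest.approx(0.014379, abs=1e-6)
        assert pt.state.C_6 == pytest.approx(0.013117, abs=1e-6)
        assert pt.state.C_10 == pytest.approx(0.014286, abs=1e-6)
        assert pt.stability == "stable"
        assert pt.residual_norm <= 1e-10
        assert all(e.real < 0 for e in pt.eigenvalues)

    def test_pre_delay_gate_off(self, params):
        points = enumerate_equilibria(params, regime="pre_delay")
        assert len(points) == 1
        assert points[0].state.C_10 == pytest.approx(0.005 / 0.35, abs=1e-10)

    def test_trivial_origin(self, params):
        p = params.replace(alpha_T=0, alpha_6=0, alpha_10=0,
                           k_T6=0, k_6T=0, k_10T=0, k_106=0)
        points = enumerate_equilibria(p)
        assert len(points) == 1
        assert points[0].state.as_array() == pytest.approx([0, 0, 0], abs=1e-12)

    def test_residuals_reevaluated_through_model(self, params):
        for pt in enumerate_equilibria(params, regime="post_delay"):
            d = rhs(pt.state, params, gate=True).as_array()
            assert np.max(np.abs(d)) <= 1e-10

    def test_scan_points_floor(self, params):
        with pytest.raises(ValueError, match="scan_points"):
            enumerate_equilibria(params, scan_points=50)


class TestJacobian:
    def test_paper_mode_printed_state(self, params):
        res = assemble_jacobian(params, PRINTED_STATE, mode="paper")
        expected = np.array([
            [-1.98370, 0.45, -0.06230],
            [0.40, -1.31022, -0.03072],
            [0.08317, -0.08317, -0.35],
        ])
        np.testing.assert_allclose(res.matrix, expected, atol=1e-5)
        assert np.trace(res.matrix) == pytest.approx(-3.64392, abs=1e-9)

    def test_exact_mode_product_rule_terms(self, params):
        res = assemble_jacobian(params, PRINTED_STATE, mode="exact")
        assert res.matrix[2, 0] == pytest.approx(0.04875, abs=5e-5)
        assert res.matrix[2, 1] == pytest.approx(-0.04689, abs=5e-5)
        paper = assemble_jacobian(params, PRINTED_STATE, mode="paper")
        for e_exact, e_paper in zip(res.eigenvalues, paper.eigenvalues):
            assert abs(e_exact - e_paper) < 5e-3

    def test_paper_mode_requires_pro_dominance(self, params):
        with pytest.raises(ValueError, match="C_T > C_6"):
            assemble_jacobian(params, CytokineState(0.0, 0.1, 0.5, 0.1),
                              mode="paper")

    def test_decoupled_block_structure(self, params):
        p = params.replace(gamma_T10=0, gamma_610=0, k_10T=0, k_106=0)
        res = assemble_jacobian(p, CytokineState(0.0, 1.0, 0.5, 0.2))
        block = np.array([[-p.beta_T, p.k_T6], [p.k_6T, -p.beta_6]])
        expected = sorted(list(np.linalg.eigvals(block)) + [-p.beta_10])
        np.testing.assert_allclose([e.real for e in res.eigenvalues],
                                   sorted(e.real for e in expected), atol=1e-12)

    def test_trace_identity_random(self, rng):
        """Eigenvalue sum equals the analytic trace in both modes."""
        for _ in range(1000):
            p = ParameterSet(
                gamma_T10=rng.uniform(0.01, 0.5), gamma_610=rng.uniform(0.01, 0.5),
                k_10T=rng.uniform(0, 0.5), k_106=rng.uniform(0, 0.5),
                beta_T=rng.uniform(0.5, 3), beta_6=rng.uniform(0.5, 3),
                beta_10=rng.uniform(0.1, 1), hill_n=rng.uniform(1, 8))
            c6 = rng.uniform(0, 1)
            s = CytokineState(0.0, c6 + rng.uniform(0.01, 2), c6, rng.uniform(0, 3))
            for mode in ("exact", "paper"):
                res = assemble_jacobian(p, s, mode=mode)
                trace = -(p.beta_T + p.gamma_T10 * s.C_10) \
                    - (p.beta_6 + p.gamma_610 * s.C_10) - p.beta_10
                assert sum(e.real for e in res.eigenvalues) == \
                    pytest.approx(trace, abs=1e-9)
                assert np.trace(res.matrix) == pytest.approx(trace, abs=1e-12)


class TestStability:
    @pytest.mark.parametrize("eigs, expected", [
        ((-2.19, -1.11, -0.35), "stable"),
        ((-1, 0, -1), "marginal"),
        ((0.2, -1, -1), "unstable"),
        ((-1, 1e-10, -1), "marginal"),
    ])
    def test_classification(self, eigs, expected):
        assert classify_stability(eigs) == expected


class TestClosedForm:
    def test_diagonal_case(self, params):
        p = params.replace(k_T6=0.0, k_6T=0.0, alpha_T=0.0, alpha_6=0.0)
        sub = LinearSubsystem.from_parameters(p, (1.0, 1.0))
        out = closed_form_linear_solution(sub, 2.0)
        np.testing.assert_allclose(
            out, [np.exp(-2 * p.beta_T), np.exp(-2 * p.beta_6)], atol=1e-12)

    def test_t_zero_returns_initial(self, params):
        sub = LinearSubsystem.from_parameters(params, (0.1, 0.05))
        np.testing.assert_allclose(closed_form_linear_solution(sub, 0.0),
                                   [0.1, 0.05], atol=1e-15)

    def test_singular_matrix_rejected(self, params):
        sub = LinearSubsystem(A=np.array([[1.0, 1.0], [1.0, 1.0]]),
                              alpha_vec=np.zeros(2), C0=np.zeros(2))
        with pytest.raises(ValueError, match="singular"):
            closed_form_linear_solution(sub, 1.0)

    def test_randomized_stable_system_fixture(self):
        from cytotriad.fixtures import FixtureSpec, generate_fixture
        fx = generate_fixture(FixtureSpec("linear_2d", seed=7))
        for t in (0.0, 0.5, 3.0):
            np.testing.assert_allclose(
                closed_form_linear_solution(fx.subsystem, t), fx.solution(t),
                atol=1e-12)
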