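"""Spectral-machinery exactness and optimal-control oracles.

The analytic references: LGL nodes/weights have closed forms at small N;
LGL quadrature is exact to degree 2N-1; the differentiation matrix is
exact on polynomials of degree <= N; the minimum-energy double
integrator from (0,0) to (1,0) in unit time has cost 12 with
u(t) = 6 - 12 t, and the scalar integrator from 0 to 1 has cost 1 with
u constant at 1 (Cauchy-Schwarz).
"""

import numpy as np
import pytest

import swdcontrol as sw
from swdcontrol.pseudospectral import (
    CollocationGrid,
    OCProblem,
    interpolate_solution,
    solve,
    transcribe,
    verify_solution,
)


class TestNodes:
    @pytest.mark.parametrize("N,expected", [
        (1, [-1.0, 1.0]),
        (2, [-1.0, 0.0, 1.0]),
        (4, [-1.0, -np.sqrt(3 / 7), 0.0, np.sqrt(3 / 7), 1.0]),
    ])
    def test_closed_forms(self, N, expected):
        assert np.allclose(sw.lgl_nodes(N), expected, atol=1e-14)

    def test_rejects_order_zero(self):
        with pytest.raises(ValueError):
            sw.lgl_nodes(0)

    @pytest.mark.parametrize("N", [3, 8, 17, 40, 80])
    def test_sorted_symmetric_with_endpoints(self, N):
        x = sw.lgl_nodes(N)
        assert x[0] == -1.0 and x[-1] == 1.0
        assert np.all(np.diff(x) > 0)
        assert np.allclose(x, -x[::-1], atol=1e-14)


class TestWeights:
    def test_n2_closed_form(self):
        assert np.allclose(sw.lgl_weights(2), [1 / 3, 4 / 3, 1 / 3], atol=1e-14)

    @pytest.mark.parametrize("N", [2, 5, 12, 40])
    def test_sum_to_two_and_positive(self, N):
        w = sw.lgl_weights(N)
        assert w.sum() == pytest.approx(2.0, abs=1e-12)
        assert np.all(w > 0)
        assert np.allclose(w, w[::-1], atol=1e-13)

    @pytest.mark.parametrize("N", [4, 9, 16])
    def test_quadrature_exact_to_degree_2N_minus_1(self, N):
        x, w = sw.lgl_nodes(N), sw.lgl_weights(N)
        for m in range(2 * N):
            exact = 2.0 / (m + 1) if m % 2 == 0 else 0.0
            assert np.sum(w * x ** m) == pytest.approx(exact, abs=1e-12)


class TestDifferentiationMatrix:
    @pytest.mark.parametrize("N", [3, 7, 16, 40])
    def test_exact_on_polynomials_to_degree_N(self, N):
        x = sw.lgl_nodes(N)
        D = sw.differentiation_matrix(N, x)
        assert np.max(np.abs(D @ np.ones(N + 1))) < 1e-11
        for k in range(1, N + 1):
            err = np.max(np.abs(D @ x ** k - k * x ** (k - 1)))
            assert err < 1e-10 * max(1.0, N ** 2)

    @pytest.mark.parametrize("N", [2, 5, 12])
    def test_corner_entries(self, N):
        D = sw.differentiation_matrix(N)
        assert D[0, 0] == pytest.approx(-N * (N + 1) / 4)
        assert D[N, N] == pytest.approx(N * (N + 1) / 4)

    def test_rows_sum_to_zero(self):
        D = sw.differentiation_matrix(20)
        assert np.max(np.abs(D.sum(axis=1))) < 1e-11


def _double_integrator():
    def F(X, U):
        return np.stack([X[:, 1], U[:, 0]], axis=1)

    def dF(X, U):
        n = len(X)
        A = np.zeros((n, 2, 2))
        A[:, 0, 1] = 1.0
        B = np.zeros((n, 2, 1))
        B[:, 1, 0] = 1.0
        return A, B

    return OCProblem(dynamics=F, dynamics_jacobian=dF, state_dim=2, control_dim=1,
                     t0=0.0, T=1.0, x0=np.array([0.0, 0.0]), xf=np.array([1.0, 0.0]))


def _scalar_integrator():
    def F(X, U):
        return U

    def dF(X, U):
        n = len(X)
        return np.zeros((n, 1, 1)), np.ones((n, 1, 1))

    return OCProblem(dynamics=F, dynamics_jacobian=dF, state_dim=1, control_dim=1,
                     t0=0.0, T=1.0, x0=np.array([0.0]), xf=np.array([1.0]))


class TestTranscription:
    def test_equilibrium_is_feasible_with_zero_objective(self):
        # x' = u with x0 = xf: the constant state, zero control point is feasible
        prob = _scalar_integrator()
        prob.xf = np.array([0.0])
        nlp = transcribe(prob, CollocationGrid.from_order(8))
        z = np.zeros(nlp.n_variables)
        assert np.max(np.abs(nlp.constraints(z))) < 1e-14
        assert nlp.objective(z) == 0.0

    def test_constant_control_solution_admitted(self):
        prob = _scalar_integrator()
        grid = CollocationGrid.from_order(10)
        nlp = transcribe(prob, grid)
        n = grid.n_nodes
        # x(t) = t mapped to tau, u = 1
        z = np.concatenate([(grid.nodes + 1.0) / 2.0, np.ones(n)])
        assert np.max(np.abs(nlp.constraints(z))) < 1e-12
        assert nlp.objective(z) == pytest.approx(1.0, abs=1e-12)

    def test_objective_matches_independent_quadrature(self, rng):
        # u of degree <= N-1 so u^2 stays within the 2N-1 exactness window;
        # reference from numpy's own Gauss-Legendre rule (independent code path)
        prob = _scalar_integrator()
        grid = CollocationGrid.from_order(12)
        nlp = transcribe(prob, grid)
        coeffs = rng.normal(size=9)
        u_nodes = np.polyval(coeffs, grid.nodes)
        z = np.concatenate([np.zeros(grid.n_nodes), u_nodes])
        gx, gw = np.polynomial.legendre.leggauss(64)
        ref = 0.5 * np.sum(gw * np.polyval(coeffs, gx) ** 2)
        assert nlp.objective(z) == pytest.approx(ref, abs=1e-10)

    def test_constraint_jacobian_matches_finite_differences(self, rng):
        prob = _double_integrator()
        grid = CollocationGrid.from_order(6)
        nlp = transcribe(prob, grid)
        z = rng.normal(size=nlp.n_variables)
        J = nlp.constraints_jacobian(z)
        h = 1e-7
        for j in range(nlp.n_variables):
            e = np.zeros(nlp.n_variables)
            e[j] = h
            col = (nlp.constraints(z + e) - nlp.constraints(z - e)) / (2 * h)
            assert np.allclose(J[:, j], col, atol=1e-6)


class TestSolve:
    def test_double_integrator_minimum_energy(self):
        grid = CollocationGrid.from_order(40)
        sol = solve(transcribe(_double_integrator(), grid))
        assert sol.cost == pytest.approx(12.0, rel=1e-6)
        t = (grid.nodes + 1.0) / 2.0
        assert np.max(np.abs(sol.controls_at_nodes[:, 0] - (6.0 - 12.0 * t))) < 1e-4
        assert sol.defect_norm < 1e-8

    def test_scalar_integrator_minimum_energy(self):
        sol = solve(transcribe(_scalar_integrator(), CollocationGrid.from_order(40)))
        assert sol.cost == pytest.approx(1.0, rel=1e-8)
        assert np.max(np.abs(sol.controls_at_nodes - 1.0)) < 1e-5

    def test_spectral_convergence_on_analytic_problem(self):
        costs = [solve(transcribe(_double_integrator(), CollocationGrid.from_order(N))).cost
                 for N in (10, 40)]
        assert abs(costs[0] - costs[1]) < 1e-6

    def test_verification_of_analytic_solution(self):
        sol = solve(transcribe(_double_integrator(), CollocationGrid.from_order(30)))
        rep = verify_solution(sol)
        assert rep.terminal_error < 1e-6
        assert rep.max_path_deviation < 1e-6


class TestInterpolation:
    def test_node_values_reproduced_exactly(self):
        sol = solve(transcribe(_scalar_integrator(), CollocationGrid.from_order(12)))
        prob = sol.problem
        t_nodes = prob.t0 + 0.5 * (prob.T - prob.t0) * (sol.grid.nodes + 1.0)
        for k in (0, 5, 12):
            xs, us = interpolate_solution(sol, t_nodes[k])
            assert np.allclose(xs, sol.states_at_nodes[k], atol=1e-12)
            assert np.allclose(us, sol.controls_at_nodes[k], atol=1e-12)

    def test_polynomial_reproduction(self, rng):
        N = 15
        grid = CollocationGrid.from_order(N)
        prob = _scalar_integrator()
        for k in (3, 9, N):
            vals = ((grid.nodes + 1) / 2) ** k
            sol_like = solve(transcribe(prob, grid))
            sol_like.states_at_nodes = vals[:, None]
            ts = rng.uniform(0, 1, size=50)
            xs, _ = interpolate_solution(sol_like, ts)
            assert np.max(np.abs(np.asarray(xs).ravel() - ts ** k)) < 1e-10

    def test_outside_window_rejected(self):
        sol = solve(transcribe(_scalar_integrator(), CollocationGrid.from_order(8)))
        with pytest.raises(ValueError):
            interpolate_solution(sol, 1.5)


class TestSerialization:
    def test_solution_json_round_trip(self, tmp_path):
        sol = solve(transcribe(_scalar_integrator(), CollocationGrid.from_order(8)))
        path = tmp_path / "sol.json"
        sol.save(path)
        import json
        d = json.loads(path.read_text())
        assert d["cost"] == pytest.approx(1.0, abs=1e-8)
        assert np.allclose(d["nodes"], sol.grid.nodes)
        assert d["problem"]["state_dim"] == 1
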