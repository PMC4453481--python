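"""Legendre-Gauss-Lobatto collocation and direct transcription of
minimum-energy optimal control problems.

States and controls are represented by their values at the N+1 LGL
nodes (the roots of (1 - x^2) L'_N(x)); Lagrange interpolation through
those values gives the continuous trajectory, and the differentiation
matrix D turns the ODE constraint into algebraic collocation defects

    D X = (T - t0)/2 * F(X, U)    (rowwise at every node),

with the affine map between physical time t in [t0, T] and the spectral
coordinate tau in [-1, 1].  The cost is the LGL quadrature of |u|^2.
The resulting nonlinear program is solved with SLSQP using the analytic
objective gradient and an analytic constraint Jacobian assembled from
the dynamics Jacobian.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from numpy.polynomial import legendre as npleg
from scipy.integrate import solve_ivp
from scipy.interpolate import BarycentricInterpolator
from scipy.optimize import NonlinearConstraint, minimize


def _barycentric(nodes: np.ndarray, values: np.ndarray) -> BarycentricInterpolator:
    # fixed rng: scipy permutes points randomly when computing barycentric
    # weights, which would make interpolation (and everything downstream)
    # nondeterministic at the 1e-6 level
    return BarycentricInterpolator(nodes, values, rng=np.random.default_rng(0))


#: Default polynomial order: 81 collocation nodes.
DEFAULT_ORDER = 80


def lgl_nodes(N: int, tol: float = 1e-14) -> np.ndarray:
    """The N+1 Legendre-Gauss-Lobatto nodes in [-1, 1].

    Endpoints +-1 plus the roots of L'_N, found by Newton iteration from
    Chebyshev-Gauss-Lobatto initial guesses.
    """
    if N < 1:
        raise ValueError(f"order N must be >= 1, got {N}")
    if N == 1:
        return np.array([-1.0, 1.0])
    cN = np.zeros(N + 1)
    cN[N] = 1.0
    d1 = npleg.legder(cN)
    d2 = npleg.legder(cN, 2)
    # interior initial guesses: Chebyshev-Lobatto points
    x = -np.cos(np.pi * np.arange(1, N) / N)
    for _ in range(100):
        dx = -npleg.legval(x, d1) / npleg.legval(x, d2)
        x = x + dx
        if np.max(np.abs(dx)) < tol:
            break
    x = np.sort(x)
    # enforce exact antisymmetry
    x = 0.5 * (x - x[::-1])
    return np.concatenate(([-1.0], x, [1.0]))


def lgl_weights(N: int, nodes: np.ndarray | None = None) -> np.ndarray:
    """LGL quadrature weights w_k = 2 / (N (N+1) L_N(x_k)^2)."""
    x = lgl_nodes(N) if nodes is None else np.asarray(nodes, dtype=float)
    if x.size != N + 1:
        raise ValueError(f"expected {N + 1} nodes, got {x.size}")
    cN = np.zeros(N + 1)
    cN[N] = 1.0
    LN = npleg.legval(x, cN)
    return 2.0 / (N * (N + 1) * LN ** 2)


def differentiation_matrix(N: int, nodes: np.ndarray | None = None) -> np.ndarray:
    """LGL differentiation matrix: (D p(nodes)) = p'(nodes) exactly for
    polynomials p of degree <= N."""
    x = lgl_nodes(N) if nodes is None else np.asarray(nodes, dtype=float)
    cN = np.zeros(N + 1)
    cN[N] = 1.0
    LN = npleg.legval(x, cN)
    D = np.zeros((N + 1, N + 1))
    for i in range(N + 1):
        for j in range(N + 1):
            if i != j:
                D[i, j] = LN[i] / (LN[j] * (x[i] - x[j]))
    D[0, 0] = -N * (N + 1) / 4.0
    D[N, N] = N * (N + 1) / 4.0
    return D


@dataclass(frozen=True)
class CollocationGrid:
    """Nodes, quadrature weights and differentiation matrix for order N."""

    order: int
    nodes: np.ndarray
    weights: np.ndarray
    diff_matrix: np.ndarray

    @classmethod
    def from_order(cls, N: int = DEFAULT_ORDER) -> "CollocationGrid":
        x = lgl_nodes(N)
        return cls(order=N, nodes=x, weights=lgl_weights(N, x),
                   diff_matrix=differentiation_matrix(N, x))

    @property
    def n_nodes(self) -> int:
        return self.order + 1


# dynamics: F(X, U) -> (n_nodes, state_dim); jacobian: (A, B) with
# A[k] = dF/dx (state_dim, state_dim), B[k] = dF/du (state_dim, control_dim)
Dynamics = Callable[[np.ndarray, np.ndarray], np.ndarray]
DynamicsJacobian = Callable[[np.ndarray, np.ndarray], tuple[np.ndarray, np.ndarray]]


@dataclass
class OCProblem:
    """Fixed-endpoint minimum-energy transfer over [t0, T]."""

    dynamics: Dynamics
    state_dim: int
    control_dim: int
    t0: float
    T: float
    x0: np.ndarray
    xf: np.ndarray
    dynamics_jacobian: DynamicsJacobian | None = None
    control_bounds: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.T <= self.t0:
            raise ValueError("T must exceed t0")
        self.x0 = np.asarray(self.x0, dtype=float)
        self.xf = np.asarray(self.xf, dtype=float)
        if self.x0.shape != (self.state_dim,) or self.xf.shape != (self.state_dim,):
            raise ValueError("x0/xf must have length state_dim")


@dataclass
class TranscribedNLP:
    """Objective/constraint callables over z = [X.ravel(), U.ravel()]."""

    problem: OCProblem
    grid: CollocationGrid
    objective: Callable[[np.ndarray], float]
    gradient: Callable[[np.ndarray], np.ndarray]
    constraints: Callable[[np.ndarray], np.ndarray]
    constraints_jacobian: Callable[[np.ndarray], np.ndarray] | str
    n_variables: int
    initial_guess: np.ndarray

    def split(self, z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        n = self.grid.n_nodes
        sd, cd = self.problem.state_dim, self.problem.control_dim
        return z[: n * sd].reshape(n, sd), z[n * sd:].reshape(n, cd)


@dataclass
class OCSolution:
    """Optimized node values, quadrature cost and residual diagnostics."""

    grid: CollocationGrid
    problem: OCProblem
    states_at_nodes: np.ndarray     # (n_nodes, state_dim)
    controls_at_nodes: np.ndarray   # (n_nodes, control_dim)
    cost: float
    status: int
    message: str
    defect_norm: float
    boundary_error: float

    @property
    def converged(self) -> bool:
        return self.defect_norm < 1e-6 and self.boundary_error < 1e-6

    def to_dict(self) -> dict:
        """JSON-ready representation (nodes, weights, node values, cost,
        status and problem metadata)."""
        prob = self.problem
        return {
            "order": self.grid.order,
            "nodes": self.grid.nodes.tolist(),
            "weights": self.grid.weights.tolist(),
            "states_at_nodes": self.states_at_nodes.tolist(),
            "controls_at_nodes": self.controls_at_nodes.tolist(),
            "cost": self.cost,
            "status": self.status,
            "message": self.message,
            "defect_norm": self.defect_norm,
            "boundary_error": self.boundary_error,
            "problem": {
                "state_dim": prob.state_dim,
                "control_dim": prob.control_dim,
                "t0": prob.t0,
                "T": prob.T,
                "x0": prob.x0.tolist(),
                "xf": prob.xf.tolist(),
                "control_bounds": prob.control_bounds,
            },
        }

    def save(self, path) -> None:
        import json
        from pathlib import Path

        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


def transcribe(problem: OCProblem, grid: CollocationGrid) -> TranscribedNLP:
    """Discretize the optimal control problem into a nonlinear program.

    Decision variables are the state and control values at the nodes;
    the objective is the LGL quadrature of |u|^2 scaled by (T-t0)/2, and
    the constraints stack the collocation defects with the two boundary
    conditions.
    """
    n = grid.n_nodes
    sd, cd = problem.state_dim, problem.control_dim
    half = 0.5 * (problem.T - problem.t0)
    D, w = grid.diff_matrix, grid.weights
    nz = n * (sd + cd)

    def split(z):
        return z[: n * sd].reshape(n, sd), z[n * sd:].reshape(n, cd)

    def objective(z) -> float:
        _, U = split(z)
        return half * float(np.sum(w[:, None] * U ** 2))

    def gradient(z) -> np.ndarray:
        _, U = split(z)
        g = np.zeros(nz)
        g[n * sd:] = (2.0 * half * w[:, None] * U).ravel()
        return g

    def constraints(z) -> np.ndarray:
        X, U = split(z)
        F = problem.dynamics(X, U)
        if F.shape != (n, sd):
            raise ValueError(f"dynamics returned shape {F.shape}, expected {(n, sd)}")
        defect = D @ X - half * F
        return np.concatenate([defect.ravel(), X[0] - problem.x0, X[-1] - problem.xf])

    if problem.dynamics_jacobian is not None:

        def constraints_jacobian(z) -> np.ndarray:
            X, U = split(z)
            A, B = problem.dynamics_jacobian(X, U)
            J = np.zeros((n * sd + 2 * sd, nz))
            # differentiation-matrix part: defect row (k, d) couples X[:, d]
            for d in range(sd):
                J[d: n * sd: sd, d: n * sd: sd] += D
            for k in range(n):
                rows = slice(k * sd, (k + 1) * sd)
                J[rows, k * sd: (k + 1) * sd] += -half * A[k]
                J[rows, n * sd + k * cd: n * sd + (k + 1) * cd] = -half * B[k]
            for d in range(sd):
                J[n * sd + d, d] = 1.0
                J[n * sd + sd + d, (n - 1) * sd + d] = 1.0
            return J

        jac = constraints_jacobian
    else:
        jac = "2-point"

    z0 = np.zeros(nz)
    z0[: n * sd] = np.linspace(problem.x0, problem.xf, n).ravel()
    return TranscribedNLP(problem=problem, grid=grid, objective=objective,
                          gradient=gradient, constraints=constraints,
                          constraints_jacobian=jac, n_variables=nz,
                          initial_guess=z0)


def solve(
    nlp: TranscribedNLP,
    initial_guess: np.ndarray | None = None,
    max_iter: int = 800,
    ftol: float = 1e-12,
) -> OCSolution:
    """Solve the transcribed NLP with SLSQP and report residuals.

    A nonconverged iterate is still returned (flagged by ``status``);
    callers should check ``defect_norm`` and ``boundary_error``.
    """
    z0 = nlp.initial_guess if initial_guess is None else np.asarray(initial_guess, float)
    if z0.size != nlp.n_variables:
        raise ValueError(f"guess has size {z0.size}, expected {nlp.n_variables}")
    cons = [NonlinearConstraint(nlp.constraints, 0.0, 0.0, jac=nlp.constraints_jacobian)]
    bounds = None
    prob = nlp.problem
    if prob.control_bounds is not None:
        lo, hi = prob.control_bounds
        n, sd, cd = nlp.grid.n_nodes, prob.state_dim, prob.control_dim
        bounds = [(None, None)] * (n * sd) + [(lo, hi)] * (n * cd)
    res = minimize(nlp.objective, z0, jac=nlp.gradient, constraints=cons,
                   bounds=bounds, method="SLSQP",
                   options={"maxiter": max_iter, "ftol": ftol})
    X, U = nlp.split(res.x)
    c = nlp.constraints(res.x)
    n_defect = nlp.grid.n_nodes * prob.state_dim
    defect_norm = float(np.max(np.abs(c[:n_defect])))
    boundary_error = float(np.max(np.abs(c[n_defect:])))
    return OCSolution(grid=nlp.grid, problem=prob, states_at_nodes=X,
                      controls_at_nodes=U, cost=float(res.fun), status=int(res.status),
                      message=str(res.message), defect_norm=defect_norm,
                      boundary_error=boundary_error)


def _to_tau(sol: OCSolution, t: float | np.ndarray) -> np.ndarray:
    prob = sol.problem
    return 2.0 * (np.asarray(t, dtype=float) - prob.t0) / (prob.T - prob.t0) - 1.0


def interpolate_solution(sol: OCSolution, t: float | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Barycentric Lagrange evaluation of states and controls at time(s) t."""
    tau = _to_tau(sol, t)
    if np.any(tau < -1 - 1e-12) or np.any(tau > 1 + 1e-12):
        raise ValueError("t outside the control window")
    tau = np.clip(tau, -1.0, 1.0)
    xs = _barycentric(sol.grid.nodes, sol.states_at_nodes)(tau)
    us = _barycentric(sol.grid.nodes, sol.controls_at_nodes)(tau)
    return xs, us


def control_interpolant(sol: OCSolution, n_fine: int = 4001) -> Callable[[float], np.ndarray]:
    """Fast control lookup: dense barycentric evaluation, linear in between,
    zero outside [t0, T]."""
    prob = sol.problem
    tf = np.linspace(prob.t0, prob.T, n_fine)
    uf = _barycentric(sol.grid.nodes, sol.controls_at_nodes)(_to_tau(sol, tf))
    uf = np.atleast_2d(np.asarray(uf))
    if uf.shape[0] != n_fine:
        uf = uf.T

    def u_of_t(t):
        t = np.asarray(t, dtype=float)
        inside = (t >= prob.t0) & (t <= prob.T)
        out = np.zeros(t.shape + (prob.control_dim,))
        if np.any(inside):
            ti = np.clip(t, prob.t0, prob.T)
            for c in range(prob.control_dim):
                vals = np.interp(ti, tf, uf[:, c])
                out[..., c] = np.where(inside, vals, 0.0)
        return out if out.ndim > 1 else out

    return u_of_t


@dataclass(frozen=True)
class VerificationReport:
    terminal_error: float
    max_path_deviation: float


def verify_solution(
    sol: OCSolution,
    problem: OCProblem | None = None,
    rtol: float = 1e-10,
    atol: float = 1e-12,
) -> VerificationReport:
    """Closed-loop check: integrate the true dynamics from x0 under the
    interpolated control with an independent adaptive integrator.

    Reports the distance of the terminal state from xf and the maximum
    deviation from the collocation state trajectory at the nodes.
    """
    prob = sol.problem if problem is None else problem
    u_of_t = control_interpolant(sol)

    def rhs(t, y):
        X = y[None, :]
        U = np.atleast_2d(u_of_t(float(t)))
        return prob.dynamics(X, U)[0]

    t_nodes = prob.t0 + 0.5 * (prob.T - prob.t0) * (sol.grid.nodes + 1.0)
    res = solve_ivp(rhs, (prob.t0, prob.T), prob.x0, t_eval=t_nodes,
                    rtol=rtol, atol=atol, max_step=(prob.T - prob.t0) / 50)
    if not res.success:
        raise RuntimeError(f"verification integration failed: {res.message}")
    path_dev = float(np.max(np.abs(res.y.T - sol.states_at_nodes)))
    terminal_error = float(np.linalg.norm(res.y[:, -1] - prob.xf))
    return VerificationReport(terminal_error=terminal_error, max_path_deviation=path_dev)
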