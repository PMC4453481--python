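"""Single-area cortico-thalamic vector field, network extension, and
fixed-point / stability analysis.

The model couples an excitatory pyramidal (PY) and inhibitory
interneuron (IN) cortical pair to thalamocortical relay (TC) and
reticular nucleus (RE) populations:

    dPY/dt = tau1 (h_py - PY + C1 f[PY] - C3 f[IN] + C9 f[TC]) + u(t)
    dIN/dt = tau2 (h_in - IN + C2 f[PY]) + u(t)
    dTC/dt = tau3 (h_tc - TC - C6 s[RE] + C7 f[PY])
    dRE/dt = tau4 (h_re - RE - C4 s[RE] + C5 s[TC] + C8 f[PY])

with the steep sigmoid f[x] = 1 / (1 + epsilon^(-x)) on cortical inputs,
the linear activation s[x] = a x + b inside the thalamic subsystem, and
the stimulus u(t) entering the two cortical equations additively.

States are numpy arrays ordered (PY, IN, TC, RE); :data:`STATE_LABELS`
gives the canonical names.  In the multi-area extension, long-range
excitatory PY<->PY coupling through a connectivity matrix M adds
``alpha * sum_j M_ij f[PY_j]`` inside the tau1 parenthesis of area i.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .params import ModelParameters

STATE_LABELS = ("PY", "IN", "TC", "RE")
PY, IN, TC, RE = 0, 1, 2, 3


class CorticothalamicState(NamedTuple):
    """Named view of one area's activity vector (all finite, dimensionless)."""

    py: float
    in_: float
    tc: float
    re: float

    @classmethod
    def from_array(cls, x: np.ndarray) -> "CorticothalamicState":
        x = np.asarray(x, dtype=float)
        if x.shape != (4,) or not np.all(np.isfinite(x)):
            raise ValueError("state must be a finite length-4 vector")
        return cls(*map(float, x))

    def as_array(self) -> np.ndarray:
        return np.array(self, dtype=float)

# exp argument clip; exp(+-500) is far outside float overflow-free range for
# downstream products, and the sigmoid is constant to machine precision there
_CLIP = 500.0


@dataclass(frozen=True)
class NetworkParameters:
    """Shared single-area parameters plus long-range coupling.

    ``weights`` is the square, symmetric, zero-diagonal coupling matrix
    (typically FA-weighted structural connectivity) and ``alpha`` the
    global gain on the long-range excitatory PY->PY term.
    """

    base: ModelParameters
    weights: np.ndarray
    alpha: float = 1.0

    def __post_init__(self) -> None:
        W = np.asarray(self.weights, dtype=float)
        if W.ndim != 2 or W.shape[0] != W.shape[1]:
            raise ValueError(f"coupling matrix must be square, got shape {W.shape}")
        if self.alpha < 0:
            raise ValueError(f"alpha must be >= 0, got {self.alpha}")
        W = W.copy()
        np.fill_diagonal(W, 0.0)  # no self-coupling
        object.__setattr__(self, "weights", W)

    @property
    def n_areas(self) -> int:
        return self.weights.shape[0]


@dataclass(frozen=True)
class StabilityReport:
    fixed_point: np.ndarray
    eigenvalues: np.ndarray
    classification: str  # stable_focus | stable_node | unstable | center


def sigmoid(x, epsilon: float):
    """Sigmoid activation f[x] = 1 / (1 + epsilon^(-x)), range (0, 1)."""
    if epsilon <= 1:
        raise ValueError(f"epsilon must be > 1, got {epsilon}")
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("sigmoid input must be finite")
    z = np.clip(x * np.log(epsilon), -_CLIP, _CLIP)
    out = 1.0 / (1.0 + np.exp(-z))
    return out if out.ndim else float(out)


def sigmoid_deriv(x, epsilon: float):
    """d/dx of :func:`sigmoid`: ln(epsilon) * f * (1 - f)."""
    f = np.asarray(sigmoid(x, epsilon))
    out = np.log(epsilon) * f * (1.0 - f)
    return out if out.ndim else float(out)


def linear_activation(x, a: float, b: float):
    """Linear activation s[x] = a*x + b used in the thalamic subsystem."""
    return a * np.asarray(x, dtype=float) + b if np.ndim(x) else a * x + b


def vector_field(state: np.ndarray, p: ModelParameters, u: float = 0.0) -> np.ndarray:
    """Time derivative of one cortico-thalamic area.

    ``u`` is the stimulus, added to the PY and IN derivatives only.
    """
    state = np.asarray(state, dtype=float)
    if state.shape != (4,):
        raise ValueError(f"state must have shape (4,), got {state.shape}")
    if not np.all(np.isfinite(state)):
        raise ValueError("state must be finite")
    py, in_, tc, re = state
    f = lambda x: sigmoid(x, p.epsilon)
    s = lambda x: p.a * x + p.b
    return np.array([
        p.tau1 * (p.h_py - py + p.C1 * f(py) - p.C3 * f(in_) + p.C9 * f(tc)) + u,
        p.tau2 * (p.h_in - in_ + p.C2 * f(py)) + u,
        p.tau3 * (p.h_tc - tc - p.C6 * s(re) + p.C7 * f(py)),
        p.tau4 * (p.h_re - re - p.C4 * s(re) + p.C5 * s(tc) + p.C8 * f(py)),
    ])


def jacobian(state: np.ndarray, p: ModelParameters) -> np.ndarray:
    """Analytic Jacobian of :func:`vector_field` (independent of u)."""
    state = np.asarray(state, dtype=float)
    py, in_, tc, re = state
    fp = lambda x: sigmoid_deriv(x, p.epsilon)
    J = np.zeros((4, 4))
    J[PY, PY] = p.tau1 * (-1.0 + p.C1 * fp(py))
    J[PY, IN] = -p.tau1 * p.C3 * fp(in_)
    J[PY, TC] = p.tau1 * p.C9 * fp(tc)
    J[IN, PY] = p.tau2 * p.C2 * fp(py)
    J[IN, IN] = -p.tau2
    J[TC, PY] = p.tau3 * p.C7 * fp(py)
    J[TC, TC] = -p.tau3
    J[TC, RE] = -p.tau3 * p.C6 * p.a
    J[RE, PY] = p.tau4 * p.C8 * fp(py)
    J[RE, TC] = p.tau4 * p.C5 * p.a
    J[RE, RE] = p.tau4 * (-1.0 - p.C4 * p.a)
    return J


def network_vector_field(
    states: np.ndarray, netp: NetworkParameters, u: np.ndarray | float = 0.0
) -> np.ndarray:
    """Time derivatives for ``n`` coupled areas.

    ``states`` has shape (n, 4); ``u`` is scalar or length-n, with u_i
    added to PY_i and IN_i.  Long-range excitatory coupling
    ``alpha * sum_j M_ij f[PY_j]`` enters inside the tau1 parenthesis of
    the PY_i equation.
    """
    X = np.asarray(states, dtype=float)
    n = netp.n_areas
    if X.shape != (n, 4):
        raise ValueError(f"states must have shape ({n}, 4), got {X.shape}")
    if not np.all(np.isfinite(X)):
        raise ValueError("states must be finite")
    uvec = np.broadcast_to(np.asarray(u, dtype=float), (n,))
    p = netp.base
    py, in_, tc, re = X[:, PY], X[:, IN], X[:, TC], X[:, RE]
    f = lambda x: sigmoid(x, p.epsilon)
    s = lambda x: p.a * x + p.b
    coupling = netp.alpha * (netp.weights @ f(py))
    out = np.empty_like(X)
    out[:, PY] = p.tau1 * (p.h_py - py + p.C1 * f(py) - p.C3 * f(in_)
                           + p.C9 * f(tc) + coupling) + uvec
    out[:, IN] = p.tau2 * (p.h_in - in_ + p.C2 * f(py)) + uvec
    out[:, TC] = p.tau3 * (p.h_tc - tc - p.C6 * s(re) + p.C7 * f(py))
    out[:, RE] = p.tau4 * (p.h_re - re - p.C4 * s(re) + p.C5 * s(tc) + p.C8 * f(py))
    return out


def network_jacobian(states: np.ndarray, netp: NetworkParameters) -> np.ndarray:
    """Analytic Jacobian of the flattened coupled system, shape (4n, 4n).

    State ordering follows ``states.reshape(-1)`` (area-major).
    """
    X = np.asarray(states, dtype=float)
    n = netp.n_areas
    p = netp.base
    J = np.zeros((4 * n, 4 * n))
    fp_py = sigmoid_deriv(X[:, PY], p.epsilon)
    for i in range(n):
        J[4 * i:4 * i + 4, 4 * i:4 * i + 4] = jacobian(X[i], p)
        # cross-area term: d PY_i' / d PY_j = tau1 alpha M_ij f'(PY_j)
        for j in range(n):
            if i != j and netp.weights[i, j] != 0.0:
                J[4 * i + PY, 4 * j + PY] += p.tau1 * netp.alpha * netp.weights[i, j] * fp_py[j]
    return J


def find_fixed_point(
    p: ModelParameters,
    guess: np.ndarray,
    tol: float = 1e-12,
    max_iter: int = 100,
) -> np.ndarray:
    """Damped Newton solve of vector_field(x, p, 0) = 0.

    Raises ``RuntimeError`` with the final residual if the iteration does
    not reach ``tol`` within ``max_iter`` steps.
    """
    x = np.asarray(guess, dtype=float).copy()
    if x.shape != (4,) or not np.all(np.isfinite(x)):
        raise ValueError("guess must be a finite length-4 vector")
    for _ in range(max_iter):
        r = vector_field(x, p, 0.0)
        if np.max(np.abs(r)) < tol:
            return x
        step = np.linalg.solve(jacobian(x, p), -r)
        lam, r0 = 1.0, np.max(np.abs(r))
        while lam > 1e-10:
            xn = x + lam * step
            if np.max(np.abs(vector_field(xn, p, 0.0))) < r0:
                break
            lam *= 0.5
        x = x + lam * step
    r = vector_field(x, p, 0.0)
    if np.max(np.abs(r)) < tol:
        return x
    raise RuntimeError(
        f"fixed-point iteration did not converge: residual {np.max(np.abs(r)):.3e}"
    )


def find_network_fixed_point(
    netp: NetworkParameters,
    guess: np.ndarray,
    tol: float = 1e-12,
    max_iter: int = 100,
) -> np.ndarray:
    """Damped Newton solve of the coupled system; guess/result shape (n, 4)."""
    n = netp.n_areas
    x = np.asarray(guess, dtype=float).reshape(n, 4).copy()
    for _ in range(max_iter):
        r = network_vector_field(x, netp, 0.0).reshape(-1)
        if np.max(np.abs(r)) < tol:
            return x
        step = np.linalg.solve(network_jacobian(x, netp), -r).reshape(n, 4)
        lam, r0 = 1.0, np.max(np.abs(r))
        while lam > 1e-10:
            xn = x + lam * step
            if np.max(np.abs(network_vector_field(xn, netp, 0.0))) < r0:
                break
            lam *= 0.5
        x = x + lam * step
    r = network_vector_field(x, netp, 0.0).reshape(-1)
    if np.max(np.abs(r)) < tol:
        return x
    raise RuntimeError(
        f"network fixed-point iteration did not converge: residual {np.max(np.abs(r)):.3e}"
    )


def _rest_given_py(py: float, p: ModelParameters) -> tuple[float, float, float]:
    """IN, TC, RE at equilibrium as functions of PY.

    The IN equation is explicit in PY; the TC/RE equations are linear in
    (TC, RE) once f[PY] is known, so equilibria reduce to a scalar root
    problem in PY.
    """
    f_py = sigmoid(py, p.epsilon)
    in_ = p.h_in + p.C2 * f_py
    A = np.array([[-1.0, -p.C6 * p.a], [p.C5 * p.a, -(1.0 + p.C4 * p.a)]])
    rhs = -np.array([
        p.h_tc - p.C6 * p.b + p.C7 * f_py,
        p.h_re - p.C4 * p.b + p.C5 * p.b + p.C8 * f_py,
    ])
    tc, re = np.linalg.solve(A, rhs)
    return float(in_), float(tc), float(re)


def find_all_fixed_points(
    p: ModelParameters,
    py_range: tuple[float, float] = (-4.0, 2.0),
    n_grid: int = 2001,
) -> list[np.ndarray]:
    """All equilibria with PY in ``py_range``, via the scalar reduction.

    Robust against the steepness of the sigmoid: brackets sign changes of
    the PY residual on a grid and polishes each with Brent's method.
    """
    from scipy.optimize import brentq

    def resid(py: float) -> float:
        in_, tc, _ = _rest_given_py(py, p)
        return (p.h_py - py + p.C1 * sigmoid(py, p.epsilon)
                - p.C3 * sigmoid(in_, p.epsilon) + p.C9 * sigmoid(tc, p.epsilon))

    grid = np.linspace(*py_range, n_grid)
    vals = np.array([resid(g) for g in grid])
    out: list[np.ndarray] = []
    for i in range(n_grid - 1):
        if vals[i] == 0.0 or vals[i] * vals[i + 1] < 0:
            py = brentq(resid, grid[i], grid[i + 1], xtol=1e-15)
            x = np.array([py, *_rest_given_py(py, p)])
            out.append(find_fixed_point(p, x))
    return out


def background_state(p: ModelParameters) -> np.ndarray:
    """The stable background equilibrium (focus or node).

    Raises ``RuntimeError`` if no linearly stable equilibrium exists,
    e.g. past the Hopf bifurcation where only the SWD attractor remains.
    """
    for x in find_all_fixed_points(p):
        ev = np.linalg.eigvals(jacobian(x, p))
        if np.max(ev.real) < 0:
            return x
    raise RuntimeError("no stable equilibrium found (monostable oscillatory regime?)")


def linear_stability(
    p: ModelParameters, fp: np.ndarray, residual_tol: float = 1e-8
) -> StabilityReport:
    """Eigenvalue classification of a fixed point of the single-area model."""
    fp = np.asarray(fp, dtype=float)
    res = np.max(np.abs(vector_field(fp, p, 0.0)))
    if res > residual_tol:
        raise ValueError(f"not a fixed point: residual {res:.3e} > {residual_tol:.1e}")
    ev = np.linalg.eigvals(jacobian(fp, p))
    max_re = float(np.max(ev.real))
    tol = 1e-9
    if max_re > tol:
        cls = "unstable"
    elif max_re > -tol:
        cls = "center"
    elif np.any(np.abs(ev.imag) > tol):
        cls = "stable_focus"
    else:
        cls = "stable_node"
    return StabilityReport(fixed_point=fp, eigenvalues=ev, classification=cls)
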