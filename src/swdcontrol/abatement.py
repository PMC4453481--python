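"""End-to-end seizure-abatement experiments.

A control is designed once, offline, as a minimum-energy transfer from a
trigger state on the spike-wave limit cycle to the background focus,
with the same scalar stimulus entering PY and IN.  At run time the
discharge is detected when (PY, IN) passes the trigger box and the
stored waveform is replayed open loop.  Experiments cover the
deterministic bistable case (induced seizure), the stochastic case
(spontaneous, noise-driven seizures; paired runs share the identical
noise path so duration differences are attributable to the control),
and the connectome-coupled network case with one joint optimal control
problem over all areas.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .model import (
    NetworkParameters,
    background_state,
    find_network_fixed_point,
    jacobian,
    network_vector_field,
    sigmoid,
    vector_field,
)
from .params import ModelParameters
from .pseudospectral import (
    CollocationGrid,
    OCProblem,
    OCSolution,
    VerificationReport,
    control_interpolant,
    solve,
    transcribe,
    verify_solution,
)
from .simulate import (
    DEFAULT_DT,
    DEFAULT_NOISE,
    OSCILLATION_FRACTION,
    SimulationConfig,
    StimulusEvent,
    TimeSeries,
    integrate_deterministic,
)
from .trigger import LimitCycle, TriggerPoint, default_seed_state, detect_trigger, extract_limit_cycle

#: Default control horizon (s); chosen by the robustness scan documented in
#: docs/methods.md.
DEFAULT_HORIZON = 0.2

#: Default collocation order for abatement designs.  A moderate order plus
#: the shooting correction lands on the robust local branch; see
#: docs/methods.md for the branch analysis.
DEFAULT_ORDER = 40

#: Success radius as a fraction of the trigger-to-focus distance.
SUCCESS_RADIUS_FRACTION = 0.05

#: Observation window after control end (s) for deterministic scoring.
POST_CONTROL_WINDOW = 2.0


def single_area_dynamics(p: ModelParameters):
    """Vectorized node dynamics and Jacobian for the shared-control OCP.

    X has shape (n_nodes, 4), U shape (n_nodes, 1); the one control
    enters both the PY and IN rows.
    """

    def F(X: np.ndarray, U: np.ndarray) -> np.ndarray:
        py, in_, tc, re = X[:, 0], X[:, 1], X[:, 2], X[:, 3]
        u = U[:, 0]
        f = lambda x: sigmoid(x, p.epsilon)
        s = lambda x: p.a * x + p.b
        return np.stack([
            p.tau1 * (p.h_py - py + p.C1 * f(py) - p.C3 * f(in_) + p.C9 * f(tc)) + u,
            p.tau2 * (p.h_in - in_ + p.C2 * f(py)) + u,
            p.tau3 * (p.h_tc - tc - p.C6 * s(re) + p.C7 * f(py)),
            p.tau4 * (p.h_re - re - p.C4 * s(re) + p.C5 * s(tc) + p.C8 * f(py)),
        ], axis=1)

    def dF(X: np.ndarray, U: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        n = X.shape[0]
        A = np.array([jacobian(X[k], p) for k in range(n)])
        B = np.zeros((n, 4, 1))
        B[:, 0, 0] = 1.0
        B[:, 1, 0] = 1.0
        return A, B

    return F, dF


def network_dynamics(netp: NetworkParameters):
    """Node dynamics and Jacobian for the joint network OCP.

    X has shape (n_nodes, 4 n_areas) (area-major flattening), U shape
    (n_nodes, n_areas); u_i enters PY_i and IN_i.
    """
    na = netp.n_areas

    def F(X: np.ndarray, U: np.ndarray) -> np.ndarray:
        return np.stack([
            network_vector_field(X[k].reshape(na, 4), netp, U[k]).reshape(-1)
            for k in range(X.shape[0])
        ])

    from .model import network_jacobian

    def dF(X: np.ndarray, U: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        n = X.shape[0]
        A = np.array([network_jacobian(X[k].reshape(na, 4), netp) for k in range(n)])
        B = np.zeros((n, 4 * na, na))
        for i in range(na):
            B[:, 4 * i + 0, i] = 1.0
            B[:, 4 * i + 1, i] = 1.0
        return A, B

    return F, dF


def shooting_polish(
    dynamics_rhs: Callable[[float, np.ndarray, np.ndarray], np.ndarray],
    jacobian_fn: Callable[[np.ndarray], np.ndarray],
    control_map: np.ndarray,
    times: np.ndarray,
    u_values: np.ndarray,
    x0: np.ndarray,
    xf: np.ndarray,
    n_iter: int = 6,
    tol: float = 1e-8,
) -> tuple[np.ndarray, float, np.ndarray]:
    """Indirect-shooting refinement of a collocation control.

    A direct collocation solution satisfies the dynamics only at the
    nodes; its continuous-time flow can land off the target.  This
    correction integrates the state together with the state-transition
    matrix Phi(t, 0) along the controlled trajectory and, per iteration,
    adds the minimum-norm control perturbation cancelling the terminal
    error, obtained from the controllability Gramian
    G = int Phi(T,s) B B' Phi(T,s)' ds.  Convergence is quadratic near a
    feasible trajectory and the energy change is second order.

    ``control_map`` is the input matrix B of shape (state_dim, control_dim);
    ``u_values`` has shape (n_times, control_dim).  Returns the corrected
    control values, the final terminal error, and the monodromy Phi(T, 0).
    """
    times = np.asarray(times, float)
    u = np.asarray(u_values, float).copy()
    if u.ndim == 1:
        u = u[:, None]
    sd = x0.size
    B = np.asarray(control_map, float).reshape(sd, -1)
    T = times[-1] - times[0]

    def forward(u_cur: np.ndarray):
        def rhs(t: float, y: np.ndarray):
            x = y[:sd]
            Phi = y[sd:].reshape(sd, sd)
            uk = np.array([np.interp(t, times, u_cur[:, c]) for c in range(u_cur.shape[1])])
            J = jacobian_fn(x)
            return np.concatenate([dynamics_rhs(t, x, uk), (J @ Phi).ravel()])

        y0 = np.concatenate([x0, np.eye(sd).ravel()])
        s = solve_ivp(rhs, (times[0], times[-1]), y0, t_eval=times,
                      rtol=1e-10, atol=1e-12, max_step=max(T / 200, 1e-4))
        if not s.success:
            raise RuntimeError(f"shooting integration failed: {s.message}")
        return s.y[:sd].T, s.y[sd:].T.reshape(-1, sd, sd)

    err = np.inf
    X = Phis = None
    for _ in range(n_iter):
        X, Phis = forward(u)
        resid = X[-1] - xf
        err = float(np.linalg.norm(resid))
        if err < tol:
            break
        PhiT = Phis[-1]
        # Phi(T, s) = Phi(T, 0) Phi(s, 0)^-1
        V = np.stack([PhiT @ np.linalg.inv(Phis[k]) @ B for k in range(times.size)])
        ds = np.gradient(times)
        G = np.einsum("k,kic,kjc->ij", ds, V, V)
        lam = np.linalg.solve(G + 1e-12 * np.eye(sd), -resid)
        u = u + np.einsum("kic,i->kc", V, lam)
    if X is None:
        X, Phis = forward(u)
    return u, err, Phis[-1]


@dataclass
class ControlDesign:
    """A solved abatement control paired with its trigger.

    ``times``/``u_values`` hold the replay waveform on a fine uniform
    grid (the collocation solution after the shooting correction, when
    polishing is enabled).  ``onset_delay`` is the time from first entry
    of the detection box to the reference passage along the nominal
    cycle; the deterministic pipeline waits it out, the stochastic one
    starts immediately at detection.
    """

    solution: OCSolution
    trigger_point: TriggerPoint
    trigger_state: np.ndarray
    focus: np.ndarray
    verification: VerificationReport
    times: np.ndarray
    u_values: np.ndarray            # (n_times, control_dim)
    onset_delay: float = 0.0
    cycle: LimitCycle | None = None

    @property
    def horizon(self) -> float:
        return self.solution.problem.T - self.solution.problem.t0

    @property
    def energy(self) -> float:
        """LGL-quadrature integral of u^2 of the replay waveform."""
        prob = self.solution.problem
        half = 0.5 * (prob.T - prob.t0)
        t_nodes = prob.t0 + half * (self.solution.grid.nodes + 1.0)
        u_nodes = np.stack([
            np.interp(t_nodes, self.times, self.u_values[:, c])
            for c in range(self.u_values.shape[1])
        ], axis=1)
        return float(half * np.sum(self.solution.grid.weights[:, None] * u_nodes ** 2))

    def control_values(self, rel_t: np.ndarray) -> np.ndarray:
        """Replay control at times relative to onset; zero outside."""
        rel_t = np.asarray(rel_t, float)
        inside = (rel_t >= 0) & (rel_t <= self.times[-1])
        out = np.zeros(rel_t.shape + (self.u_values.shape[1],))
        ti = np.clip(rel_t, 0.0, self.times[-1])
        for c in range(self.u_values.shape[1]):
            out[..., c] = np.where(inside, np.interp(ti, self.times, self.u_values[:, c]), 0.0)
        return out

    def control_fn(self, start_time: float = 0.0) -> Callable[[float], float]:
        """Scalar control as a function of absolute time, starting at
        ``start_time``; zero outside the window."""

        def fn(t: float) -> float:
            return float(self.control_values(np.asarray(t - start_time)).ravel()[0])

        return fn


def _entry_delay(cycle: LimitCycle, tp: TriggerPoint) -> float:
    """Time from first entry of the detection box to the reference passage
    along the nominal cycle."""
    inbox = tp.contains(cycle.states[:, 0], cycle.states[:, 1])
    if not inbox.any():
        return 0.0
    entries = inbox & ~np.roll(inbox, 1)
    k_entry = int(np.argmax(entries)) if entries.any() else 0
    k_ref = int(np.argmin(
        np.abs(cycle.states[:, 0] - tp.reference_py)
        + np.abs(cycle.states[:, 1] - tp.reference_in)))
    return float((cycle.times[k_ref] - cycle.times[k_entry]) % cycle.period)


def design_control(
    p: ModelParameters,
    trigger_state: np.ndarray,
    xf: np.ndarray,
    T: float = DEFAULT_HORIZON,
    order: int = DEFAULT_ORDER,
    trigger_point: TriggerPoint | None = None,
    cycle: LimitCycle | None = None,
    polish: bool = True,
    n_fine: int = 2001,
) -> ControlDesign:
    """Design the minimum-energy transfer trigger_state -> xf.

    Direct collocation at the given order, optionally followed by the
    indirect-shooting terminal correction so that the continuous-time
    flow (not only the collocation system) reaches ``xf``.  The result
    is verified by independently integrating the dynamics under the
    replay waveform; a solve whose collocation or boundary residuals
    exceed 1e-6 raises ``RuntimeError``.
    """
    x0 = np.asarray(trigger_state, float)
    xf = np.asarray(xf, float)
    F, dF = single_area_dynamics(p)
    prob = OCProblem(dynamics=F, dynamics_jacobian=dF, state_dim=4, control_dim=1,
                     t0=0.0, T=T, x0=x0, xf=xf)
    grid = CollocationGrid.from_order(order)
    sol = solve(transcribe(prob, grid))
    if not sol.converged:
        raise RuntimeError(
            f"control design failed: defect {sol.defect_norm:.2e}, "
            f"boundary {sol.boundary_error:.2e}, status {sol.status} ({sol.message})"
        )
    u_int = control_interpolant(sol)
    times = np.linspace(0.0, T, n_fine)
    u_vals = u_int(times)
    if polish:
        u_vals, term_err, _ = shooting_polish(
            dynamics_rhs=lambda t, x, uk: vector_field(x, p, float(uk[0])),
            jacobian_fn=lambda x: jacobian(x, p),
            control_map=np.array([[1.0], [1.0], [0.0], [0.0]]),
            times=times, u_values=u_vals, x0=x0, xf=xf)
    # independent verification of the replay waveform
    u_replay = lambda t: np.array([np.interp(t, times, u_vals[:, 0])])
    vs = solve_ivp(lambda t, y: vector_field(y, p, float(u_replay(t)[0])),
                   (0.0, T), x0, rtol=1e-10, atol=1e-12, max_step=max(T / 200, 1e-4))
    if not vs.success:
        raise RuntimeError(f"verification integration failed: {vs.message}")
    report = VerificationReport(
        terminal_error=float(np.linalg.norm(vs.y[:, -1] - xf)),
        max_path_deviation=float("nan") if polish else verify_solution(sol).max_path_deviation)
    if trigger_point is None:
        if cycle is not None:
            trigger_point = TriggerPoint.from_cycle(cycle)
        else:
            amp = np.abs(x0 - xf)
            trigger_point = TriggerPoint(
                reference_py=float(x0[0]), reference_in=float(x0[1]),
                scale_py=float(max(amp[0], 1e-6)), scale_in=float(max(amp[1], 1e-6)))
    delay = _entry_delay(cycle, trigger_point) if cycle is not None else 0.0
    return ControlDesign(solution=sol, trigger_point=trigger_point,
                         trigger_state=x0, focus=xf, verification=report,
                         times=times, u_values=u_vals, onset_delay=delay, cycle=cycle)


def design_default_control(
    p: ModelParameters,
    T: float = DEFAULT_HORIZON,
    order: int = DEFAULT_ORDER,
    polish: bool = True,
) -> ControlDesign:
    """Standard design: trigger at the cycle's PY maximum, target the focus."""
    focus = background_state(p)
    cycle = extract_limit_cycle(p, default_seed_state(p))
    trig_state = cycle.state_at_extremum("PY", "max")
    tp = TriggerPoint.from_cycle(cycle)
    return design_control(p, trig_state, focus, T=T, order=order,
                          trigger_point=tp, cycle=cycle, polish=polish)


def classify_attractor(
    p: ModelParameters,
    state: np.ndarray,
    focus: np.ndarray,
    relax_time: float = 3.0,
    amplitude_scale: float | None = None,
) -> str:
    """Basin membership by noise-free relaxation.

    Integrates the deterministic flow from ``state`` for ``relax_time``
    seconds and inspects the PY peak-to-peak amplitude over the final
    sixth of the window: below the oscillation threshold -> ``focus``,
    otherwise ``swd``.
    """
    sol = solve_ivp(lambda t, y: vector_field(y, p, 0.0), (0.0, relax_time),
                    np.asarray(state, float), rtol=1e-8, atol=1e-10,
                    max_step=0.01, dense_output=True)
    if not sol.success:
        raise RuntimeError(f"relaxation integration failed: {sol.message}")
    tt = np.linspace(relax_time * 5 / 6, relax_time, 400)
    py = sol.sol(tt)[0]
    scale = amplitude_scale if amplitude_scale is not None else 0.38
    return "focus" if (py.max() - py.min()) < OSCILLATION_FRACTION * scale else "swd"


@dataclass
class AbatementResult:
    detected_at: float | None
    control_window: tuple[float, float] | None
    success: bool
    terminal_distance: float
    seizure_duration_with: float | None
    seizure_duration_without: float | None
    trace_with: TimeSeries | None = None
    trace_without: TimeSeries | None = None


def score_success(
    ts: TimeSeries,
    focus: np.ndarray,
    control_end: float,
    trigger_to_focus_distance: float,
    window_after_control: float = POST_CONTROL_WINDOW,
    amplitude_scale: float = 0.38,
) -> tuple[bool, float]:
    """Deterministic success check after the control window.

    Success requires the post-control PY peak-to-peak amplitude to stay
    below the oscillation threshold and the final state to lie within
    ``SUCCESS_RADIUS_FRACTION`` of the trigger-to-focus distance of the
    focus.  Returns (success, terminal_distance).
    """
    if control_end > ts.times[-1]:
        raise ValueError("control end beyond the simulated window")
    mask = (ts.times >= control_end) & (ts.times <= control_end + window_after_control)
    py_label = "PY" if "PY" in ts.labels else "PY_0"
    py = ts.column(py_label)[mask]
    quiescent = (py.max() - py.min()) < OSCILLATION_FRACTION * amplitude_scale
    final = ts.values[mask][-1][:4] if len(focus) == 4 else ts.values[mask][-1]
    terminal_distance = float(np.linalg.norm(final[: len(focus)] - focus))
    within = terminal_distance <= SUCCESS_RADIUS_FRACTION * trigger_to_focus_distance
    return bool(quiescent and within), terminal_distance


def _seizure_duration(ts: TimeSeries, onset: float, spike_level: float) -> float:
    """Time from onset until PY last exceeds the spike level (window end if
    it never stops)."""
    py_label = "PY" if "PY" in ts.labels else "PY_0"
    py = ts.column(py_label)
    above = np.nonzero((ts.times >= onset) & (py >= spike_level))[0]
    if above.size == 0:
        return 0.0
    return float(ts.times[above[-1]] - onset)


def _detect_entry(ts: TimeSeries, tp: TriggerPoint, t_min: float) -> float | None:
    """First fresh entry of the detection box at or after ``t_min``."""
    py_label = "PY" if "PY" in ts.labels else "PY_0"
    in_label = "IN" if "IN" in ts.labels else "IN_0"
    inbox = tp.contains(ts.column(py_label), ts.column(in_label))
    entry = inbox & ~np.roll(inbox, 1)
    entry[0] = inbox[0]
    idx = np.nonzero(entry & (ts.times >= t_min))[0]
    return float(ts.times[idx[0]]) if idx.size else None


def run_deterministic_experiment(
    p: ModelParameters,
    design: ControlDesign,
    induction: StimulusEvent | None = None,
    t_end: float = 8.0,
    enable_control: bool = True,
    settle_time: float = 2.5,
) -> AbatementResult:
    """Induce a seizure, detect it at the trigger, splice the stored
    control, and score abatement against a matched no-control run.

    The detector is armed ``settle_time`` seconds after the induction so
    the orbit has converged onto the limit cycle (the stored waveform is
    designed for a state on the cycle, and the first spike of the
    transient is still well off it), and only a fresh entry of the
    detection box counts (arming mid-pass would fire at the wrong phase).
    """
    if induction is None:
        induction = StimulusEvent(time=3.0, py_offset=1.5, in_offset=1.5)
    focus = design.focus
    cfg = SimulationConfig(t_start=0.0, t_end=t_end, initial_state=focus)
    base = integrate_deterministic(p, cfg, events=[induction])
    t_det = _detect_entry(base, design.trigger_point, induction.time + settle_time)
    if t_det is None:  # no discharge survived the settle window: fall back to immediate arming
        t_det = detect_trigger(base, design.trigger_point, t_min=induction.time)
    spike_level = design.trigger_point.reference_py - \
        design.trigger_point.tolerance_fraction * design.trigger_point.scale_py
    d0 = float(np.linalg.norm(design.trigger_state - focus))

    if t_det is None:
        # induction failed to start a seizure; vacuous success
        _, dist = score_success(base, focus, induction.time, d0,
                                amplitude_scale=design.trigger_point.scale_py)
        return AbatementResult(detected_at=None, control_window=None,
                               success=True, terminal_distance=dist,
                               seizure_duration_with=0.0, seizure_duration_without=0.0,
                               trace_with=base, trace_without=base)

    dur_without = _seizure_duration(base, t_det, spike_level)
    if not enable_control:
        return AbatementResult(detected_at=t_det, control_window=None, success=False,
                               terminal_distance=float(np.linalg.norm(base.values[-1][:4] - focus)),
                               seizure_duration_with=None, seizure_duration_without=dur_without,
                               trace_with=None, trace_without=base)

    onset = t_det + design.onset_delay
    u_fn = design.control_fn(start_time=onset)
    ctrl = integrate_deterministic(p, cfg, events=[induction], control=u_fn)
    control_end = onset + design.horizon
    success, dist = score_success(ctrl, focus, control_end, d0,
                                  amplitude_scale=design.trigger_point.scale_py)
    dur_with = _seizure_duration(ctrl, t_det, spike_level)
    return AbatementResult(detected_at=t_det, control_window=(onset, control_end),
                           success=success, terminal_distance=dist,
                           seizure_duration_with=dur_with,
                           seizure_duration_without=dur_without,
                           trace_with=ctrl, trace_without=base)


# ---------------------------------------------------------------------------
# stochastic ensemble experiment


@dataclass
class SeedResult:
    seed_lane: int
    detected_at: float | None
    success: bool | None           # None when no seizure occurred
    terminal_state: np.ndarray | None
    seizure_duration_with: float | None
    seizure_duration_without: float | None


@dataclass
class StochasticSummary:
    results: list[SeedResult]
    n_events: int
    n_success: int
    success_rate: float
    ci_low: float
    ci_high: float


def _wilson_ci(k: int, n: int, z: float = 1.96) -> tuple[float, float]:
    if n == 0:
        return 0.0, 1.0
    ph = k / n
    den = 1 + z * z / n
    center = (ph + z * z / (2 * n)) / den
    half = z * np.sqrt(ph * (1 - ph) / n + z * z / (4 * n * n)) / den
    return max(0.0, center - half), min(1.0, center + half)


def _ensemble_em(
    p: ModelParameters,
    n_lanes: int,
    t_end: float,
    dt: float,
    seed: int,
    sigma: np.ndarray,
    x0: np.ndarray,
    tp: TriggerPoint,
    control: Callable[[np.ndarray], np.ndarray] | None,
    horizon: float,
):
    """Vectorized Euler-Maruyama over lanes with online trigger detection.

    Both phases of a paired experiment call this with the same ``seed``;
    the noise draws depend only on (seed, step), so the paths agree
    exactly until the control switches on (common random numbers).
    Returns detection times, terminal states at control end, and the
    last time each lane's PY exceeded the spike level.
    """
    n_steps = int(round(t_end / dt))
    rng = np.random.default_rng(seed)
    sqdt = np.sqrt(dt)
    Y = np.tile(np.asarray(x0, float), (n_lanes, 1))
    det = np.full(n_lanes, np.nan)
    term = np.full((n_lanes, 4), np.nan)
    got = np.zeros(n_lanes, bool)
    spike_level = tp.reference_py - tp.tolerance_fraction * tp.scale_py
    last_spike = np.full(n_lanes, np.nan)
    seizure_end = np.full(n_lanes, np.nan)   # end of the first detected seizure
    gap = 0.7  # spike-free gap (s, ~2 cycle periods) that closes a seizure
    sig_py, sig_in = float(sigma[0]), float(sigma[1])

    for k in range(n_steps):
        t = k * dt
        if control is not None:
            rel = t - det
            u = np.where(np.isnan(rel) | (rel < 0) | (rel > horizon),
                         0.0, control(np.nan_to_num(rel)))
        else:
            u = 0.0
        py, in_, tc, re = Y[:, 0], Y[:, 1], Y[:, 2], Y[:, 3]
        f = lambda x: sigmoid(x, p.epsilon)
        Y = Y + dt * np.stack([
            p.tau1 * (p.h_py - py + p.C1 * f(py) - p.C3 * f(in_) + p.C9 * f(tc)) + u,
            p.tau2 * (p.h_in - in_ + p.C2 * f(py)) + u,
            p.tau3 * (p.h_tc - tc - p.C6 * (p.a * re + p.b) + p.C7 * f(py)),
            p.tau4 * (p.h_re - re - p.C4 * (p.a * re + p.b)
                      + p.C5 * (p.a * tc + p.b) + p.C8 * f(py)),
        ], axis=1)
        xi = rng.standard_normal((n_lanes, 2))
        Y[:, 0] += sqdt * sig_py * xi[:, 0]
        Y[:, 1] += sqdt * sig_in * xi[:, 1]
        hit = tp.contains(Y[:, 0], Y[:, 1]) & np.isnan(det)
        det[hit] = t
        rel = t - det
        fin = (~np.isnan(rel)) & (rel >= horizon) & (~got)
        term[fin] = Y[fin]
        got[fin] = True
        sp = Y[:, 0] >= spike_level
        last_spike[sp] = t
        ref = np.fmax(last_spike, det)
        closed = (~np.isnan(det)) & np.isnan(seizure_end) & (t - ref > gap)
        seizure_end[closed] = np.fmax(last_spike[closed], det[closed])
    return det, term, got, seizure_end


def run_stochastic_experiment(
    p: ModelParameters,
    design: ControlDesign,
    n_seeds: int = 50,
    t_end: float = 20.0,
    dt: float = DEFAULT_DT,
    noise_intensity: np.ndarray | None = None,
    seed: int = 0,
) -> StochasticSummary:
    """Spontaneous-seizure abatement over an ensemble of noise paths.

    Each lane starts at the focus and is driven by additive cortical
    noise until a spontaneous discharge reaches the trigger box; the
    stored control is then replayed.  Success is basin membership of the
    state at control end (noise-free relaxation classifier).  Lanes with
    no detected seizure are excluded from the rate denominator.
    """
    sigma = DEFAULT_NOISE if noise_intensity is None else np.asarray(noise_intensity, float)
    focus = design.focus
    tp = design.trigger_point
    u_vec = lambda rel: design.control_values(rel)[..., 0]

    det0, _, _, end0 = _ensemble_em(p, n_seeds, t_end, dt, seed, sigma,
                                    focus, tp, None, design.horizon)
    det1, term1, got1, end1 = _ensemble_em(p, n_seeds, t_end, dt, seed, sigma,
                                           focus, tp, u_vec, design.horizon)
    if not np.allclose(det0, det1, equal_nan=True):
        raise AssertionError("paired runs diverged before control onset")

    results: list[SeedResult] = []
    n_events = n_success = 0
    for i in range(n_seeds):
        if np.isnan(det1[i]) or not got1[i]:
            results.append(SeedResult(i, None, None, None, None, None))
            continue
        n_events += 1
        ok = classify_attractor(p, term1[i], focus,
                                amplitude_scale=tp.scale_py) == "focus"
        n_success += ok
        # right-censored at the window end when the seizure never closes
        dur_with = (end1[i] if np.isfinite(end1[i]) else t_end) - det1[i]
        dur_without = (end0[i] if np.isfinite(end0[i]) else t_end) - det0[i]
        results.append(SeedResult(i, float(det1[i]), bool(ok), term1[i].copy(),
                                  float(max(dur_with, 0.0)), float(max(dur_without, 0.0))))
    rate = n_success / n_events if n_events else float("nan")
    lo, hi = _wilson_ci(n_success, n_events)
    return StochasticSummary(results=results, n_events=n_events, n_success=n_success,
                             success_rate=rate, ci_low=lo, ci_high=hi)


# ---------------------------------------------------------------------------
# network experiment


@dataclass
class EnergyMap:
    """Per-area control energy (LGL quadrature of u_i^2 over the window)."""

    energies: np.ndarray
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        self.energies = np.asarray(self.energies, dtype=float)
        if np.any(self.energies < -1e-12):
            raise ValueError("energies must be nonnegative")
        if self.energies.size != len(self.labels):
            raise ValueError("labels length must match energies")

    def to_tsv(self, path) -> None:
        import pandas as pd
        pd.DataFrame({"label": self.labels, "energy": self.energies}).to_csv(
            path, sep="\t", index=False)


def per_area_energies(sol: OCSolution, absolute: bool = False) -> np.ndarray:
    """Quadrature energies E_i = (T-t0)/2 * sum_k w_k u_i(t_k)^2.

    With ``absolute=True`` returns the integral of |u_i| instead.
    """
    half = 0.5 * (sol.problem.T - sol.problem.t0)
    U = sol.controls_at_nodes
    w = sol.grid.weights
    if absolute:
        return half * np.sum(w[:, None] * np.abs(U), axis=0)
    return half * np.sum(w[:, None] * U ** 2, axis=0)


@dataclass
class NetworkAbatementResult:
    detected_at: float | None
    success: bool
    terminal_distance: float
    energy_map: EnergyMap
    solution: OCSolution
    background: np.ndarray          # (n_areas, 4)
    times: np.ndarray | None = None      # replay grid for the polished controls
    u_values: np.ndarray | None = None   # (n_times, n_areas)


def run_network_experiment(
    netp: NetworkParameters,
    labels: Sequence[str] | None = None,
    order: int = 40,
    T: float = DEFAULT_HORIZON,
    t_end: float = 8.0,
    induction_time: float = 2.0,
    induction_offset: float = 1.5,
    settle_time: float = 2.5,
    success_fraction: float = SUCCESS_RADIUS_FRACTION,
    single_design: ControlDesign | None = None,
) -> NetworkAbatementResult:
    """Joint optimal control of a multi-area seizure.

    Induces a network-wide discharge, detects it on area 0's trigger
    after a settle window, designs the joint control from the detected
    full network state back to the network background equilibrium, and
    verifies abatement by independent integration.  The joint solve is
    warm-started from the replicated single-area design (the coupled
    problem is a weak perturbation of n independent copies for small
    alpha), and the converged collocation solution is refined by the
    shooting correction.  Per-area energies come from the same
    quadrature as the optimized cost.
    """
    na = netp.n_areas
    p = netp.base
    focus1 = background_state(p)
    bg = find_network_fixed_point(netp, np.tile(focus1, (na, 1)), tol=1e-10)
    xf_net = bg.reshape(-1)

    cfg = SimulationConfig(t_start=0.0, t_end=t_end, initial_state=xf_net)
    event = StimulusEvent(time=induction_time, py_offset=induction_offset,
                          in_offset=induction_offset)
    base_ts = integrate_deterministic(netp, cfg, events=[event])

    # trigger box from area 0's post-settle oscillation
    mask = base_ts.times >= induction_time + settle_time
    py0 = base_ts.column("PY_0")[mask]
    in0 = base_ts.column("IN_0")[mask]
    if py0.max() - py0.min() < 0.1:
        raise RuntimeError("induction failed to start a sustained network discharge")
    i_pk = int(np.argmax(py0))
    tp = TriggerPoint(reference_py=float(py0[i_pk]), reference_in=float(in0[i_pk]),
                      scale_py=float(py0.max() - py0.min()),
                      scale_in=float(in0.max() - in0.min()))
    t_det = _detect_entry(base_ts, tp, induction_time + settle_time)
    if t_det is None:
        raise RuntimeError("network trigger was never reached")
    # start the control at the reference passage (first PY_0 max after entry)
    seg = (base_ts.times >= t_det) & (base_ts.times <= t_det + 0.2)
    pyseg = base_ts.column("PY_0")[seg]
    t_onset = float(base_ts.times[seg][np.argmax(pyseg)])
    x_det = base_ts.values[np.searchsorted(base_ts.times, t_onset)]

    # warm start: replicate the single-area design, integrate the coupled
    # system under it for the state guess
    if single_design is None:
        single_design = design_default_control(p, T=T)
    grid = CollocationGrid.from_order(order)
    t_nodes = 0.5 * T * (grid.nodes + 1.0)
    u_single = single_design.control_values(t_nodes)[:, 0]
    U0 = np.tile(u_single[:, None], (1, na))
    u_rep = lambda t: np.full(na, float(single_design.control_values(np.asarray(t)).ravel()[0]))
    ws = solve_ivp(lambda t, y: network_vector_field(y.reshape(na, 4), netp, u_rep(t)).reshape(-1),
                   (0.0, T), x_det, t_eval=t_nodes, rtol=1e-9, atol=1e-11,
                   max_step=max(T / 200, 1e-4))
    if not ws.success:
        raise RuntimeError(f"warm-start integration failed: {ws.message}")
    X0 = ws.y.T

    F, dF = network_dynamics(netp)
    prob = OCProblem(dynamics=F, dynamics_jacobian=dF, state_dim=4 * na,
                     control_dim=na, t0=0.0, T=T, x0=x_det, xf=xf_net)
    nlp = transcribe(prob, grid)
    z0 = np.concatenate([X0.ravel(), U0.ravel()])
    # SLSQP occasionally stalls just above tolerance on hard instances;
    # re-warm-starting from the current iterate resumes progress
    sol = None
    for _ in range(3):
        sol = solve(nlp, initial_guess=z0, max_iter=400)
        if sol.defect_norm <= 1e-5 and sol.boundary_error <= 1e-5:
            break
        z0 = np.concatenate([sol.states_at_nodes.ravel(),
                             sol.controls_at_nodes.ravel()])
    if sol.defect_norm > 1e-5 or sol.boundary_error > 1e-5:
        raise RuntimeError(
            f"joint network solve did not converge: defect {sol.defect_norm:.2e}, "
            f"boundary {sol.boundary_error:.2e}; reduce the node count or network size"
        )
    # shooting correction so the continuous flow lands on the background state
    from .model import network_jacobian
    u_int = control_interpolant(sol)
    times = np.linspace(0.0, T, 1001)
    u_vals = np.atleast_2d(u_int(times))
    Bmap = np.zeros((4 * na, na))
    for i in range(na):
        Bmap[4 * i + 0, i] = 1.0
        Bmap[4 * i + 1, i] = 1.0
    u_vals, term_err, _ = shooting_polish(
        dynamics_rhs=lambda t, x, uk: network_vector_field(x.reshape(na, 4), netp, uk).reshape(-1),
        jacobian_fn=lambda x: network_jacobian(x.reshape(na, 4), netp),
        control_map=Bmap, times=times, u_values=u_vals, x0=x_det, xf=xf_net)
    d0 = float(np.linalg.norm(x_det - xf_net))
    success = term_err <= success_fraction * d0
    if labels is None:
        labels = tuple(f"area_{i}" for i in range(na))
    half = 0.5 * T
    u_nodes = np.stack([np.interp(t_nodes, times, u_vals[:, c]) for c in range(na)], axis=1)
    energies = half * np.sum(grid.weights[:, None] * u_nodes ** 2, axis=0)
    emap = EnergyMap(energies, tuple(labels))
    return NetworkAbatementResult(detected_at=t_det, success=bool(success),
                                  terminal_distance=float(term_err),
                                  energy_map=emap, solution=sol, background=bg,
                                  times=times, u_values=u_vals)
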