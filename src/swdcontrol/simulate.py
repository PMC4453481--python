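"""Deterministic and stochastic time-stepping, seizure induction, and
bifurcation scanning.

Deterministic trajectories use an adaptive Runge-Kutta integrator
(scipy ``solve_ivp`` RK45) restarted at every stimulus event so that
events act as exact state jumps.  Stochastic trajectories use a fixed
step Euler-Maruyama scheme,

    x_{k+1} = x_k + dt F(x_k, u_k) + sqrt(dt) * sigma o xi_k,

with i.i.d. standard-normal increments applied (by default) to the
cortical PY and IN variables only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .model import STATE_LABELS, NetworkParameters, network_vector_field, vector_field
from .params import ModelParameters

#: Default Euler-Maruyama step (s).
DEFAULT_DT = 1.0 / 15000.0

#: Default additive noise intensity per state variable (PY, IN, TC, RE).
DEFAULT_NOISE = np.array([0.08, 0.08, 0.0, 0.0])


@dataclass(frozen=True)
class SimulationConfig:
    """Time window, stepping and noise settings for one run."""

    t_start: float = 0.0
    t_end: float = 10.0
    dt: float = DEFAULT_DT
    seed: int = 0
    noise_intensity: np.ndarray = field(default_factory=lambda: DEFAULT_NOISE.copy())
    initial_state: np.ndarray | None = None
    rtol: float = 1e-8
    atol: float = 1e-10
    sample_dt: float = 1e-3  # output sampling interval for deterministic runs

    def __post_init__(self) -> None:
        if self.t_end <= self.t_start:
            raise ValueError("t_end must exceed t_start")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        sig = np.asarray(self.noise_intensity, dtype=float)
        if np.any(sig < 0):
            raise ValueError("noise intensities must be >= 0")
        object.__setattr__(self, "noise_intensity", sig)


@dataclass(frozen=True)
class StimulusEvent:
    """Instantaneous additive displacement of PY and IN at a given time."""

    time: float
    py_offset: float
    in_offset: float

    def offsets(self, n_vars: int) -> np.ndarray:
        """Per-variable jump vector for a flattened n_vars-dim state."""
        out = np.zeros(n_vars)
        out[0::4] = self.py_offset
        out[1::4] = self.in_offset
        return out


@dataclass
class TimeSeries:
    """Sampled trajectory: times (s), values (n_times, n_vars), labels."""

    times: np.ndarray
    values: np.ndarray
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.times.size, len(self.labels)):
            raise ValueError(
                f"values shape {self.values.shape} inconsistent with "
                f"{self.times.size} times and {len(self.labels)} labels"
            )
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    def column(self, label: str) -> np.ndarray:
        return self.values[:, self.labels.index(label)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=pd.Index(self.times, name="time"),
                            columns=list(self.labels))

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "TimeSeries":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df.index.to_numpy(), df.to_numpy(), tuple(df.columns))


def _area_labels(n_areas: int) -> tuple[str, ...]:
    if n_areas == 1:
        return STATE_LABELS
    return tuple(f"{v}_{i}" for i in range(n_areas) for v in STATE_LABELS)


def _make_rhs(
    p: ModelParameters | NetworkParameters,
    control: Callable[[float], float | np.ndarray] | None,
):
    """Flattened RHS closure for either the single-area or network model."""
    if isinstance(p, NetworkParameters):
        n = p.n_areas

        def rhs(t: float, y: np.ndarray) -> np.ndarray:
            u = control(t) if control is not None else 0.0
            return network_vector_field(y.reshape(n, 4), p, u).reshape(-1)

        return rhs, n
    else:

        def rhs(t: float, y: np.ndarray) -> np.ndarray:
            u = float(control(t)) if control is not None else 0.0
            return vector_field(y, p, u)

        return rhs, 1


def integrate_deterministic(
    p: ModelParameters | NetworkParameters,
    config: SimulationConfig,
    events: Sequence[StimulusEvent] = (),
    control: Callable[[float], float | np.ndarray] | None = None,
) -> TimeSeries:
    """Adaptive Runge-Kutta solution with events applied as state jumps.

    The integration is restarted at every event time; ``control`` is a
    callable of time returning the stimulus (scalar for one area, length-n
    for a network), added to PY and IN.
    """
    rhs, n_areas = _make_rhs(p, control)
    if config.initial_state is None:
        raise ValueError("config.initial_state is required")
    y = np.asarray(config.initial_state, dtype=float).reshape(-1).copy()
    if y.size != 4 * n_areas:
        raise ValueError(f"initial state size {y.size} != {4 * n_areas}")

    ev = sorted((e for e in events), key=lambda e: e.time)
    for e in ev:
        if not (config.t_start <= e.time <= config.t_end):
            raise ValueError(f"event time {e.time} outside simulation window")
    breaks = [config.t_start] + [e.time for e in ev] + [config.t_end]

    times_out: list[np.ndarray] = []
    vals_out: list[np.ndarray] = []
    for i in range(len(breaks) - 1):
        t0, t1 = breaks[i], breaks[i + 1]
        if i > 0:
            y = y + ev[i - 1].offsets(y.size)
        if t1 <= t0:
            continue
        n_samp = max(2, int(round((t1 - t0) / config.sample_dt)) + 1)
        t_eval = np.linspace(t0, t1, n_samp)
        sol = solve_ivp(rhs, (t0, t1), y, t_eval=t_eval, rtol=config.rtol,
                        atol=config.atol, method="RK45", max_step=0.01)
        if not sol.success:
            raise RuntimeError(f"integration failed at t={sol.t[-1]:.6f}: {sol.message}")
        keep = slice(0, -1) if i < len(breaks) - 2 else slice(None)
        times_out.append(sol.t[keep])
        vals_out.append(sol.y.T[keep])
        y = sol.y[:, -1].copy()

    return TimeSeries(np.concatenate(times_out), np.vstack(vals_out), _area_labels(n_areas))


def integrate_stochastic(
    p: ModelParameters | NetworkParameters,
    config: SimulationConfig,
    events: Sequence[StimulusEvent] = (),
    control: Callable[[float], float | np.ndarray] | None = None,
    sample_every: int = 15,
) -> TimeSeries:
    """Fixed-step Euler-Maruyama path, reproducible by ``config.seed``.

    Noise intensities are per state variable (tiled across areas for a
    network).  Output is subsampled every ``sample_every`` steps.
    """
    rhs, n_areas = _make_rhs(p, control)
    if config.initial_state is None:
        raise ValueError("config.initial_state is required")
    y = np.asarray(config.initial_state, dtype=float).reshape(-1).copy()
    nv = y.size
    if nv != 4 * n_areas:
        raise ValueError(f"initial state size {nv} != {4 * n_areas}")

    sig = np.tile(config.noise_intensity, n_areas) if config.noise_intensity.size == 4 \
        else np.asarray(config.noise_intensity, dtype=float)
    if sig.size != nv:
        raise ValueError("noise_intensity must have 4 or 4*n_areas entries")
    driven = np.nonzero(sig > 0)[0]

    dt = config.dt
    n_steps = int(round((config.t_end - config.t_start) / dt))
    rng = np.random.default_rng(config.seed)
    sqdt = np.sqrt(dt)

    ev = sorted(events, key=lambda e: e.time)
    ev_steps = {int(round((e.time - config.t_start) / dt)): e for e in ev}

    times = [config.t_start]
    samples = [y.copy()]
    for k in range(n_steps):
        t = config.t_start + k * dt
        if k in ev_steps:
            y = y + ev_steps[k].offsets(nv)
        y = y + dt * rhs(t, y)
        if driven.size:
            y[driven] += sqdt * sig[driven] * rng.standard_normal(driven.size)
        if (k + 1) % sample_every == 0 or k == n_steps - 1:
            times.append(config.t_start + (k + 1) * dt)
            samples.append(y.copy())

    return TimeSeries(np.array(times), np.vstack(samples), _area_labels(n_areas))


def detect_extrema(
    ts: TimeSeries, variable: str = "PY", transient: float = 5.0
) -> list[tuple[float, float, str]]:
    """Strict local extrema of a sampled trace after a transient discard."""
    span = ts.times[-1] - ts.times[0]
    if transient >= span:
        raise ValueError(f"transient {transient} s >= window length {span} s")
    mask = ts.times >= ts.times[0] + transient
    t = ts.times[mask]
    x = ts.column(variable)[mask]
    if t.size < 3:
        raise ValueError("post-transient window too short")
    out: list[tuple[float, float, str]] = []
    interior = np.arange(1, t.size - 1)
    is_max = (x[interior] > x[interior - 1]) & (x[interior] > x[interior + 1])
    is_min = (x[interior] < x[interior - 1]) & (x[interior] < x[interior + 1])
    for i in interior[is_max]:
        out.append((float(t[i]), float(x[i]), "max"))
    for i in interior[is_min]:
        out.append((float(t[i]), float(x[i]), "min"))
    out.sort(key=lambda e: e[0])
    return out


@dataclass
class BifurcationScan:
    """Post-transient PY extrema and attractor labels over an h_tc grid."""

    h_tc_grid: np.ndarray
    extrema: list[list[list[tuple[float, float, str]]]]  # [grid][ic] -> extrema
    attractor_labels: list[set[str]]


#: Peak-to-peak PY fraction of the SWD cycle amplitude above which a
#: post-transient trace is labelled an oscillatory (swd) attractor.
OSCILLATION_FRACTION = 0.25

#: Reference SWD peak-to-peak PY amplitude in the default bistable regime,
#: used as the amplitude scale when a scan point has no oscillatory run.
SWD_REFERENCE_AMPLITUDE = 0.38


def scan_bifurcation(
    p_base: ModelParameters,
    h_tc_grid: Sequence[float],
    initial_conditions,
    transient: float = 5.0,
    t_end: float = 10.0,
    rtol: float = 1e-8,
) -> BifurcationScan:
    """Simulate each (h_tc, initial condition) pair and label attractors.

    ``initial_conditions`` is either a sequence of states applied at
    every grid value, or a callable ``h_tc -> sequence of states`` for
    per-value conditions (e.g. the local background state plus a kicked
    copy).  A run is labelled ``swd`` if its post-transient PY
    peak-to-peak amplitude exceeds :data:`OSCILLATION_FRACTION` of the
    largest oscillation amplitude seen at that grid point (falling back
    to :data:`SWD_REFERENCE_AMPLITUDE` when every run is quiescent), and
    ``focus`` otherwise.
    """
    grid = np.asarray(list(h_tc_grid), dtype=float)
    if grid.size == 0:
        raise ValueError("h_tc grid must be nonempty")
    all_extrema: list[list[list[tuple[float, float, str]]]] = []
    labels: list[set[str]] = []
    for h_tc in grid:
        p = p_base.with_(h_tc=float(h_tc))
        ics = initial_conditions(float(h_tc)) if callable(initial_conditions) \
            else initial_conditions
        per_ic: list[list[tuple[float, float, str]]] = []
        amps: list[float] = []
        for ic in ics:
            cfg = SimulationConfig(t_start=0.0, t_end=t_end, rtol=rtol,
                                   initial_state=np.asarray(ic, dtype=float))
            ts = integrate_deterministic(p, cfg)
            ext = detect_extrema(ts, "PY", transient)
            per_ic.append(ext)
            tail = ts.column("PY")[ts.times >= transient]
            amps.append(float(tail.max() - tail.min()))
        scale = max(max(amps), SWD_REFERENCE_AMPLITUDE)
        lab = {"swd" if a > OSCILLATION_FRACTION * scale else "focus" for a in amps}
        all_extrema.append(per_ic)
        labels.append(lab)
    return BifurcationScan(grid, all_extrema, labels)


def _sustained_swd(p: ModelParameters, t_end: float = 8.0, transient: float = 5.0,
                   kick: float = 1.5, rtol: float = 1e-8) -> bool:
    """Does a strong cortical kick from the background state leave a
    sustained large-amplitude oscillation?"""
    from .model import background_state

    x0 = background_state(p) + np.array([kick, kick, 0.0, 0.0])
    cfg = SimulationConfig(t_start=0.0, t_end=t_end, rtol=rtol, initial_state=x0)
    ts = integrate_deterministic(p, cfg)
    tail = ts.column("PY")[ts.times >= transient]
    return bool(tail.max() - tail.min() > OSCILLATION_FRACTION * SWD_REFERENCE_AMPLITUDE)


def locate_fold_of_cycles(
    p_base: ModelParameters,
    h_lo: float = -2.6,
    h_hi: float = -1.6,
    tol: float = 0.01,
) -> float:
    """Bisect in h_tc for the birth of the sustained SWD cycle.

    Below the fold a strong perturbation decays back to the focus; above
    it the cycle persists.  Requires the bracket to straddle the fold.
    """
    lo, hi = float(h_lo), float(h_hi)
    if _sustained_swd(p_base.with_(h_tc=lo)) or not _sustained_swd(p_base.with_(h_tc=hi)):
        raise ValueError(f"bracket [{lo}, {hi}] does not straddle the fold of cycles")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if _sustained_swd(p_base.with_(h_tc=mid)):
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


def locate_hopf(
    p_base: ModelParameters,
    h_lo: float = -2.0,
    h_hi: float = -1.0,
    tol: float = 1e-6,
) -> float:
    """Bisect in h_tc for the loss of stability of the background focus.

    Uses the maximal real part of the equilibrium's eigenvalues (the
    equilibrium is followed through the scalar reduction, so this works
    on both sides of the bifurcation).
    """
    from scipy.optimize import brentq

    from .model import find_all_fixed_points, jacobian

    def max_re(h_tc: float) -> float:
        p = p_base.with_(h_tc=h_tc)
        fps = find_all_fixed_points(p)
        if not fps:
            raise RuntimeError(f"no equilibrium found at h_tc={h_tc}")
        return min(float(np.max(np.linalg.eigvals(jacobian(x, p)).real)) for x in fps)

    if max_re(h_lo) >= 0 or max_re(h_hi) <= 0:
        raise ValueError(f"bracket [{h_lo}, {h_hi}] does not straddle the Hopf point")
    return float(brentq(max_re, h_lo, h_hi, xtol=tol))
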