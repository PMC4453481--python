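"""Trigger-point placement on the SWD limit cycle and online detection.

The precomputed abatement stimulus starts when the ongoing discharge
passes close to a predeclared point on the spike-wave limit cycle.
Closeness is measured in the (PY, IN) plane only — the thalamic
variables are not assumed observable — with a per-variable tolerance of
``tolerance_fraction`` (default 10%) of that variable's peak-to-peak
amplitude on the cycle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import STATE_LABELS, background_state
from .params import ModelParameters
from .simulate import SimulationConfig, TimeSeries, integrate_deterministic


@dataclass(frozen=True)
class LimitCycle:
    """One period of the post-transient SWD orbit."""

    times: np.ndarray        # seconds, starting at 0, one period
    states: np.ndarray       # (n_samples, 4)
    period: float            # seconds
    amplitudes: np.ndarray   # per-variable peak-to-peak over the cycle

    def state_at_extremum(self, variable: str = "PY", kind: str = "max") -> np.ndarray:
        """Full 4-d state at the cycle's extremum of one variable."""
        col = STATE_LABELS.index(variable)
        idx = np.argmax(self.states[:, col]) if kind == "max" else np.argmin(self.states[:, col])
        return self.states[idx].copy()


@dataclass(frozen=True)
class TriggerPoint:
    """Reference (PY, IN) on the cycle plus detection tolerances."""

    reference_py: float
    reference_in: float
    scale_py: float
    scale_in: float
    tolerance_fraction: float = 0.10

    def __post_init__(self) -> None:
        if self.tolerance_fraction <= 0:
            raise ValueError("tolerance_fraction must be > 0")
        if self.scale_py <= 0 or self.scale_in <= 0:
            raise ValueError("scales must be > 0")

    def contains(self, py: np.ndarray, in_: np.ndarray) -> np.ndarray:
        """Boolean mask: samples within the detection box."""
        return (
            (np.abs(py - self.reference_py) <= self.tolerance_fraction * self.scale_py)
            & (np.abs(in_ - self.reference_in) <= self.tolerance_fraction * self.scale_in)
        )

    @classmethod
    def from_cycle(cls, cycle: LimitCycle, variable: str = "PY", kind: str = "max",
                   tolerance_fraction: float = 0.10) -> "TriggerPoint":
        ref = cycle.state_at_extremum(variable, kind)
        return cls(reference_py=float(ref[0]), reference_in=float(ref[1]),
                   scale_py=float(cycle.amplitudes[0]), scale_in=float(cycle.amplitudes[1]),
                   tolerance_fraction=tolerance_fraction)


def extract_limit_cycle(
    p: ModelParameters,
    seed_state: np.ndarray,
    transient: float = 10.0,
    settle_window: float = 3.0,
    min_amplitude: float = 0.1,
    period_mismatch_tol: float = 0.02,
) -> LimitCycle:
    """Integrate from ``seed_state``, discard the transient, and return one
    period of the orbit.

    The period is estimated from recurrence of PY maxima; a quiescent
    trajectory (peak-to-peak below ``min_amplitude``) or irregular peak
    spacing raises ``RuntimeError``.
    """
    cfg = SimulationConfig(t_start=0.0, t_end=transient + settle_window,
                           initial_state=np.asarray(seed_state, dtype=float),
                           rtol=1e-10, atol=1e-12, sample_dt=1e-4)
    ts = integrate_deterministic(p, cfg)
    mask = ts.times >= transient
    t = ts.times[mask]
    X = ts.values[mask]
    py = X[:, 0]
    if py.max() - py.min() < min_amplitude:
        raise RuntimeError(
            f"no sustained oscillation: post-transient PY amplitude "
            f"{py.max() - py.min():.4f} < {min_amplitude}"
        )
    # spike peaks only: the wave phase has secondary maxima near midrange
    thresh = py.min() + 0.75 * (py.max() - py.min())
    peaks = [i for i in range(1, len(t) - 1)
             if py[i] > py[i - 1] and py[i] > py[i + 1] and py[i] > thresh]
    if len(peaks) < 3:
        raise RuntimeError("fewer than three PY peaks in the settle window")
    gaps = np.diff(t[peaks])
    # the cycle may carry several spikes per period (poly-spike complexes):
    # find the smallest recurrence length m for which the gap sequence repeats
    period = None
    m_rec = 1
    for m in range(1, min(5, len(gaps))):
        if len(gaps) <= m:
            break
        if np.max(np.abs(gaps[:-m] - gaps[m:])) <= period_mismatch_tol * np.mean(gaps):
            m_rec = m
            period = float(np.sum(gaps[-m:]))
            break
    if period is None:
        raise RuntimeError(f"irregular peak spacing: {gaps}")
    i0, i1 = peaks[-1 - m_rec], peaks[-1]
    seg_t = t[i0:i1 + 1] - t[i0]
    seg = X[i0:i1 + 1]
    amplitudes = seg.max(axis=0) - seg.min(axis=0)
    return LimitCycle(times=seg_t, states=seg, period=period, amplitudes=amplitudes)


def default_seed_state(p: ModelParameters,
                       py_offset: float = 1.5, in_offset: float = 1.5) -> np.ndarray:
    """Background state kicked into the SWD basin (suprathreshold jump)."""
    x = background_state(p)
    return x + np.array([py_offset, in_offset, 0.0, 0.0])


def detect_trigger(stream: TimeSeries, tp: TriggerPoint,
                   t_min: float | None = None) -> float | None:
    """Earliest sample time at which (PY, IN) is inside the detection box.

    ``t_min`` restricts detection to ``time >= t_min``.  Returns None if
    the stream never enters the box.  For a multi-area stream the first
    area's PY/IN traces are used.
    """
    py_label = "PY" if "PY" in stream.labels else "PY_0"
    in_label = "IN" if "IN" in stream.labels else "IN_0"
    hit = tp.contains(stream.column(py_label), stream.column(in_label))
    if t_min is not None:
        hit &= stream.times >= t_min
    idx = np.nonzero(hit)[0]
    return float(stream.times[idx[0]]) if idx.size else None
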