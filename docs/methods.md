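# Methods

## Model

The single-area model is an Amari-type neural mass description of a
cortico-thalamic loop with four population activities: excitatory
pyramidal cells (PY) and inhibitory interneurons (IN) in cortex, and
thalamocortical relay (TC) and reticular nucleus (RE) populations in
thalamus:

    dPY/dt = tau1 (h_py - PY + C1 f[PY] - C3 f[IN] + C9 f[TC]) + u(t)
    dIN/dt = tau2 (h_in - IN + C2 f[PY]) + u(t)
    dTC/dt = tau3 (h_tc - TC - C6 s[RE] + C7 f[PY])
    dRE/dt = tau4 (h_re - RE - C4 s[RE] + C5 s[TC] + C8 f[PY])

with the sigmoid `f[x] = 1 / (1 + epsilon^(-x))` on cortical inputs and
a linear activation `s[x] = a x + b` inside the thalamic subsystem (the
linearization simplifies analysis without changing the dynamics
qualitatively).  The stimulus u(t) enters the two cortical equations
only, with the same waveform on PY and IN — the experimentally relevant
case of a nonselective cortical stimulus.

Default parameters (the published set for this model family):
tau1 = 26, tau2 = 32.5, tau3 = tau4 = 2.6 s^-1; h_py = -0.35,
h_in = -3.4, h_re = -5; C1 = 1.8, C2 = 4, C3 = 1.5, C4 = 0.2, C5 = 10.5,
C6 = 0.6, C7 = 3, C8 = 3, C9 = 1; epsilon = 250000; a = 2.8, b = 0.5.
All values are dimensionless except the timescales.  `h_tc` is the
bifurcation parameter: sweeping it, the model passes a fold of cycles
at h_tc ≈ -2.00 (birth of the stable spike-wave limit cycle) and a
subcritical Hopf bifurcation at h_tc ≈ -1.48 (loss of stability of the
background focus).  Between them the background focus coexists with a
large-amplitude spike-wave discharge (SWD) cycle; the package default
h_tc = -1.75 sits in the middle of this bistable window.  The SWD
attractor at the default is a period-two poly-spike-wave complex with
full period ≈ 0.346 s (two spikes of slightly different amplitude per
period); the limit-cycle extractor therefore estimates the period from
recurrence of the spike-gap *pattern*, not single peak spacing.

In the multi-area extension each area keeps its local loop and receives
long-range excitatory input through a structural connectivity matrix M:
`alpha * sum_j M_ij f[PY_j]` is added inside the tau1 parenthesis of
PY_i, with M_ii = 0.  M is symmetric, nonnegative, zero-diagonal, with
FA-like weights in [0, 1].

## Simulation

Deterministic runs use adaptive RK45 (`rtol 1e-8`, `atol 1e-10`),
restarted at stimulus events so that seizure-inducing perturbations are
exact jumps in PY/IN.  Stochastic runs use fixed-step Euler-Maruyama
with dt = 1/15000 s and additive white Gaussian noise on the cortical
variables only (sigma_PY = sigma_IN = 0.08 by default, zero on TC/RE).
That intensity was chosen once so that, from the background focus,
spontaneous noise-driven SWD onsets occur every few seconds — irregular
low-amplitude background interrupted by abrupt high-amplitude discharge
— while the background remains clearly sub-seizure.  Both smaller and
larger intensities were examined: at 0.05 no spontaneous onsets occur
within a minute; at 0.12 the background dwell time shrinks to a couple
of seconds.

## Attractor labelling

A post-transient trace is labelled oscillatory (`swd`) when its PY
peak-to-peak amplitude exceeds 25% of the SWD cycle amplitude
(≈ 0.38 at default parameters).  Basin membership of an arbitrary state
is decided by integrating the noise-free flow for 3 s and applying the
amplitude test to the final 0.5 s.  The relaxation must be this long
because the focus's slowest eigenvalue pair is only about -1.2 ± 20i;
after 1.5 s a genuinely in-basin state can still carry visible ringing.

## Trigger detection

Detection uses the observable cortical pair only: the discharge is
detected at the first sample whose (PY, IN) lies within ±10% of the
per-variable cycle amplitude around a reference point on the cycle (the
spike maximum by default, chosen for robustness; see below).  The
deterministic pipeline arms the detector 2.5 s after induction and only
accepts fresh entries of the detection box: the orbit converges onto
the limit cycle geometrically (contraction ≈ 0.2 per period), and
detections on the first post-induction spike would start the control
from a state well off the cycle.  It then waits out the stored
entry-to-reference delay (≈ 40 ms) so the control starts exactly at its
design point.  The stochastic pipeline instead applies the waveform
immediately at box entry: under operating noise the orbital phase at
entry is uncertain, and in closed-loop measurements the immediate start
was roughly twice as reliable as delaying to the reference passage.

## Optimal control

The abatement stimulus solves a fixed-endpoint minimum-energy problem:
minimize the integral of u(t)^2 over [0, T] subject to the model
dynamics, x(0) = trigger state on the SWD cycle, x(T) = background
focus.  Direct transcription uses Legendre-Gauss-Lobatto collocation:
states and controls are represented by their values at the N+1 LGL
nodes, the ODE becomes `D X = (T/2) F(X, U)` at every node through the
differentiation matrix, and the cost is the LGL quadrature of u^2.  The
nonlinear program is solved by SLSQP with the analytic objective
gradient and an analytic constraint Jacobian assembled from the model's
closed-form Jacobian.  Nodes are computed by Newton iteration on L'_N
from Chebyshev initial guesses (tolerance 1e-14); weights and the
differentiation matrix use the standard closed forms.  The machinery is
exact to machine precision on polynomials (quadrature to degree 2N-1,
differentiation to degree N) and recovers the analytic minimum-energy
double-integrator (cost 12, u = 6 - 12t) and scalar-integrator
(cost 1, u ≡ 1) solutions to <1e-6 relative error at N = 40.

### Branch structure and the robust design

At the default operating point the abatement problem is nonconvex with
several local minima whose trajectories differ strongly in sensitivity.
The globally cheapest waveform found at fine discretization (cost
≈ 11.9 at T = 0.2 s) skims the basin boundary: its terminal-state
sensitivity to initial deviations (largest singular value of the
controlled-flow monodromy) is ≈ 38, and under operating noise it abates
only ~80% of detected discharges.  A distinct branch, found reliably by
the coarse N = 40 transcription, costs ≈ 27.6 but has monodromy norm
≈ 7 and abates ≈ 97%.  The default design therefore solves the
collocation problem at N = 40 and keeps that robust branch.  A scan
over design points (spike maximum, detection-box entry, and the mean
detected state under noise) and horizons T ∈ {0.1, …, 0.5} s preceded
this choice: the spike-maximum trigger with T = 0.2 s was the clear
plateau, and the alternatives were fragile regardless of horizon.  The
horizon is configurable and always reported with a stored design.

### Shooting correction

A collocation solution satisfies the dynamics only at the nodes; at
coarse N its continuous-time flow can land a few percent away from the
focus.  Designs are therefore polished by indirect shooting: the state
and the state-transition matrix Phi(t, 0) are integrated along the
controlled trajectory, and the minimum-norm control correction
cancelling the terminal error is applied via the controllability
Gramian `G = ∫ Phi(T,s) B B' Phi(T,s)' ds`.  Two to three iterations
reduce the terminal error from ~2e-2 to <1e-7 while changing the energy
by <1%, and leave the branch's low sensitivity intact.  The stored
replay waveform is the polished control on a 2001-point uniform grid.

## Experiments

*Deterministic*: a PY/IN jump of +1.5 at t = 3 s induces the discharge;
after detection the stored waveform is replayed and success requires
the post-control trace to stay below the oscillation threshold for 2 s
and the final state to lie within 5% of the trigger-to-focus distance
of the focus.  A matched no-control run provides the duration
comparison (the bistable discharge otherwise persists to the end of the
window).

*Stochastic*: 50 lanes are driven from the focus by seeded cortical
noise for 20 s; the first detected spontaneous discharge per lane is
treated with the stored waveform.  Control-on and control-off phases
consume the identical noise stream (common random numbers), so
durations are paired.  Success is basin membership of the state at
control end under the relaxation classifier; lanes with no spontaneous
discharge are excluded from the denominator.  Seizure duration is the
time from detection to the last spike before a 0.7 s spike-free gap,
right-censored at the window end.  Because noise occasionally
self-terminates an uncontrolled discharge almost immediately, the
duration claim is distributional (medians, paired signed-rank test),
not per-pair.

*Network*: a 6-area synthetic connectome (see below), row-sum
normalized, with coupling gain alpha = 0.02.  The gain was calibrated
once against the coupled system's linear stability: long-range input is
purely excitatory, so by alpha ≈ 0.05 it destabilizes the network
background equilibrium at the default operating point, while at 0.02
the network keeps both a stable background state (computed by Newton on
the full coupled system — coupling shifts it away from the replicated
single-area focus) and a sustained all-channel SWD.  After induction
and detection on area 0, one joint optimal control problem over all
areas (control_dim = n, u_i entering PY_i and IN_i) is transcribed at
N = 32 and solved warm-started from the replicated single-area design —
for small alpha the joint problem is a weak perturbation of n
independent copies, and cold starts reliably fall onto fragile or
spurious branches.  The solution is polished by the same shooting
correction (with the 4n-dimensional Gramian), and per-area energies
E_i = (T/2) Σ_k w_k u_i(t_k)^2 use the same quadrature as the cost; an
integral-of-|u| variant is available.  Heterogeneous connectivity makes
these energies unequal across areas; with alpha = 0 the experiment
reproduces the replicated single-area control and equal energies.

## Synthetic connectome

Stands in for an FA-weighted, 66-region bilateral gyral parcellation:
Beta-distributed weights (mean 0.45, concentration 8, truncated to
(0, 1]), connection density 0.3, intra-hemispheric blocks denser and
slightly stronger, homotopic pairs (i, i + n/2) always connected with
boosted weight, symmetric with zero diagonal, reproducible by seed.  It
emulates the gross statistics (bounded FA-like weights, bilateral block
structure, heterogeneous node strengths) but none of the spatial
embedding, distance-dependent fall-off, or subject-specific topology of
a measured tractography matrix.  Passing network tests therefore show
that the joint control machinery handles heterogeneous coupling, not
that any particular patient's spatial energy pattern is reproduced.

## Numerical choices and degenerate inputs

- Fixed-point solving: damped Newton with the analytic Jacobian,
  residual tolerance 1e-12, max 100 iterations; the global background
  state is found through the scalar reduction of the equilibrium
  equations (IN explicit in PY; TC/RE linear given PY), which is immune
  to the sigmoid's stiffness (epsilon = 250000 makes f essentially a
  step with slope ln(eps)/4 ≈ 3.1 at the origin).
- Lagrange evaluation is barycentric with deterministic weights (the
  scipy implementation's randomized point permutation is pinned so that
  identical designs are bit-identical across runs).
- Events exactly at the window start are applied before integration;
  zero-offset events are inert up to solver restart tolerance.
- An identity transfer (x0 = xf = focus) yields the zero control with
  zero cost; a stable-regime cycle extraction raises an error rather
  than returning a spurious orbit.
- All randomness flows through explicitly seeded numpy Generators; no
  wall-clock seeding anywhere.

## Problem sizes

Default experiment sizes: 81-point replay grids from N = 40 collocation
(single area) and N = 32 (network), 50-lane, 20 s stochastic ensembles,
6-area networks.  The full 66-area, 81-node joint problem is supported
by the same code path but is not part of the standard experiment set.

## Known limitations

- Open-loop replay: robustness comes only from the branch selection
  described above; no ensemble or feedback control.
- Single trigger point per design; multi-phase trigger banks are not
  implemented.
- The noise model (additive, cortical variables only) is a convention;
  state-dependent or thalamic noise would change the spontaneous-onset
  statistics.
- EEG observables are identified with PY traces; no forward model.
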