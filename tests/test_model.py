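"""Unit and property tests for the cortico-thalamic vector field,
fixed points and linear stability."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import swdcontrol as sw
from swdcontrol.model import jacobian, network_jacobian, NetworkParameters

finite_x = st.floats(min_value=-20, max_value=20, allow_nan=False)


class TestSigmoid:
    def test_zero_maps_to_half_for_any_steepness(self):
        for eps in (1.5, np.e, 250.0, 250000.0):
            assert sw.sigmoid(0.0, eps) == pytest.approx(0.5)

    def test_limits(self):
        assert sw.sigmoid(50.0, 250000.0) == pytest.approx(1.0)
        assert sw.sigmoid(-50.0, 250000.0) == pytest.approx(0.0)

    def test_equals_logistic_for_base_e(self):
        # 1/(1+e^-x) is the standard logistic; direct arithmetic oracle
        x = 1.0
        assert sw.sigmoid(x, np.e) == pytest.approx(1.0 / (1.0 + np.exp(-1.0)), rel=1e-14)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(finite_x, finite_x)
    def test_monotone_and_bounded(self, a, b):
        lo, hi = min(a, b), max(a, b)
        fa, fb = sw.sigmoid(lo, 250000.0), sw.sigmoid(hi, 250000.0)
        assert 0.0 <= fa <= fb <= 1.0

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            sw.sigmoid(np.nan, 250000.0)
        with pytest.raises(ValueError):
            sw.sigmoid(0.0, 0.5)


class TestLinearActivation:
    @pytest.mark.parametrize("x,a,b,expected", [
        (0.0, 2.8, 0.5, 0.5),       # intercept at zero input
        (1.0, 1.0, 0.0, 1.0),       # identity
        (1.25, 2.0, 0.5, 3.0),      # direct arithmetic
    ])
    def test_values(self, x, a, b, expected):
        assert sw.linear_activation(x, a, b) == pytest.approx(expected)


class TestVectorField:
    def test_decoupled_equilibrium(self, params):
        p = params.with_(**{f"C{i}": 0.0 for i in range(1, 10)})
        state = np.array([p.h_py, p.h_in, p.h_tc, p.h_re])
        assert np.allclose(sw.vector_field(state, p, 0.0), 0.0, atol=1e-14)

    def test_control_enters_py_and_in_additively(self, params, rng):
        state = rng.normal(size=4)
        d0 = sw.vector_field(state, params, 0.0)
        d1 = sw.vector_field(state, params, 0.7)
        assert np.allclose(d1 - d0, [0.7, 0.7, 0.0, 0.0], atol=1e-14)

    def test_rejects_nonfinite_state(self, params):
        with pytest.raises(ValueError):
            sw.vector_field(np.array([0.0, np.inf, 0.0, 0.0]), params)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(st.lists(st.floats(min_value=-3, max_value=3), min_size=4, max_size=4))
    def test_analytic_jacobian_matches_finite_differences(self, state_list):
        p = sw.DEFAULT_PARAMETERS
        x = np.asarray(state_list)
        J = jacobian(x, p)
        h = 1e-7
        for j in range(4):
            e = np.zeros(4)
            e[j] = h
            col = (sw.vector_field(x + e, p) - sw.vector_field(x - e, p)) / (2 * h)
            assert np.allclose(J[:, j], col, rtol=1e-5, atol=1e-5)


class TestNetworkVectorField:
    def _netp(self, params, n, alpha, rng=None):
        if rng is None:
            W = np.zeros((n, n))
        else:
            W = rng.uniform(0.1, 0.9, (n, n))
            W = 0.5 * (W + W.T)
        return NetworkParameters(base=params, weights=W, alpha=alpha)

    def test_alpha_zero_equals_independent_areas(self, params, rng):
        netp = self._netp(params, 3, 0.0, rng)
        X = rng.normal(size=(3, 4))
        u = rng.normal(size=3)
        out = sw.network_vector_field(X, netp, u)
        for i in range(3):
            assert np.array_equal(out[i], sw.vector_field(X[i], params, u[i]))

    def test_symmetric_coupling_identical_states(self, params):
        netp = NetworkParameters(base=params, weights=np.array([[0.0, 1.0], [1.0, 0.0]]),
                                 alpha=0.5)
        x = np.array([0.1, -0.2, 0.05, -0.4])
        out = sw.network_vector_field(np.stack([x, x]), netp, 0.0)
        assert np.allclose(out[0], out[1])

    def test_coupling_matches_hand_expanded_sum(self, params, rng):
        n = 3
        netp = self._netp(params, n, 0.7, rng)
        X = rng.normal(size=(n, 4))
        out = sw.network_vector_field(X, netp, 0.0)
        # brute-force sum for area 0
        extra = sum(netp.weights[0, j] * sw.sigmoid(X[j, 0], params.epsilon)
                    for j in range(n))
        expected = sw.vector_field(X[0], params, 0.0)
        expected[0] += params.tau1 * 0.7 * extra
        assert np.allclose(out[0], expected, rtol=1e-12)

    def test_dimension_mismatch_raises(self, params):
        netp = self._netp(params, 2, 0.0)
        with pytest.raises(ValueError):
            sw.network_vector_field(np.zeros((3, 4)), netp, 0.0)

    def test_network_jacobian_matches_finite_differences(self, params, rng):
        n = 3
        netp = self._netp(params, n, 0.4, rng)
        X = rng.normal(scale=0.5, size=(n, 4))
        J = network_jacobian(X, netp)
        h = 1e-7
        flat = X.reshape(-1)
        for j in range(4 * n):
            e = np.zeros(4 * n)
            e[j] = h
            col = (sw.network_vector_field((flat + e).reshape(n, 4), netp, 0.0)
                   - sw.network_vector_field((flat - e).reshape(n, 4), netp, 0.0)
                   ).reshape(-1) / (2 * h)
            assert np.allclose(J[:, j], col, rtol=1e-5, atol=1e-5)


class TestFixedPoints:
    def test_decoupled_fixed_point_is_offsets(self, params):
        p = params.with_(**{f"C{i}": 0.0 for i in range(1, 10)})
        fp = sw.find_fixed_point(p, np.zeros(4))
        assert np.allclose(fp, [p.h_py, p.h_in, p.h_tc, p.h_re], atol=1e-10)

    def test_result_independent_of_guess_within_basin(self, params, focus):
        for shift in ([0.05, 0.05, 0.0, 0.0], [-0.05, 0.0, 0.02, -0.05]):
            fp = sw.find_fixed_point(params, focus + np.array(shift))
            assert np.allclose(fp, focus, atol=1e-9)

    def test_forward_integration_stays_near_fixed_point(self, params, focus):
        cfg = sw.SimulationConfig(t_start=0.0, t_end=5.0,
                                  initial_state=focus + 1e-3)
        ts = sw.integrate_deterministic(params, cfg)
        tail = ts.values[ts.times > 4.0]
        assert np.max(np.linalg.norm(tail - focus, axis=1)) < 1e-3

    def test_residual_below_tolerance(self, params, focus):
        assert np.max(np.abs(sw.vector_field(focus, params))) < 1e-10


class TestLinearStability:
    def test_decoupled_eigenvalues_are_minus_taus(self, params):
        p = params.with_(**{f"C{i}": 0.0 for i in range(1, 10)})
        fp = np.array([p.h_py, p.h_in, p.h_tc, p.h_re])
        rep = sw.linear_stability(p, fp)
        got = np.sort(rep.eigenvalues.real)
        expect = np.sort([-p.tau1, -p.tau2, -p.tau3 * 1.0, -p.tau4 * (1 + p.C4 * p.a)])
        # C4 = 0 here so the RE eigenvalue reduces to -tau4
        assert np.allclose(got, np.sort([-p.tau1, -p.tau2, -p.tau3, -p.tau4]), atol=1e-9)
        assert np.allclose(rep.eigenvalues.imag, 0.0, atol=1e-9)

    def test_bistable_focus_is_stable_focus(self, params, focus):
        rep = sw.linear_stability(params, focus)
        assert rep.classification == "stable_focus"
        assert np.max(rep.eigenvalues.real) < 0
        assert np.any(np.abs(rep.eigenvalues.imag) > 1.0)

    def test_rejects_non_fixed_point(self, params, focus):
        with pytest.raises(ValueError):
            sw.linear_stability(params, focus + 0.1)


class TestStateType:
    def test_round_trip_and_validation(self):
        st = sw.CorticothalamicState.from_array(np.array([0.1, -0.2, 0.3, -0.4]))
        assert st.py == 0.1 and st.re == -0.4
        assert np.array_equal(st.as_array(), [0.1, -0.2, 0.3, -0.4])
        with pytest.raises(ValueError):
            sw.CorticothalamicState.from_array(np.array([np.nan, 0, 0, 0]))
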