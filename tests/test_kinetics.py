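"""Gating-equation unit tests: sigmoid steady states, bell-shaped time
constants, first-order relaxation against the closed-form solution."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fsneuron.kinetics import (
    ChannelSpec,
    GateKinetics,
    GateState,
    channel_current,
    gate_derivative,
    steady_state,
    time_constant,
)

K = GateKinetics(v_half=-40.0, v_slope=8.0, tau_max=5.0, tau_min=1.0,
                 v_tau_half=-50.0, v_tau_slope=15.0)


class TestSteadyState:
    def test_midpoint_is_half(self):
        assert steady_state(K.v_half, K) == pytest.approx(0.5, abs=1e-15)

    def test_saturation(self):
        assert steady_state(K.v_half + 500.0, K) == pytest.approx(1.0, abs=1e-12)
        assert steady_state(K.v_half - 500.0, K) == pytest.approx(0.0, abs=1e-12)

    def test_negative_slope_inverts_direction(self):
        k_inv = GateKinetics(-40.0, -8.0, 5.0, 1.0, -50.0, 15.0)
        assert steady_state(-20.0, k_inv) < 0.5 < steady_state(-60.0, k_inv)

    @given(st.floats(-120, 40), st.floats(0.5, 30), st.floats(0.01, 60))
    @settings(max_examples=100, deadline=None)
    def test_odd_symmetry_about_midpoint(self, v_half, v_slope, d):
        """x_inf(Vh + d) + x_inf(Vh - d) = 1 for any offset d."""
        k = GateKinetics(v_half, v_slope, 5.0, 1.0, -50.0, 15.0)
        s = steady_state(v_half + d, k) + steady_state(v_half - d, k)
        assert s == pytest.approx(1.0, abs=1e-12)

    @given(st.floats(-120, 40), st.floats(0.5, 30), st.floats(-100, 20))
    @settings(max_examples=100, deadline=None)
    def test_sign_flip_invariance(self, v_half, v_slope, v):
        """Flipping both (V - Vh) and the slope sign leaves x_inf unchanged."""
        k_pos = GateKinetics(v_half, v_slope, 5.0, 1.0, -50.0, 15.0)
        k_neg = GateKinetics(v_half, -v_slope, 5.0, 1.0, -50.0, 15.0)
        d = v - v_half
        assert steady_state(v_half + d, k_pos) == pytest.approx(
            steady_state(v_half - d, k_neg), abs=1e-12)


class TestTimeConstant:
    def test_maximum_at_center(self):
        assert time_constant(K.v_tau_half, K) == pytest.approx(K.tau_max)

    def test_saturates_to_tau_min(self):
        assert time_constant(K.v_tau_half + 1e3, K) == pytest.approx(K.tau_min)
        assert time_constant(K.v_tau_half - 1e3, K) == pytest.approx(K.tau_min)

    def test_unit_offset_closed_form(self):
        # tau at one slope-width from center: tau_min + (1 - tanh(1)^2) * range
        # with tau_min = 1 ms, tau_max = 5 ms this is 2.6798973664561045 ms
        assert time_constant(K.v_tau_half + K.v_tau_slope, K) == pytest.approx(
            2.6798973664561045, rel=1e-12)

    @given(st.floats(-120, 40))
    @settings(max_examples=50, deadline=None)
    def test_bounded(self, v):
        tau = time_constant(v, K)
        assert K.tau_min <= tau <= K.tau_max


class TestGateDerivative:
    def test_fixed_point(self):
        v = -45.0
        assert gate_derivative(steady_state(v, K), v, K) == pytest.approx(0.0, abs=1e-15)

    @given(st.floats(0, 1), st.floats(-100, 20))
    @settings(max_examples=100, deadline=None)
    def test_sign_matches_displacement(self, x, v):
        d = gate_derivative(x, v, K)
        assert np.sign(d) == np.sign(steady_state(v, K) - x)

    def test_direct_substitution(self):
        # x = 0, x_inf = 1, tau = 2 ms -> dx/dt = 0.5 /ms
        k = GateKinetics(v_half=-40.0, v_slope=8.0, tau_max=2.0, tau_min=2.0,
                         v_tau_half=-50.0, v_tau_slope=15.0)
        assert gate_derivative(0.0, 1e4, k) == pytest.approx(0.5, rel=1e-9)

    @pytest.mark.parametrize("v_clamp", [-70.0, -45.0, -20.0])
    def test_clamped_relaxation_matches_exponential(self, v_clamp):
        """Integrated gate equals x_inf + (x0 - x_inf) e^{-t/tau} to 1e-6."""
        from scipy.integrate import solve_ivp

        x_inf = float(steady_state(v_clamp, K))
        tau = float(time_constant(v_clamp, K))
        x0 = 0.9
        sol = solve_ivp(lambda t, x: gate_derivative(x, v_clamp, K),
                        (0.0, tau), [x0], rtol=1e-10, atol=1e-12)
        exact = x_inf + (x0 - x_inf) * math.exp(-1.0)
        assert sol.y[0, -1] == pytest.approx(exact, rel=1e-6)

    @given(st.floats(0, 1), st.floats(-90, 0), st.integers(1, 500))
    @settings(max_examples=50, deadline=None)
    def test_exponential_euler_stays_bounded(self, x0, v, steps):
        """The integrator update keeps gates in [0, 1] for any trajectory."""
        x = x0
        x_inf = float(steady_state(v, K))
        tau = float(time_constant(v, K))
        for _ in range(steps):
            x = x_inf + (x - x_inf) * math.exp(-0.01 / tau)
        assert 0.0 <= x <= 1.0


class TestChannelCurrent:
    SPEC = ChannelSpec(name="k", p=1, e_rev=-90.0, activation=K)

    def test_zero_at_reversal(self):
        assert channel_current(-90.0, 20.0, GateState(0.5, 1.0), self.SPEC) == 0.0

    def test_worked_example(self):
        # 20 nS * 0.5 * (-90 - (-40)) = -500 pA
        i = channel_current(-40.0, 20.0, GateState(m=0.5, h=1.0), self.SPEC)
        assert i == pytest.approx(-500.0)

    def test_leak_independent_of_gate(self):
        leak = ChannelSpec(name="leak", p=0, e_rev=-68.0)
        i1 = channel_current(-50.0, 5.0, GateState(m=0.1, h=1.0), leak)
        i2 = channel_current(-50.0, 5.0, GateState(m=0.9, h=1.0), leak)
        assert i1 == i2 == pytest.approx(5.0 * (-68.0 + 50.0))

    def test_current_sign_follows_driving_force(self):
        for v in (-120.0, -90.0, -30.0, 0.0):
            i = channel_current(v, 10.0, GateState(0.3, 0.8), self.SPEC)
            assert np.sign(i) == np.sign(self.SPEC.e_rev - v)

    def test_negative_conductance_rejected(self):
        with pytest.raises(ValueError):
            channel_current(-40.0, -1.0, GateState(), self.SPEC)


class TestValidation:
    def test_tau_ordering_enforced(self):
        with pytest.raises(ValueError):
            GateKinetics(-40.0, 8.0, tau_max=1.0, tau_min=2.0,
                         v_tau_half=-50.0, v_tau_slope=15.0)

    def test_zero_slope_rejected(self):
        with pytest.raises(ValueError):
            GateKinetics(-40.0, 0.0, 5.0, 1.0, -50.0, 15.0)

    def test_gate_state_bounds(self):
        with pytest.raises(ValueError):
            GateState(m=1.2)

    def test_leak_cannot_inactivate(self):
        with pytest.raises(ValueError):
            ChannelSpec(name="bad", p=0, e_rev=-68.0, inactivation=K)
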