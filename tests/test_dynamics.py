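"""Closed-form oracle checks for the cell and synapse equations.

Every model family here has an analytic solution in some regime (RC
charging, exponential gate relaxation, LIF inter-spike interval, geometric
steady state of the activity proxy); the tests integrate the update rules
with forward Euler and compare against those solutions.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nemasim.dynamics import (
    ActivityParams,
    ChannelSpec,
    ConductanceCellParams,
    GateSpec,
    GradedSynapseParams,
    LIFParams,
    activity_step,
    conductance_cell_derivatives,
    gap_junction_current,
    gate_inf_tau,
    graded_synapse_step,
    lif_step,
    synapse_current,
)

DT = 0.05


class TestLIF:
    P = LIFParams(C_m=3.0, g_leak=0.1, E_leak=-60.0, V_thresh=-40.0,
                  V_reset=-65.0, t_refract=2.0)

    def test_equilibrium_is_a_fixed_point(self):
        V, spiked, _ = lif_step(self.P.E_leak, 0.0, self.P, DT)
        assert V == pytest.approx(self.P.E_leak)
        assert not spiked

    def test_subthreshold_charging_matches_rc_closed_form(self):
        I = 1.5  # pA; steady state E_leak + I/g = -45 mV, below threshold
        V, t, refract = self.P.E_leak, 0.0, -np.inf
        tau = self.P.C_m / self.P.g_leak
        for _ in range(int(100.0 / DT)):
            V, _, refract = lif_step(V, I, self.P, DT, refract, t)
            t += DT
            exact = self.P.E_leak + (I / self.P.g_leak) * (1 - math.exp(-t / tau))
            assert V == pytest.approx(exact, rel=0.01, abs=0.05)

    @pytest.mark.parametrize("I", [2.5, 4.0, 10.0])
    def test_interspike_interval_matches_closed_form(self, I):
        p = self.P
        tau = p.C_m / p.g_leak
        V_inf = p.E_leak + I / p.g_leak
        isi_exact = tau * math.log((V_inf - p.V_reset) / (V_inf - p.V_thresh)) \
            + p.t_refract
        V, t, refract = p.V_reset, 0.0, -np.inf
        spike_times = []
        while t < 400.0 and len(spike_times) < 6:
            V, spiked, refract = lif_step(V, I, p, DT, refract, t)
            t += DT
            if spiked:
                spike_times.append(t)
        isis = np.diff(spike_times)
        assert len(isis) >= 3
        # one dt of spike-time quantization plus Euler truncation bias
        assert np.all(np.abs(isis - isi_exact) <= DT + 0.01)
        assert np.all(np.abs(isis - isi_exact) <= 0.01 * isi_exact)

    def test_refractory_clamps_at_reset(self):
        V, spiked, refract = lif_step(-50.0, 100.0, self.P, DT,
                                      refract_until=5.0, t=1.0)
        assert V == self.P.V_reset and not spiked and refract == 5.0


class TestGates:
    def test_midpoint_and_saturation(self):
        g = GateSpec(V_half=-35.0, slope_k=5.0, tau=10.0)
        assert gate_inf_tau(-35.0, g)[0] == pytest.approx(0.5)
        assert gate_inf_tau(200.0, g)[0] == pytest.approx(1.0, abs=1e-9)
        assert gate_inf_tau(-300.0, g)[0] == pytest.approx(0.0, abs=1e-9)

    def test_boltzmann_point_value(self):
        g = GateSpec(V_half=-35.0, slope_k=5.0, tau=10.0)
        x_inf, tau = gate_inf_tau(-30.0, g)
        assert x_inf == pytest.approx(1 / (1 + math.exp(-1.0)), rel=1e-12)
        assert tau == 10.0

    @pytest.mark.parametrize("tau", [5.0, 40.0])
    def test_voltage_clamp_relaxation_is_exponential(self, tau):
        # gate relaxes from 0 toward x_inf(V) with its own time constant
        g = GateSpec(V_half=-35.0, slope_k=5.0, tau=tau)
        V = -20.0
        x_inf, _ = gate_inf_tau(V, g)
        x, t = 0.0, 0.0
        for _ in range(int(4 * tau / DT)):
            x += DT * (x_inf - x) / tau
            t += DT
            exact = x_inf * (1 - math.exp(-t / tau))
            assert abs(x - exact) <= 0.005 * x_inf


class TestConductanceCell:
    def _cell(self, **kw):
        ch = ChannelSpec(gbar=kw.pop("gbar", 0.0), E_rev=-80.0,
                         activation=GateSpec(-40.0, 5.0, 20.0, 1),
                         is_calcium_carrier=False)
        return ConductanceCellParams(C_m=3.0, g_leak=0.1, E_leak=-60.0,
                                     channels=(ch,), ca_rho=0.001,
                                     ca_tau=100.0, **kw)

    def test_passive_equilibrium_has_zero_derivatives(self):
        p = self._cell(gbar=0.0)
        state = {"V": -60.0, ("act", 0): gate_inf_tau(-60.0, p.channels[0].activation)[0],
                 "Ca": 0.0}
        d = conductance_cell_derivatives(state, p, I_total=0.0)
        assert d["V"] == pytest.approx(0.0, abs=1e-12)
        assert d[("act", 0)] == pytest.approx(0.0, abs=1e-12)
        assert d["Ca"] == pytest.approx(0.0, abs=1e-12)

    def test_calcium_decays_exponentially_without_inflow(self):
        p = self._cell(gbar=0.0)
        Ca0, Ca, t = 2.0, 2.0, 0.0
        for _ in range(int(3 * p.ca_tau / DT)):
            state = {"V": -60.0, ("act", 0): 0.5, "Ca": Ca}
            Ca += DT * conductance_cell_derivatives(state, p)["Ca"]
            t += DT
            exact = Ca0 * math.exp(-t / p.ca_tau)
            assert abs(Ca - exact) <= 0.005 * Ca0

    def test_gate_error_raised_outside_unit_interval(self):
        p = self._cell(gbar=1.0)
        with pytest.raises(ValueError, match="gate"):
            conductance_cell_derivatives({"V": -60.0, ("act", 0): 1.5, "Ca": 0.0}, p)

    def test_channel_current_enters_voltage_equation(self):
        p = self._cell(gbar=2.0)
        state = {"V": -60.0, ("act", 0): 1.0, "Ca": 0.0}
        d = conductance_cell_derivatives(state, p)
        # fully open channel: I = gbar (V - E_rev) = 2 * 20 = 40 pA outward,
        # leak is zero at V = E_leak, so dV/dt = -40 / C_m
        assert d["V"] == pytest.approx(-40.0 / 3.0, rel=1e-12)

    def test_calcium_carrier_inward_current_raises_ca(self):
        ch = ChannelSpec(gbar=1.0, E_rev=60.0,
                         activation=GateSpec(-40.0, 5.0, 5.0, 1),
                         is_calcium_carrier=True)
        p = ConductanceCellParams(C_m=3.0, g_leak=0.1, E_leak=-60.0,
                                  channels=(ch,), ca_rho=0.01, ca_tau=100.0)
        state = {"V": -20.0, ("act", 0): 1.0, "Ca": 0.0}
        d = conductance_cell_derivatives(state, p)
        assert d["Ca"] > 0  # inward (negative) current feeds the pool


class TestGradedSynapse:
    P = GradedSynapseParams(E_syn=0.0, V_th_pre=-35.0, delta=4.0, tau_s=50.0)

    def test_half_activation_is_a_fixed_point(self):
        assert graded_synapse_step(0.5, self.P.V_th_pre, self.P, DT) == pytest.approx(0.5)

    def test_relaxation_toward_one_is_exponential(self):
        s, t = 0.0, 0.0
        for _ in range(int(4 * self.P.tau_s / DT)):
            s = graded_synapse_step(s, 50.0, self.P, DT)  # far above threshold
            t += DT
            exact = 1 - math.exp(-t / self.P.tau_s)
            assert abs(s - exact) <= 0.005

    @given(st.floats(-80.0, 10.0), st.floats(0.5, 10.0))
    @settings(max_examples=100, deadline=None)
    def test_delta_sign_flip_mirrors_activation_curve(self, V, delta):
        def s_inf(V, d):
            return 1.0 / (1.0 + math.exp((self.P.V_th_pre - V) / d))

        mirrored = 2 * self.P.V_th_pre - V
        assert s_inf(V, delta) + s_inf(mirrored, delta) == pytest.approx(1.0, abs=1e-9)

    @given(st.floats(0.0, 1.0), st.floats(-100.0, 50.0))
    @settings(max_examples=100, deadline=None)
    def test_gate_stays_in_unit_interval(self, s0, V):
        s = s0
        for _ in range(50):
            s = graded_synapse_step(s, V, self.P, 0.5)
            assert 0.0 <= s <= 1.0


class TestCurrents:
    def test_zero_at_reversal_potential(self):
        assert synapse_current("graded", 1.0, 0.5, -30.0, -30.0) == 0.0
        assert synapse_current("spike", 2.0, 0.5, -70.0, -70.0) == 0.0

    def test_unit_arithmetic_ns_times_mv_is_pa(self):
        # 0.13 nS fully open, 10 mV driving force -> 1.3 pA
        assert synapse_current("graded", 1.0, 0.13, -10.0, 0.0) == pytest.approx(1.3)

    def test_spike_kind_without_events_is_silent(self):
        assert synapse_current("spike", 0.0, 0.5, -50.0, 0.0) == 0.0

    def test_gap_junction_ohms_law(self):
        I_a, I_b = gap_junction_current(-60.0, -50.0, 1.0)
        assert I_a == pytest.approx(10.0)
        assert I_b == pytest.approx(-10.0)

    @given(st.floats(-100, 50), st.floats(-100, 50), st.floats(0, 10))
    @settings(max_examples=200, deadline=None)
    def test_gap_currents_conserve_charge_exactly(self, Va, Vb, w):
        I_a, I_b = gap_junction_current(Va, Vb, w)
        assert I_a + I_b == 0.0

    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError):
            gap_junction_current(0.0, 0.0, -1.0)
        with pytest.raises(ValueError):
            synapse_current("graded", 0.5, -1.0, 0.0, 0.0)


class TestActivityProxy:
    P = ActivityParams(tau_activity=100.0, increment_per_spike=1.0)

    def test_decays_exponentially_without_spikes(self):
        a, t = 5.0, 0.0
        for _ in range(int(300.0 / DT)):
            a = activity_step(a, False, self.P, DT)
            t += DT
        assert a == pytest.approx(5.0 * math.exp(-t / self.P.tau_activity), rel=0.01)

    def test_zero_stays_zero(self):
        assert activity_step(0.0, False, self.P, DT) == 0.0

    def test_steady_state_under_periodic_spiking(self):
        # spiking at rate r, the proxy fluctuates about increment * r * tau
        rate = 0.02  # spikes per ms (20 Hz)
        every = int(1 / rate / DT)
        a = 0.0
        history = []
        for k in range(int(3000.0 / DT)):
            a = activity_step(a, k % every == 0, self.P, DT)
            if k > int(2000.0 / DT):
                history.append(a)
        expected = self.P.increment_per_spike * rate * self.P.tau_activity
        assert np.mean(history) == pytest.approx(expected, rel=0.05)


class TestEulerConvergence:
    def test_first_order_in_dt_for_linear_decay(self):
        # halving dt halves the error of the Euler solution of ds/dt = -s/tau
        tau, T = 20.0, 60.0

        def euler_final(dt):
            s = 1.0
            for _ in range(int(T / dt)):
                s += dt * (-s / tau)
            return s

        exact = math.exp(-T / tau)
        e1 = abs(euler_final(0.2) - exact)
        e2 = abs(euler_final(0.1) - exact)
        assert e1 / e2 == pytest.approx(2.0, rel=0.15)
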