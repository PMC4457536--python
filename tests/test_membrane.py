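import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cbcstim import membrane as mb
from cbcstim.units import CA_RES_UM, RT_2F_MV


class TestGateFunctions:
    def test_t_type_half_activation_and_inactivation(self):
        m_inf, _, h_inf, _ = mb.t_gate_functions(37.55)
        assert m_inf == pytest.approx(0.5, abs=1e-12)
        assert mb.t_gate_functions(8.97)[2] == pytest.approx(0.5, abs=1e-12)

    def test_t_type_time_constants(self):
        # at the tau_m sigmoid midpoint: 1.36 + 21.68/2
        assert mb.t_gate_functions(39.96)[1] == pytest.approx(12.20, abs=1e-10)
        _, tau_m, _, tau_h = mb.t_gate_functions(np.linspace(-150, 150, 301))
        assert np.all(tau_m > 0) and np.all(tau_h > 0)

    def test_l_type_removable_singularity(self):
        alpha, *_ = mb.l_gate_functions(63.0)
        assert alpha == pytest.approx(0.427 * 10.5, abs=1e-12)
        for eps in (1e-9, -1e-9, 1e-4, -1e-4):
            a_eps, *_ = mb.l_gate_functions(63.0 + eps)
            assert a_eps == pytest.approx(4.4835, rel=1e-4)

    def test_l_type_inactivation(self):
        _, _, h_inf, tau_h = mb.l_gate_functions(0.0)
        assert h_inf == pytest.approx(0.5, abs=1e-12)
        assert np.all(mb.l_gate_functions(np.array([-90., 0., 90.]))[3] == 292.0)

    @given(vm=st.floats(min_value=-300, max_value=300))
    @settings(deadline=None, max_examples=60)
    def test_rates_total_and_positive(self, vm):
        m_inf, tau_m, h_inf, tau_h = mb.t_gate_functions(vm)
        assert 0.0 <= m_inf <= 1.0 and 0.0 <= h_inf <= 1.0
        assert tau_m > 0 and tau_h > 0
        alpha, beta, h_inf_l, _ = mb.l_gate_functions(vm)
        assert alpha >= 0 and beta >= 0 and 0.0 <= h_inf_l <= 1.0


class TestChannelCurrent:
    def test_closed_channel_carries_nothing(self):
        t = mb.TTypeChannel()
        assert t.current(0.0, 1.0, 40.0) == 0.0

    def test_reversal_potential_zeroes_current(self):
        t = mb.TTypeChannel()
        e = t.reversal(CA_RES_UM)
        assert t.current(0.7, 0.5, e) == pytest.approx(0.0, abs=1e-12)

    def test_t_current_scale(self):
        # gbar * 1 * 1 * (-100 mV) = -95.4 uA/cm^2 with the reversal pinned
        t = mb.TTypeChannel()
        e = float(t.reversal(CA_RES_UM))
        assert t.current(1.0, 1.0, e - 100.0) == pytest.approx(-95.4, rel=1e-9)

    def test_l_current_uses_m_squared(self):
        l = mb.LTypeChannel()
        e = float(l.reversal(CA_RES_UM))
        i_half = l.current(0.5, 1.0, e - 100.0)
        i_full = l.current(1.0, 1.0, e - 100.0)
        assert i_half == pytest.approx(i_full / 4.0)


class TestEffectiveReversal:
    def test_pure_nernst_identity(self):
        rev = mb.EffectiveReversal(weight=1.0)
        assert mb.effective_reversal(1800.0, 1800.0, rev) == pytest.approx(0.0)

    def test_resting_nernst_value(self):
        rev = mb.EffectiveReversal(weight=1.0)
        expected = RT_2F_MV * np.log(1800.0 / 0.15)    # ~ +120.6 mV
        got = mb.effective_reversal(0.15, 1800.0, rev)
        assert got == pytest.approx(expected, rel=1e-12)
        assert got == pytest.approx(120.6, abs=0.2)

    def test_blend_endpoints(self):
        rev = mb.EffectiveReversal(weight=0.0, e_k=-75.0)
        assert mb.effective_reversal(0.3, 1800.0, rev) == -75.0

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            mb.effective_reversal(-1.0, 1800.0, mb.EffectiveReversal())
        with pytest.raises(ValueError):
            mb.EffectiveReversal(weight=1.5)


class TestCalcium:
    def test_resting_fixed_point(self):
        cm = mb.CalciumModel()
        assert cm.step(cm.ca_res, 0.0, 3.3, 0.1) == pytest.approx(cm.ca_res)

    def test_exponential_decay_time_constant(self):
        cm = mb.CalciumModel()
        ca = cm.ca_res + 1.0
        dt = 0.01
        for _ in range(150):                      # one time constant
            ca = cm.step(ca, 0.0, 3.3, dt)
        expected = cm.ca_res + np.exp(-1.5 / cm.tau)
        assert ca == pytest.approx(expected, rel=1e-9)

    def test_steady_state_matches_analytic_fixed_point(self):
        cm = mb.CalciumModel()
        i_ca, sov = -16.0, 2.667
        analytic = cm.steady_state(i_ca, sov)
        ca = cm.ca_res
        for _ in range(2000):
            ca = cm.step(ca, i_ca, sov, 0.01)
        assert ca == pytest.approx(analytic, rel=1e-3)

    def test_outward_current_floors_at_residual(self):
        cm = mb.CalciumModel()
        ca = cm.step(cm.ca_res + 0.01, +200.0, 3.3, 1.0)
        assert ca == cm.ca_res

    def test_nonpositive_dt_raises(self):
        with pytest.raises(ValueError):
            mb.CalciumModel().step(0.2, 0.0, 3.3, 0.0)


class TestGateIntegration:
    def test_exponential_update_matches_closed_form(self):
        # fixed Vm: m(t) = m_inf - (m_inf - m0) exp(-t/tau) exactly
        t_ch = mb.TTypeChannel()
        vm = -20.0
        m_inf, tau_m, h_inf, tau_h = mb.t_gate_functions(vm)
        m, h = 0.9, 0.1
        dt, n = 0.05, 400
        for _ in range(n):
            m, h = t_ch.step_gates(m, h, vm, dt)
        t_tot = dt * n
        m_exact = m_inf + (0.9 - m_inf) * np.exp(-t_tot / tau_m)
        h_exact = h_inf + (0.1 - h_inf) * np.exp(-t_tot / tau_h)
        assert m == pytest.approx(m_exact, rel=1e-9)
        assert h == pytest.approx(h_exact, rel=1e-9)

    @given(seed=st.integers(0, 2**16))
    @settings(deadline=None, max_examples=25)
    def test_gates_stay_in_unit_interval(self, seed):
        rng = np.random.default_rng(seed)
        vm_trace = rng.uniform(-250.0, 250.0, size=50)
        for ch in (mb.TTypeChannel(), mb.LTypeChannel()):
            m, h = ch.steady_state(-53.08)
            m, h = float(m), float(h)
            for vm in vm_trace:
                m, h = ch.step_gates(m, h, float(vm), 0.05)
                assert 0.0 <= m <= 1.0 and 0.0 <= h <= 1.0


class TestVoltageClamp:
    def test_no_step_gives_flat_trace(self):
        t_ch = mb.TTypeChannel()
        proto = mb.ClampProtocol(hold_mv=-80.0, steps_mv=(-80.0,),
                                 step_ms=50.0, dt=0.05)
        res = mb.run_voltage_clamp(t_ch, proto)
        assert np.ptp(res["i"][0]) < 1e-9

    def test_t_type_step_is_transient(self):
        # depolarizing step: current activates then inactivates toward a
        # smaller sustained level
        t_ch = mb.TTypeChannel()
        proto = mb.ClampProtocol(hold_mv=-80.0, steps_mv=(45.0,),
                                 step_ms=250.0, pre_ms=10.0, post_ms=10.0,
                                 dt=0.05)
        res = mb.run_voltage_clamp(t_ch, proto, dynamic_ca=False)
        window = (res["t"] >= 10.0) & (res["t"] < 260.0)
        i_step = np.abs(res["i"][0][window])
        t_peak = np.argmax(i_step)
        assert i_step[t_peak] > 2.0 * i_step[-1]      # inactivating
        assert 0 < t_peak < i_step.size - 1

    def test_l_type_family_peaks_non_monotone(self):
        # driving-force / activation trade-off across the step family
        l_ch = mb.LTypeChannel()
        proto = mb.ClampProtocol(hold_mv=-70.0,
                                 steps_mv=(-45.0, -20.0, 5.0, 30.0, 55.0),
                                 step_ms=300.0, pre_ms=10.0, post_ms=10.0,
                                 dt=0.05)
        res = mb.run_voltage_clamp(l_ch, proto)
        window = (res["t"] >= 10.0) & (res["t"] < 310.0)
        peaks = [float(-res["i"][k][window].min())
                 for k in range(len(proto.steps_mv))]
        assert max(peaks) > 0
        assert np.argmax(peaks) < len(peaks) - 1      # not the largest step

    def test_empty_protocol_rejected(self):
        with pytest.raises(ValueError):
            mb.ClampProtocol(hold_mv=-80.0, steps_mv=(), step_ms=10.0)
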