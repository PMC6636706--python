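"""Membrane dynamics: receptor waveforms, Mg block, GHK, bAP, circuit."""

import math

import numpy as np
import pytest

from erspine import electrical, engine, parameters, protocols


class TestReceptorWaveforms:
    def test_ampar_zero_at_onset_and_late(self, params):
        assert electrical.ampar_conductance(0.0, params) == pytest.approx(0.0)
        assert electrical.ampar_conductance(1.0, params) == pytest.approx(0.0, abs=1e-12)

    def test_ampar_peak_location_and_value(self, params):
        el = params.electrical
        t_star = (math.log(el.tau_ampa_decay / el.tau_ampa_rise)
                  * el.tau_ampa_decay * el.tau_ampa_rise
                  / (el.tau_ampa_decay - el.tau_ampa_rise))
        assert t_star == pytest.approx(0.512e-3, rel=1e-3)
        peak = electrical.ampar_conductance(t_star, params)
        assert peak == pytest.approx(0.3485, rel=1e-3)
        # t_star is the maximum
        ts = np.linspace(0, 0.02, 2000)
        assert electrical.ampar_conductance(ts, params).max() <= peak + 1e-12

    def test_train_sums_pulse_waveforms(self, params):
        single = electrical.ampar_conductance(0.003, params)
        double = electrical.ampar_conductance(
            0.003, params, pulse_times=(0.0, 0.003))
        assert double == pytest.approx(single + 0.0)

    def test_mg_block_printed_sigmoid(self, params):
        assert electrical.mg_block(0.0, params) == pytest.approx(1 / 1.28)
        assert electrical.mg_block(-70.0, params) == pytest.approx(0.0445, abs=2e-4)

    def test_nmdar_conductance_zero_at_onset(self, params):
        for u in (-70.0, 0.0, 30.0):
            assert electrical.nmdar_conductance(0.0, u, params) == pytest.approx(0.0)


class TestVGCC:
    def test_gate_midpoints(self, params):
        assert electrical.vgcc_m_inf(-20.0, params) == pytest.approx(0.5)
        assert electrical.vgcc_h_inf(-65.0, params) == pytest.approx(0.5)

    def test_fixed_point(self, params):
        u = -48.0
        m = float(electrical.vgcc_m_inf(u, params))
        h = float(electrical.vgcc_h_inf(u, params))
        dm, dh = electrical.vgcc_gate_derivatives(u, m, h, params)
        assert dm == pytest.approx(0.0, abs=1e-12)
        assert dh == pytest.approx(0.0, abs=1e-12)

    def test_closed_gate_no_current(self, params):
        assert electrical.lvgcc_ca_flux(-20.0, 0.0, 0.5, 0.05, params) == 0.0

    def test_ghk_continuous_through_zero(self, params):
        ca, ca_ext, k = 0.05, 2000.0, params.electrical.ghk_slope
        limit = ca_ext - ca
        for u in (-1e-6, 1e-6, -1e-3, 1e-3):
            val = electrical.ghk_driving(u, ca, ca_ext, k)
            assert val == pytest.approx(limit, rel=1e-4)

    def test_flux_inward_below_reversal(self, params):
        for u in np.linspace(0.0, 40.0, 9):
            flux = electrical.lvgcc_ca_flux(u, 0.5, 0.5, 0.05, params)
            assert flux > 0.0


class TestBAP:
    def test_peak_at_onset(self, params):
        assert electrical.bap_waveform(0.0, params) == pytest.approx(67.0)

    def test_causality(self, params):
        assert electrical.bap_waveform(-0.001, params) == 0.0

    def test_printed_decay_value(self, params):
        # 67*(0.7 e^-1 + 0.3 e^-(3/40)) at t = 3 ms
        exact = 67.0 * (0.7 * np.exp(-1.0) + 0.3 * np.exp(-3.0 / 40.0))
        assert electrical.bap_waveform(3e-3, params) == pytest.approx(exact, rel=1e-9)
        assert electrical.bap_waveform(3e-3, params) == pytest.approx(35.90, abs=0.01)

    def test_slope_matches_waveform(self, params):
        t = np.linspace(1e-4, 0.05, 200)
        num = np.gradient(electrical.bap_waveform(t, params), t)
        ana = electrical.bap_slope(t, params)
        assert np.allclose(num[2:-2], ana[2:-2], rtol=5e-3)


class TestCircuit:
    def test_rest_is_fixed_point(self, params):
        u = params.electrical.u_rest
        m = float(electrical.vgcc_m_inf(u, params))
        h = float(electrical.vgcc_h_inf(u, params))
        # the rest state is defined with the L-VGCC disengaged (its tiny
        # residual window current at -70 mV is a protocol-dependent term)
        du, dud = electrical.voltage_derivatives(
            u, u, m, h, 0.05, ampa_wave=0.0, nmda_wave=0.0, params=params,
            vgcc_enabled=False, dendrite_mode="passive")
        assert du == pytest.approx(0.0, abs=1e-9)
        assert dud == pytest.approx(0.0, abs=1e-9)

    def test_unitary_epsp_depolarization_few_mv(self, params, epsp_er_minus):
        depol = epsp_er_minus.u.max() - params.electrical.u_rest
        assert 1.0 <= depol <= 8.0

    def test_infinite_neck_resistance_decouples(self, params):
        p = params.copy(R_C=float("inf"))
        traj = engine.run(protocols.single_bap(duration=0.5), p, er=False)
        assert np.abs(traj.u - p.electrical.u_rest).max() < 0.05

    def test_bap_spine_depolarization_monotone_in_v0(self, params):
        peaks = []
        for v0 in (40.0, 67.0):
            traj = engine.run(protocols.single_bap(duration=0.4),
                              params.copy(V_0=v0), er=False)
            peaks.append(traj.u.max())
        assert peaks[1] > peaks[0]


def test_engine_rhs_matches_module_formulas(params):
    """The engine's inlined fast path must agree with the module functions."""
    from erspine import calcium, er_store, mglur_cascade, plasticity

    rest = engine.find_rest(params, er=True)
    y = rest.y.copy()
    # perturb away from rest so every term is exercised
    rng = np.random.default_rng(7)
    y[engine.I_U] += 11.0
    y[engine.I_UD] += 25.0
    y[engine.I_CA] = 0.4
    y[engine.I_HER] = 0.55
    y[engine.I_W] = 0.1
    y[engine.BUF] *= rng.uniform(0.8, 1.2, calcium.N_BUFFER_STATES)
    y[engine.CASC] *= rng.uniform(0.8, 1.2, mglur_cascade.N_SPECIES)

    glu_events = (0.02,)
    t = 0.035
    rhs = engine._make_rhs(params, er=True, vgcc=True, dendrite_mode="passive",
                           glu_active=glu_events, bap_active=(),
                           k_s_eff=rest.k_s_eff, ip3_source=rest.ip3_source)
    dy = rhs(t, y)

    ampa = electrical.ampar_conductance(t, params, glu_events) / params.electrical.g_ampa
    nmda = electrical.nmdar_gating(t, params, glu_events)
    glu = mglur_cascade.glutamate_pulse(t, params, glu_events)
    du, dud = electrical.voltage_derivatives(
        y[engine.I_U], y[engine.I_UD], y[engine.I_M], y[engine.I_H],
        y[engine.I_CA], ampa_wave=ampa, nmda_wave=nmda, params=params,
        vgcc_enabled=True, dendrite_mode="passive")
    assert dy[engine.I_U] == pytest.approx(du, rel=1e-9)
    assert dy[engine.I_UD] == pytest.approx(dud, rel=1e-9)

    j_n = calcium.nmdar_ca_flux(y[engine.I_U], y[engine.I_CA], nmda, params)
    j_v = electrical.lvgcc_ca_flux(y[engine.I_U], y[engine.I_M], y[engine.I_H],
                                   y[engine.I_CA], params)
    db, j_b = calcium.buffer_derivatives(y[engine.I_CA], y[engine.BUF], params)
    dp, j_o = calcium.pump_flux(y[engine.I_CA], y[engine.PUMP], params)
    dcasc, j_c = mglur_cascade.cascade_derivatives(
        y[engine.CASC], glu, y[engine.I_CA], params, rest.ip3_source)
    j_er = er_store.er_net_flux(y[engine.I_IP3], y[engine.I_CA],
                                y[engine.I_HER], params, rest.k_s_eff)
    dca = calcium.calcium_derivative(j_n, j_v, j_er, j_b, j_o, j_c)
    assert dy[engine.I_CA] == pytest.approx(dca, rel=1e-9)
    np.testing.assert_allclose(dy[engine.BUF], db, rtol=1e-9)
    np.testing.assert_allclose(dy[engine.PUMP], dp, rtol=1e-9)
    np.testing.assert_allclose(dy[engine.CASC], dcasc, rtol=1e-9, atol=1e-12)

    acam = plasticity.active_cam(
        (y[engine._CAM_C0], None, None, y[engine._CAM_N0]), params)
    assert dy[engine.I_W] == pytest.approx(
        plasticity.weight_derivative(y[engine.I_W], acam, params), rel=1e-9)
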