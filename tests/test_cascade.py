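"""mGluR-PLC-IP3 cascade: drive, topology, conservation, basal balance."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.integrate import solve_ivp

from erspine import mglur_cascade as mc
from erspine import parameters


def _random_cascade_state(params, rng):
    c = params.cascade
    y = np.zeros(mc.N_SPECIES)
    r = rng.dirichlet(np.ones(4)) * c.mglur_total
    y[mc.IDX["R"]], y[mc.IDX["RL"]], y[mc.IDX["RG"]], y[mc.IDX["RLG"]] = r
    # split the G-protein among free/complexed alpha forms
    g = rng.dirichlet(np.ones(5)) * (c.gq_total - r[2] - r[3])
    y[mc.IDX["Gq"]], y[mc.IDX["Ga"]], y[mc.IDX["GaGDP"]] = g[0], g[1], g[2]
    plc_g = g[3:5]
    y[mc.IDX["Gbg"]] = c.gq_total - (y[mc.IDX["Gq"]] + r[2] + r[3])
    p = rng.dirichlet(np.ones(6)) * c.plc_total
    for val, name in zip(p, ("PLC", "PLC_Ca", "PLC_G", "PLC_Ca_G",
                             "PLC_Ca_P", "PLC_Ca_G_P")):
        y[mc.IDX[name]] = val
    y[mc.IDX["IP3"]] = rng.uniform(0.01, 5.0)
    y[mc.IDX["DAG"]] = rng.uniform(0.0, 5.0)
    k = rng.dirichlet(np.ones(3)) * c.ip3k_total
    y[mc.IDX["K"]], y[mc.IDX["K_Ca2"]], y[mc.IDX["K_Ca2_IP3"]] = k
    p5 = rng.uniform(0, 1)
    y[mc.IDX["P5"]] = p5 * c.ip5p_total
    y[mc.IDX["P5_IP3"]] = (1 - p5) * c.ip5p_total
    return y


class TestGlutamatePulse:
    def test_peak_amplitude_at_time_constant(self, params):
        assert mc.glutamate_pulse(1e-3, params) == pytest.approx(300.0)

    def test_zero_at_onset_and_before(self, params):
        assert mc.glutamate_pulse(0.0, params) == 0.0
        assert mc.glutamate_pulse(-1e-3, params) == 0.0

    def test_alpha_tail_value(self, params):
        # 300 * 10 * e^-9 at t = 10 ms
        assert mc.glutamate_pulse(10e-3, params) == pytest.approx(
            300.0 * 10.0 * np.exp(-9.0), rel=1e-9)
        assert mc.glutamate_pulse(10e-3, params) == pytest.approx(0.370, abs=5e-3)

    def test_train_sums(self, params):
        v1 = mc.glutamate_pulse(6e-3, params)
        v2 = mc.glutamate_pulse(6e-3, params, pulse_times=(0.0, 5e-3))
        assert v2 == pytest.approx(v1 + mc.glutamate_pulse(1e-3, params))


class TestTopology:
    @given(seed=st.integers(0, 500), glu=st.floats(0.0, 300.0),
           ca=st.floats(0.001, 20.0))
    def test_hand_coded_matches_reaction_table(self, seed, glu, ca):
        """The fast derivative path equals the declarative-table evaluator."""
        params = parameters.default_parameters()
        y = _random_cascade_state(params, np.random.default_rng(seed))
        d1, j1 = mc.cascade_derivatives(y, glu, ca, params, 0.17)
        d2, j2 = mc.table_derivatives(y, glu, ca, params, 0.17)
        np.testing.assert_allclose(d1, d2, rtol=1e-12, atol=1e-12)
        assert j1 == pytest.approx(j2, rel=1e-12, abs=1e-12)

    @given(seed=st.integers(0, 500), glu=st.floats(0.0, 300.0),
           ca=st.floats(0.001, 20.0))
    def test_conserved_totals_are_invariant(self, seed, glu, ca):
        params = parameters.default_parameters()
        y = _random_cascade_state(params, np.random.default_rng(seed))
        dy, _ = mc.cascade_derivatives(y, glu, ca, params, 0.0)
        g = {n: dy[mc.IDX[n]] for n in mc.SPECIES}
        assert abs(g["R"] + g["RL"] + g["RG"] + g["RLG"]) < 1e-9
        assert abs(g["Gq"] + g["RG"] + g["RLG"] + g["Ga"] + g["GaGDP"]
                   + g["PLC_G"] + g["PLC_Ca_G"] + g["PLC_Ca_G_P"]) < 1e-9
        assert abs(g["Gbg"] + g["Gq"] + g["RG"] + g["RLG"]) < 1e-9
        assert abs(sum(g[n] for n in ("PLC", "PLC_Ca", "PLC_G", "PLC_Ca_G",
                                      "PLC_Ca_P", "PLC_Ca_G_P"))) < 1e-9
        assert abs(g["K"] + g["K_Ca2"] + g["K_Ca2_IP3"]) < 1e-9
        assert abs(g["P5"] + g["P5_IP3"]) < 1e-9

    def test_every_rate_symbol_used_once(self, params):
        symbols = [r.rate_symbol for r in mc.reaction_table(params)]
        assert len(symbols) == len(set(symbols))
        expected = ({f"a{i}" for i in range(1, 9)}
                    | {f"b{i}" for i in range(1, 13)}
                    | {f"c{i}" for i in range(1, 6)})
        assert set(symbols) == expected

    def test_table_export_is_readable(self, params):
        text = mc.format_reaction_table(params)
        assert "b7" in text and "IP3" in text and "kf=" in text


class TestBasalBalance:
    def test_source_pins_resting_ip3(self, params):
        source = mc.basal_ip3_balance(params)
        assert source > 0.0
        y0 = mc.basal_state(params, source)
        ca = params.concentrations.ca_rest

        def rhs(_t, y):
            return mc.cascade_derivatives(y, 0.0, ca, params, source)[0]
        sol = solve_ivp(rhs, (0.0, 200.0), y0, method="LSODA",
                        rtol=1e-8, atol=1e-12)
        assert sol.y[mc.I_IP3, -1] == pytest.approx(0.1, abs=1e-3)

    def test_without_source_ip3_falls_below_resting(self, params):
        y = mc.stationary_state(params, glu=0.0,
                               ca=params.concentrations.ca_rest,
                               ip3_source=0.0)
        assert y[mc.I_IP3] < params.concentrations.ip3_rest

    def test_more_phosphatase_lowers_stationary_ip3(self, params):
        source = mc.basal_ip3_balance(params)
        base = mc.stationary_state(params, 0.0, 0.05, ip3_source=source)
        heavy = mc.stationary_state(params.copy(IP5P_total=2.0), 0.0, 0.05,
                                    ip3_source=source)
        assert heavy[mc.I_IP3] < base[mc.I_IP3]

    def test_basal_state_is_stationary(self, params):
        source = mc.basal_ip3_balance(params)
        y = mc.basal_state(params, source)
        dy, _ = mc.cascade_derivatives(y, 0.0, params.concentrations.ca_rest,
                                       params, source)
        assert np.abs(dy).max() < 1e-9


class TestDynamics:
    def test_sustained_glutamate_raises_ip3_within_a_second(self, params):
        source = mc.basal_ip3_balance(params)
        y0 = mc.basal_state(params, source)

        def rhs(_t, y):
            return mc.cascade_derivatives(y, 300.0, 0.05, params, source)[0]
        sol = solve_ivp(rhs, (0.0, 1.0), y0, method="LSODA",
                        rtol=1e-8, atol=1e-12)
        assert sol.y[mc.I_IP3, -1] > 0.1

    def test_latency_in_the_few_hundred_ms_range(self, params):
        delay = mc.ip3_timecourse_latency(params)
        assert delay is not None
        assert 100.0 <= delay <= 1000.0

    def test_unscaled_source_rates_respond_faster(self, params):
        fast = params.copy(a1b=100.0, a2b=100.0, b11=8.0)
        assert mc.ip3_timecourse_latency(fast) < mc.ip3_timecourse_latency(params)

    def test_no_glutamate_no_event(self, params):
        class Empty:
            glu_times = ()
        assert mc.ip3_timecourse_latency(params, protocol=Empty()) is None

    def test_ip3_production_monotone_in_receptor_count(self, params):
        source = mc.basal_ip3_balance(params)
        y0 = mc.basal_state(params, source)

        def peak(p, y_init):
            def rhs(t, y):
                glu = mc.glutamate_pulse(t, p, (0.0,))
                return mc.cascade_derivatives(y, glu, 0.05, p, source)[0]
            sol = solve_ivp(rhs, (0.0, 2.0), y_init, method="LSODA",
                            rtol=1e-8, atol=1e-12, dense_output=True)
            return sol.sol(np.linspace(0, 2, 400))[mc.I_IP3].max()

    # scale receptor number only; conserved total adjusts with it
        more = params.copy(mGluR_total=0.45)
        y0b = y0.copy()
        y0b[mc.IDX["R"]] += 0.15
        assert peak(more, y0b) > peak(params, y0)
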