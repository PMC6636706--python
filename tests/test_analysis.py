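"""Trajectory metrics, curves, shifts and the sampling machinery."""

import numpy as np
import pytest

from erspine import analysis, engine, parameters, protocols
from erspine.analysis import PlasticityCurve


def _synthetic_trajectory(params, t, ca):
    """Wrap a constructed Ca2+ trace in a Trajectory."""
    y = np.zeros((len(t), engine.N_STATE))
    y[:, engine.I_CA] = ca
    proto = protocols.StimulusProtocol(
        glu_times=(0.1,), bap_times=(), co_input=False, vgcc=False,
        duration=float(t[-1]), label="synthetic")
    return engine.Trajectory(t=t, y=y, protocol=proto, params=params,
                             er=True, k_s_eff=0.0, ip3_source=0.0)


class TestPeakMetrics:
    def test_two_gaussians_give_programmed_delay(self, params):
        t = np.linspace(0.0, 2.0, 4001)
        ca = (0.05 + 0.2 * np.exp(-0.5 * ((t - 0.2) / 0.02) ** 2)
              + 0.3 * np.exp(-0.5 * ((t - 0.5) / 0.05) ** 2))
        traj = _synthetic_trajectory(params, t, ca)
        assert analysis.iccr_delay(traj) == pytest.approx(400.0, abs=2.0)

    def test_equal_bumps_give_unit_ratio(self, params):
        t = np.linspace(0.0, 2.0, 4001)
        bump = lambda mu: 0.25 * np.exp(-0.5 * ((t - mu) / 0.03) ** 2)
        traj = _synthetic_trajectory(params, t, 0.05 + bump(0.2) + bump(0.6))
        assert analysis.peak_ratio(traj) == pytest.approx(1.0, abs=1e-3)

    def test_er_minus_trace_reports_no_event(self, epsp_er_minus):
        assert analysis.iccr_delay(epsp_er_minus) is None
        assert analysis.peak_ratio(epsp_er_minus) is None

    def test_flat_trace_raises(self, params):
        t = np.linspace(0.0, 1.0, 101)
        traj = _synthetic_trajectory(params, t, np.full_like(t, 0.05))
        with pytest.raises(ValueError):
            analysis.iccr_delay(traj)

    def test_delay_insensitive_to_sampling_density(self, params):
        for n in (2001, 10001):
            t = np.linspace(0.0, 2.0, n)
            ca = (0.05 + 0.2 * np.exp(-0.5 * ((t - 0.2) / 0.02) ** 2)
                  + 0.3 * np.exp(-0.5 * ((t - 0.5) / 0.05) ** 2))
            traj = _synthetic_trajectory(params, t, ca)
            assert analysis.iccr_delay(traj) == pytest.approx(400.0, abs=2.0)


class TestPopenMap:
    def test_basal_column_is_small(self, params):
        ca_grid = np.geomspace(0.02, 2.0, 8)
        pmap = analysis.steady_state_popen_map(ca_grid, [0.0], params)
        assert np.nanmax(pmap) < 1e-4

    def test_inhibition_branch_decreasing(self, params):
        ca_grid = np.geomspace(1.0, 3.0, 6)
        pmap = analysis.steady_state_popen_map(ca_grid, [1.0], params)
        assert np.all(np.diff(pmap[0]) < 0)


class TestCurveMetrics:
    @staticmethod
    def _rate_curve(shift=0.0):
        grid = np.arange(0.5, 20.1, 0.5)
        dw = np.clip(0.02 * (grid - 10.0 - shift), -0.3, 0.5)
        dw[grid < 2.0 + shift] = 0.0
        return PlasticityCurve(grid=grid, dw=dw, kind="rate", er=False)

    def test_identical_curves_zero_shift(self):
        c = self._rate_curve()
        assert analysis.threshold_shifts(c, c) == (0.0, 0.0)

    def test_programmed_half_hz_shift_recovered(self):
        a, b = self._rate_curve(0.0), self._rate_curve(0.5)
        dfd, dfp = analysis.threshold_shifts(a, b)
        assert dfp == pytest.approx(0.5, abs=1e-9)
        assert dfd == pytest.approx(0.5, abs=0.5)  # onset quantized by grid

    def test_window_widths_of_box_curve(self):
        grid = np.arange(-50.0, 50.1, 1.0)
        dw = np.where((grid > -30) & (grid < -10), -0.2,
                      np.where((grid > 5) & (grid < 25), 0.3, 0.0))
        c = PlasticityCurve(grid=grid, dw=dw, kind="stdp_triplet", er=False)
        ltd, ltp = analysis.window_widths(c)
        assert ltd == pytest.approx(20.0, abs=2.5)
        assert ltp == pytest.approx(20.0, abs=2.5)

    def test_mismatched_grids_rejected(self):
        a = self._rate_curve()
        b = PlasticityCurve(grid=a.grid[:-1], dw=a.dw[:-1], kind="rate",
                            er=True)
        with pytest.raises(ValueError):
            analysis.threshold_shifts(a, b)


class TestSteadyWindow:
    def test_max_over_last_fifth(self, params):
        t = np.linspace(0.0, 10.0, 1001)
        proto = protocols.rate_train(1.0, n_spikes=9, margin=1.0)
        y = np.zeros((len(t), engine.N_STATE))
        # C0/N0 encode an aCaM ramp; peak value sits in the final window
        total = params.buffering.cam_total
        y[:, engine._CAM_C0] = total * (1.0 - t / 20.0)
        y[:, engine._CAM_N0] = total
        traj = engine.Trajectory(t=t, y=y, protocol=proto, params=params,
                                 er=False, k_s_eff=0.0, ip3_source=0.0)
        expect = traj.acam[t <= proto.glu_times[-1] + 1.0].max()
        assert analysis.steady_window_max(traj, "acam") == pytest.approx(
            expect, rel=1e-6)


class TestSampling:
    def test_zero_draws_empty(self, params):
        out = analysis.sensitivity_sample(
            params, "stdp_triplet", 0, seed=3, lo_range=(-45, -25),
            hi_range=(25, 45), n_r_values=(30,), grid=np.array([-40.0, 40.0]),
            n_events=1)
        assert out == []

    def test_same_seed_reproduces_draws(self, params):
        kwargs = dict(n_draws=4, seed=11, lo_range=(-45.0, -25.0),
                      hi_range=(25.0, 45.0), n_r_values=(30.0,),
                      grid=np.arange(-40.0, 60.1, 20.0), n_events=2)
        a = analysis.sensitivity_sample(params, "stdp_triplet", **kwargs)
        b = analysis.sensitivity_sample(params, "stdp_triplet", **kwargs)
        assert a == b
        assert all(s.seed == 11 for s in a)
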