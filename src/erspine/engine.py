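"""Full spine ODE system: rest-state solving and protocol integration.

The state vector concatenates the electrical variables, free Ca2+, all
buffer/pump species, the IP3R inactivation gate, the mGluR cascade and
the synaptic weight::

    0   u        spine potential (mV)
    1   u_d      dendrite potential (mV)
    2   m_u      L-VGCC activation
    3   h_u      L-VGCC inactivation
    4   Ca       free cytosolic Ca2+ (uM)
    5-23         buffer species (see calcium module)
    24-27        PMCA/NCX pump states
    28  h        IP3R inactivation
    29-49        cascade species (see mglur_cascade module)
    50  w        synaptic weight

The layout is fixed regardless of ER presence; ER-lacking runs simply
carry J_ER = 0.  Stimulation is integrated in per-event segments with
event onsets as forced mesh points (the inputs are smooth except for
their step-function onsets).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.integrate import solve_ivp

from . import calcium, electrical, er_store, mglur_cascade, plasticity
from .parameters import ParameterSet
from .protocols import StimulusProtocol

log = logging.getLogger("erspine")

I_U, I_UD, I_M, I_H, I_CA = 0, 1, 2, 3, 4
BUF = slice(5, 5 + calcium.N_BUFFER_STATES)            # 5..23
PUMP = slice(BUF.stop, BUF.stop + calcium.N_PUMP_STATES)  # 24..27
I_HER = PUMP.stop                                       # 28
CASC = slice(I_HER + 1, I_HER + 1 + mglur_cascade.N_SPECIES)  # 29..49
I_W = CASC.stop                                         # 50
N_STATE = I_W + 1

I_IP3 = CASC.start + mglur_cascade.I_IP3
_CAM_C0 = BUF.start + 13
_CAM_N0 = BUF.start + 16

# waveform lookback windows (s); beyond these the kernels are < 5e-5 of peak
_WIN_AMPA = 0.05
_WIN_NMDA = 0.8
_WIN_GLU = 0.03
_WIN_BAP = 0.6


class SolverError(RuntimeError):
    """Integration failure (step-size underflow, NaN or negative state)."""


@dataclass
class SpineState:
    """A full dynamical state plus the rest-balance metadata."""

    y: np.ndarray
    params: ParameterSet
    k_s_eff: float = 0.0
    ip3_source: float = 0.0
    residual: float = 0.0

    @property
    def u(self): return float(self.y[I_U])
    @property
    def u_d(self): return float(self.y[I_UD])
    @property
    def ca(self): return float(self.y[I_CA])
    @property
    def h(self): return float(self.y[I_HER])
    @property
    def ip3(self): return float(self.y[I_IP3])
    @property
    def w(self): return float(self.y[I_W])


def _cache(params: ParameterSet) -> dict:
    cache = getattr(params, "_erspine_cache", None)
    if cache is None:
        cache = {}
        object.__setattr__(params, "_erspine_cache", cache)
    return cache


def basal_ip3_source(params: ParameterSet) -> float:
    """Cached constitutive IP3 source (see mglur_cascade.basal_ip3_balance)."""
    cache = _cache(params)
    if "ip3_source" not in cache:
        cache["ip3_source"] = mglur_cascade.basal_ip3_balance(params)
    return cache["ip3_source"]


# ---------------------------------------------------------------------------
# Right-hand side
# ---------------------------------------------------------------------------

def _make_rhs(params: ParameterSet, *, er: bool, vgcc: bool,
              dendrite_mode: str, glu_active, bap_active,
              k_s_eff: float, ip3_source: float):
    """Compiled scalar RHS for one integration segment.

    The hot formulas (waveforms, Mg block, GHK driving, membrane
    equation) are inlined with hoisted constants; module-level functions
    remain the vectorized reference implementations and the test suite
    asserts agreement.
    """
    el, geo, conc = params.electrical, params.geometry, params.concentrations
    exp = math.exp

    ta_r, ta_d = el.tau_ampa_rise, el.tau_ampa_decay
    tn_r, tn_d = el.tau_nmda_rise, el.tau_nmda_decay
    tau_glu, g_max = params.cascade.tau_glu, params.cascade.g_max
    tb_f, tb_s = el.tau_bap_fast, el.tau_bap_slow
    fb, sb, v0 = el.bap_fast_frac, el.bap_slow_frac, el.v0_bap
    mg_b0, mg_k = el.mg_b0, el.mg_slope
    ghk_k = el.ghk_slope
    ca_ext = conc.ca_ext
    u_rest = el.u_rest

    a_cm2 = geo.a_spine * 1.0e-8
    c_spine = el.c_m * 1.0e-6 * a_cm2
    g_leak_tot = el.g_leak * a_cm2
    g_coup = 0.0 if math.isinf(el.r_c) else 1.0 / (el.r_c * 1.0e6)
    flux_to_amp = 2.0 * 96485.0 * 1.0e-21 * geo.v_spine
    inv_cm_area = 1.0 / (el.c_m * 1.0e-6)
    rho_scale = el.rho_s * 1.0e-9

    g_nmda_ca_per_v = el.g_nmda_ca / geo.v_spine
    g_lvgcc_per_v = el.g_lvgcc / geo.v_spine
    u_m, k_m, tau_m = el.u_m, el.k_m, el.tau_m
    u_h, k_h, tau_h = el.u_h, el.k_h, el.tau_h

    glu_active = tuple(glu_active)
    bap_active = tuple(bap_active)
    prescribed = dendrite_mode == "prescribed"
    co_input = dendrite_mode == "co_input"

    def ghk(u, ca):
        x = ghk_k * u
        if -1.0e-4 < x < 1.0e-4:
            return (ca_ext - ca) - 0.5 * x * (ca_ext + ca)
        e = exp(-x)
        return x * (ca_ext * e - ca) / (1.0 - e)

    def rhs(t, y):
        u = y[I_U]
        u_d = y[I_UD]
        m_u = y[I_M]
        h_u = y[I_H]
        ca = y[I_CA]

        # input waveforms
        ampa = nmda = glu = 0.0
        for t0 in glu_active:
            d = t - t0
            if d >= 0.0:
                if d < _WIN_AMPA:
                    ampa += exp(-d / ta_d) - exp(-d / ta_r)
                if d < _WIN_NMDA:
                    nmda += exp(-d / tn_d) - exp(-d / tn_r)
                if d < _WIN_GLU:
                    glu += g_max * (d / tau_glu) * exp(1.0 - d / tau_glu)

        b_u = 1.0 / (1.0 + mg_b0 * exp(-mg_k * u))

        # membrane equation (currents in amperes)
        i_leak = g_leak_tot * (u - u_rest) * 1.0e-3
        i_ampa = el.g_ampa * ampa * 1.0e-9 * (u - el.e_ampa) * 1.0e-3
        i_nmda = el.g_nmda * nmda * b_u * 1.0e-9 * (u - el.e_nmda) * 1.0e-3
        if vgcc:
            j_vgcc = m_u * m_u * h_u * g_lvgcc_per_v * ghk(u, ca)
            i_vgcc = -j_vgcc * flux_to_amp
        else:
            j_vgcc = 0.0
            i_vgcc = 0.0
        i_coup = (u - u_d) * 1.0e-3 * g_coup
        du = -(i_leak + i_ampa + i_nmda + i_vgcc + i_coup) / c_spine * 1.0e3

        # dendrite
        if prescribed:
            dud = 0.0
            for t0 in bap_active:
                d = t - t0
                if 0.0 <= d < _WIN_BAP:
                    dud -= v0 * (fb / tb_f * exp(-d / tb_f)
                                 + sb / tb_s * exp(-d / tb_s))
        elif co_input:
            b_d = 1.0 / (1.0 + mg_b0 * exp(-mg_k * u_d))
            g_syn = rho_scale * (el.g_ampa * ampa + el.g_nmda * nmda * b_d)
            dud = (-el.g_leak * (u_d - u_rest) - g_syn * u_d) * inv_cm_area
        else:
            dud = -el.g_leak * (u_d - u_rest) * inv_cm_area

        # VGCC gates
        dm = (1.0 / (1.0 + exp(-(u - u_m) / k_m)) - m_u) / tau_m
        dh = (1.0 / (1.0 + exp(-(u - u_h) / k_h)) - h_u) / tau_h

        # calcium fluxes
        j_nmda = g_nmda_ca_per_v * nmda * b_u * ghk(u, ca)
        db, j_buf = calcium.buffer_derivatives(ca, y[BUF], params)
        dp, j_out = calcium.pump_flux(ca, y[PUMP], params)
        dcasc, j_casc = mglur_cascade.cascade_derivatives(
            y[CASC], glu, ca, params, ip3_source)

        h_er = y[I_HER]
        if er:
            j_er = er_store.er_net_flux(y[I_IP3], ca, h_er, params, k_s_eff)
        else:
            j_er = 0.0
        dher = er_store.h_derivative(h_er, ca, params)

        dca = calcium.calcium_derivative(j_nmda, j_vgcc, j_er, j_buf,
                                         j_out, j_casc)

        # plasticity
        cam_total = params.buffering.cam_total
        if cam_total > 0.0:
            acam = cam_total * (1.0 - (y[_CAM_C0] / cam_total)
                                * (y[_CAM_N0] / cam_total))
        else:
            acam = 0.0
        dw = plasticity.weight_derivative(y[I_W], acam, params)

        dy = np.empty(N_STATE)
        dy[I_U] = du
        dy[I_UD] = dud
        dy[I_M] = dm
        dy[I_H] = dh
        dy[I_CA] = dca
        dy[BUF] = db
        dy[PUMP] = dp
        dy[I_HER] = dher
        dy[CASC] = dcasc
        dy[I_W] = dw
        return dy

    return rhs


# ---------------------------------------------------------------------------
# Rest state
# ---------------------------------------------------------------------------

def find_rest(params: ParameterSet, er: bool = True,
              tol: float = 1e-9) -> SpineState:
    """The stationary state of the unstimulated spine.

    Assembled from closed-form buffer/pump equilibria at resting Ca2+,
    the basal cascade stationarity (with its constitutive IP3 source)
    and h at its Ca-dependent steady state.  For the ER-bearing spine
    the effective SERCA leak is trimmed so that the net ER flux vanishes
    at rest despite the small basal IP3R flux; the trim is logged.  The
    residual of the full right-hand side is verified against ``tol``.
    """
    cache = _cache(params)
    key = ("rest", er)
    if key in cache:
        return cache[key]

    conc = params.concentrations
    ca0 = conc.ca_rest
    source = basal_ip3_source(params)

    y = np.zeros(N_STATE)
    y[I_U] = params.electrical.u_rest
    y[I_UD] = params.electrical.u_rest
    y[I_M] = float(electrical.vgcc_m_inf(params.electrical.u_rest, params))
    y[I_H] = float(electrical.vgcc_h_inf(params.electrical.u_rest, params))
    y[I_CA] = ca0
    y[BUF] = calcium.equilibrium_buffers(ca0, params)
    y[PUMP] = calcium.equilibrium_pumps(ca0, params)
    y[I_HER] = float(er_store.h_inf(ca0, params))
    y[CASC] = mglur_cascade.basal_state(params, source)
    y[I_W] = 0.0

    k_s_eff = params.er.k_serca_leak
    if er:
        k_s_eff = er_store.trimmed_serca_leak(params)
        if abs(k_s_eff - params.er.k_serca_leak) > 1e-12:
            log.info("rest balance: effective SERCA leak trimmed from "
                     "%.6g to %.6g s^-1 to offset basal IP3R flux",
                     params.er.k_serca_leak, k_s_eff)

    rhs = _make_rhs(params, er=er, vgcc=False, dendrite_mode="passive",
                    glu_active=(), bap_active=(), k_s_eff=k_s_eff,
                    ip3_source=source)
    dy = rhs(0.0, y)
    worst = int(np.argmax(np.abs(dy)))
    residual = float(np.max(np.abs(dy)))
    if residual > tol:
        raise RuntimeError(
            f"rest state residual {residual:.3g} exceeds {tol:.3g} "
            f"(worst component index {worst})")
    state = SpineState(y=y, params=params, k_s_eff=k_s_eff,
                       ip3_source=source, residual=residual)
    cache[key] = state
    return state


# ---------------------------------------------------------------------------
# Trajectories
# ---------------------------------------------------------------------------

@dataclass
class Trajectory:
    """Sampled states and derived flux channels for one simulation run."""

    t: np.ndarray
    y: np.ndarray
    protocol: StimulusProtocol
    params: ParameterSet
    er: bool
    k_s_eff: float
    ip3_source: float
    solver: dict = field(default_factory=dict)
    _fluxes: Optional[dict] = None

    @property
    def u(self): return self.y[:, I_U]
    @property
    def u_d(self): return self.y[:, I_UD]
    @property
    def ca(self): return self.y[:, I_CA]
    @property
    def ip3(self): return self.y[:, I_IP3]
    @property
    def w(self): return self.y[:, I_W]

    @property
    def acam(self):
        total = self.params.buffering.cam_total
        if total <= 0.0:
            return np.zeros(len(self.t))
        return total * (1.0 - (self.y[:, _CAM_C0] / total)
                        * (self.y[:, _CAM_N0] / total))

    def _summed(self, fn, events, window):
        out = np.zeros(len(self.t))
        for t0 in events:
            i0 = np.searchsorted(self.t, t0)
            i1 = np.searchsorted(self.t, t0 + window)
            if i1 > i0:
                out[i0:i1] += fn(self.t[i0:i1] - t0)
        return out

    def fluxes(self) -> dict:
        """Derived flux channels, recomputed exactly from the snapshots."""
        if self._fluxes is not None:
            return self._fluxes
        p = self.params
        el = p.electrical
        glu_ev = self.protocol.glu_times
        nmda = self._summed(
            lambda d: np.exp(-d / el.tau_nmda_decay) - np.exp(-d / el.tau_nmda_rise),
            glu_ev, _WIN_NMDA)
        glu = self._summed(
            lambda d: p.cascade.g_max * (d / p.cascade.tau_glu)
            * np.exp(1.0 - d / p.cascade.tau_glu), glu_ev, _WIN_GLU)
        j_nmda = calcium.nmdar_ca_flux(self.u, self.ca, nmda, p)
        if self.protocol.vgcc:
            j_vgcc = electrical.lvgcc_ca_flux(self.u, self.y[:, I_M],
                                              self.y[:, I_H], self.ca, p)
        else:
            j_vgcc = np.zeros(len(self.t))
        h_er = self.y[:, I_HER]
        popen = er_store.ip3r_open_fraction(self.ip3, self.ca, h_er, p)
        if self.er:
            j_iccr = er_store.iccr_flux(popen, self.ca, p)
            uptake, leak = er_store.serca_flux(self.ca, p, self.k_s_eff)
            j_er = j_iccr - uptake + leak
        else:
            j_iccr = np.zeros(len(self.t))
            uptake = np.zeros(len(self.t))
            leak = np.zeros(len(self.t))
            j_er = np.zeros(len(self.t))
        e = p.extrusion
        pump = self.y[:, PUMP]
        j_out = (e.pmca_kf * self.ca * pump[:, 0] - e.pmca_kb * pump[:, 1]
                 - e.pmca_kl * pump[:, 0]
                 + e.ncx_kf * self.ca * pump[:, 2] - e.ncx_kb * pump[:, 3]
                 - e.ncx_kl * pump[:, 2])
        self._fluxes = {
            "glu": glu, "nmda_gating": nmda, "j_nmda": j_nmda,
            "j_vgcc": j_vgcc, "p_open": popen, "j_iccr": j_iccr,
            "serca_uptake": uptake, "serca_leak": leak, "j_er": j_er,
            "j_out": j_out, "acam": self.acam,
        }
        return self._fluxes

    def to_frame(self):
        """Wide-format table: time, key state channels and fluxes."""
        import pandas as pd
        data = {"t": self.t, "u": self.u, "u_d": self.u_d, "ca": self.ca,
                "ip3": self.ip3, "h": self.y[:, I_HER], "w": self.w}
        data.update(self.fluxes())
        return pd.DataFrame(data)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_npz(self, path) -> None:
        """Compact columnar export (full state plus flux channels)."""
        np.savez_compressed(path, t=self.t, y=self.y,
                            **{k: v for k, v in self.fluxes().items()})


def _sample_grid(t0: float, t1: float, dense_rate: float,
                 dense_window: float, sparse_rate: float) -> np.ndarray:
    dense_end = min(t0 + dense_window, t1)
    pts = [np.arange(t0, dense_end, 1.0 / dense_rate)]
    if dense_end < t1:
        pts.append(np.arange(dense_end, t1, 1.0 / sparse_rate))
    pts.append([t1])
    grid = np.unique(np.concatenate(pts))
    return grid[(grid >= t0) & (grid <= t1)]


def run(protocol: StimulusProtocol, params: ParameterSet, er: bool = True,
        rtol: float = 1e-6, atol_conc: float = 1e-9, atol_volt: float = 1e-6,
        method: str = "LSODA") -> Trajectory:
    """Integrate a stimulation protocol from the rest state.

    Event onsets are forced mesh points; output is sampled densely
    (``protocol.dense_rate``) inside a window after each event and
    sparsely elsewhere.  Raises SolverError on integrator failure, NaNs
    or negative-concentration excursions beyond -1e-9.
    """
    rest = find_rest(params, er=er)
    y = rest.y.copy()
    glu_all = np.asarray(protocol.glu_times, float)
    bap_all = np.asarray(protocol.bap_times, float)

    if protocol.co_input:
        mode = "co_input"
    elif len(bap_all):
        mode = "prescribed"
    else:
        mode = "passive"
    vgcc = protocol.vgcc

    atol = np.full(N_STATE, atol_conc)
    atol[I_U] = atol[I_UD] = atol_volt

    boundaries = np.unique(np.concatenate(
        [[0.0], protocol.events, [protocol.duration]]))
    boundaries = boundaries[(boundaries >= 0.0)
                            & (boundaries <= protocol.duration)]

    ts_out = [np.array([0.0])]
    ys_out = [y[None, :].copy()]
    n_steps = 0

    for t0, t1 in zip(boundaries[:-1], boundaries[1:]):
        if t1 <= t0:
            continue
        if mode == "prescribed":
            y[I_UD] = params.electrical.u_rest + electrical.bap_waveform(
                t0, params, bap_all[bap_all <= t0 + 1e-12])
        glu_active = glu_all[(glu_all <= t1) & (glu_all > t0 - _WIN_NMDA)]
        bap_active = bap_all[(bap_all <= t1) & (bap_all > t0 - _WIN_BAP)]
        rhs = _make_rhs(params, er=er, vgcc=vgcc, dendrite_mode=mode,
                        glu_active=glu_active, bap_active=bap_active,
                        k_s_eff=rest.k_s_eff, ip3_source=rest.ip3_source)
        grid = _sample_grid(t0, t1, protocol.dense_rate,
                            protocol.dense_window, protocol.sparse_rate)
        sol = solve_ivp(rhs, (t0, t1), y, method=method, rtol=rtol,
                        atol=atol, t_eval=grid)
        if not sol.success:
            raise SolverError(f"integration failed at t={sol.t[-1] if len(sol.t) else t0:.4f} s: "
                              f"{sol.message}")
        n_steps += sol.t.size
        y = sol.y[:, -1].copy()
        ts_out.append(sol.t)
        ys_out.append(sol.y.T)

    t = np.concatenate(ts_out)
    yy = np.vstack(ys_out)
    # drop duplicated boundary samples
    keep = np.concatenate([[True], np.diff(t) > 0])
    t, yy = t[keep], yy[keep]

    if not np.all(np.isfinite(yy)):
        raise SolverError("non-finite state encountered")
    conc_cols = np.r_[I_CA, np.arange(BUF.start, PUMP.stop),
                      np.arange(CASC.start, CASC.stop)]
    if yy[:, conc_cols].min() < -1e-9:
        raise SolverError(
            f"negative concentration excursion {yy[:, conc_cols].min():.3g} uM")

    return Trajectory(t=t, y=yy, protocol=protocol, params=params, er=er,
                      k_s_eff=rest.k_s_eff, ip3_source=rest.ip3_source,
                      solver={"method": method, "rtol": rtol,
                              "n_samples": int(len(t))})
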