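"""Spine and dendrite membrane-potential dynamics.

The spine head is a single electrical compartment carrying a passive
leak, AMPAR/NMDAR synaptic currents, an L-type voltage-gated Ca2+
current (GHK form) and resistive coupling to the parent dendrite.  The
dendrite is either passive, driven by a co-active synaptic conductance
density (rate protocols), or follows a prescribed bAP voltage profile
(STDP protocols).
"""

from __future__ import annotations

import math

import numpy as np

from .parameters import ParameterSet

__all__ = [
    "mg_block", "ampar_conductance", "nmdar_gating", "nmdar_conductance",
    "vgcc_m_inf", "vgcc_h_inf", "vgcc_gate_derivatives", "ghk_driving",
    "lvgcc_ca_flux", "lvgcc_current", "bap_waveform", "bap_slope",
    "voltage_derivatives",
]

#: 2F in C/mol; converts (uM/s * um^3) to amperes via 1e-21 mol/s.
_TWO_F = 2.0 * 96485.0
_FLUX_TO_AMP = _TWO_F * 1.0e-21


def mg_block(u, params: ParameterSet):
    """Voltage-dependent Mg2+ block of the NMDAR, B(u) = 1/(1 + 0.28 e^{-0.062 u})."""
    el = params.electrical
    return 1.0 / (1.0 + el.mg_b0 * np.exp(-el.mg_slope * np.asarray(u, float)))


def _two_exp_sum(t, pulse_times, tau_r: float, tau_d: float):
    """Sum of (e^{-dt/tau_d} - e^{-dt/tau_r}) over pulses at or before t."""
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    for t0 in np.atleast_1d(pulse_times):
        dt = t - t0
        mask = dt >= 0.0
        if np.any(mask):
            d = dt[mask] if t.ndim else dt
            out_masked = np.exp(-d / tau_d) - np.exp(-d / tau_r)
            if t.ndim:
                out[mask] += out_masked
            elif mask:
                out += out_masked
    return out if t.ndim else float(out)


def ampar_conductance(t, params: ParameterSet, pulse_times=(0.0,)):
    """AMPAR conductance (nS) at time t for glutamate pulses at pulse_times.

    Each pulse contributes g_A (e^{-dt/tau_d} - e^{-dt/tau_r}); train
    responses are the sum of the per-pulse waveforms.
    """
    el = params.electrical
    return el.g_ampa * _two_exp_sum(t, pulse_times, el.tau_ampa_rise, el.tau_ampa_decay)


def nmdar_gating(t, params: ParameterSet, pulse_times=(0.0,)):
    """Dimensionless glutamate gating waveform of the NMDAR (two-exponential sum)."""
    el = params.electrical
    return _two_exp_sum(t, pulse_times, el.tau_nmda_rise, el.tau_nmda_decay)


def nmdar_conductance(t, u, params: ParameterSet, pulse_times=(0.0,)):
    """NMDAR conductance (nS): glutamate gating times the Mg2+ block B(u)."""
    return params.electrical.g_nmda * nmdar_gating(t, params, pulse_times) * mg_block(u, params)


def vgcc_m_inf(u, params: ParameterSet):
    el = params.electrical
    return 1.0 / (1.0 + np.exp(-(np.asarray(u, float) - el.u_m) / el.k_m))


def vgcc_h_inf(u, params: ParameterSet):
    el = params.electrical
    return 1.0 / (1.0 + np.exp(-(np.asarray(u, float) - el.u_h) / el.k_h))


def vgcc_gate_derivatives(u, m_u, h_u, params: ParameterSet):
    """First-order relaxation of the L-VGCC gates toward their voltage targets."""
    el = params.electrical
    dm = (vgcc_m_inf(u, params) - m_u) / el.tau_m
    dh = (vgcc_h_inf(u, params) - h_u) / el.tau_h
    return dm, dh


def ghk_driving(u, ca, ca_ext, slope):
    """GHK driving term  x (Ca_ext e^{-x} - Ca) / (1 - e^{-x}),  x = slope*u.

    Positive for inward Ca2+ flux (cytosolic Ca far below its GHK
    reversal).  Evaluated by a series expansion for |x| < 1e-4 to remain
    continuous through u = 0:  f -> (Ca_ext - Ca) - x (Ca_ext + Ca)/2.
    """
    u = np.asarray(u, dtype=float)
    x = slope * u
    small = np.abs(x) < 1.0e-4
    x_safe = np.where(small, 1.0, x)
    e = np.exp(-x_safe)
    full = x_safe * (ca_ext * e - ca) / (1.0 - e)
    series = (ca_ext - ca) - 0.5 * x * (ca_ext + ca)
    out = np.where(small, series, full)
    return float(out) if out.ndim == 0 else out


def lvgcc_ca_flux(u, m_u, h_u, ca, params: ParameterSet):
    """Cytosolic Ca2+ influx rate (uM/s) through the L-VGCC cluster."""
    el = params.electrical
    drive = ghk_driving(u, ca, params.concentrations.ca_ext, el.ghk_slope)
    return (m_u * m_u * h_u) * el.g_lvgcc * drive / params.geometry.v_spine


def lvgcc_current(u, m_u, h_u, ca, params: ParameterSet):
    """L-VGCC membrane current in amperes (negative = inward, HH convention)."""
    flux = lvgcc_ca_flux(u, m_u, h_u, ca, params)
    return -flux * params.geometry.v_spine * _FLUX_TO_AMP


def bap_waveform(t, params: ParameterSet, bap_times=(0.0,)):
    """Dendritic bAP depolarization (mV above rest) at time t.

    V0 theta(t) (0.7 e^{-t/tau_f} + 0.3 e^{-t/tau_s}) summed over bAPs;
    the waveform peaks (value V0) at its onset.
    """
    el = params.electrical
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    for t0 in np.atleast_1d(bap_times):
        dt = t - t0
        mask = dt >= 0.0
        if np.any(mask):
            d = dt[mask] if t.ndim else dt
            val = el.v0_bap * (el.bap_fast_frac * np.exp(-d / el.tau_bap_fast)
                              + el.bap_slow_frac * np.exp(-d / el.tau_bap_slow))
            if t.ndim:
                out[mask] += val
            elif mask:
                out += val
    return out if t.ndim else float(out)


def bap_slope(t, params: ParameterSet, bap_times=(0.0,)):
    """Time derivative (mV/s) of the summed bAP waveform (zero at t < onset)."""
    el = params.electrical
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    for t0 in np.atleast_1d(bap_times):
        dt = t - t0
        mask = dt >= 0.0
        if np.any(mask):
            d = dt[mask] if t.ndim else dt
            val = -el.v0_bap * (el.bap_fast_frac / el.tau_bap_fast * np.exp(-d / el.tau_bap_fast)
                                + el.bap_slow_frac / el.tau_bap_slow * np.exp(-d / el.tau_bap_slow))
            if t.ndim:
                out[mask] += val
            elif mask:
                out += val
    return out if t.ndim else float(out)


def voltage_derivatives(u, u_d, m_u, h_u, ca, *, ampa_wave, nmda_wave,
                        params: ParameterSet, vgcc_enabled: bool,
                        dendrite_mode: str, u_d_slope: float = 0.0):
    """Time derivatives (mV/s) of the spine and dendrite potentials.

    Parameters
    ----------
    ampa_wave, nmda_wave : float
        Dimensionless summed conductance waveforms at the current time
        (the conductance parameters multiply them here).
    dendrite_mode : {'passive', 'co_input', 'prescribed'}
        'passive'    - leaky dendrite relaxing to rest;
        'co_input'   - per-area passive compartment driven by the
                       synchronous synaptic conductance density rho_S;
        'prescribed' - dendrite voltage follows an injected waveform;
                       ``u_d_slope`` supplies its analytic derivative.
    """
    el = params.electrical
    b_u = float(mg_block(u, params))

    # spine currents, amperes
    a_cm2 = params.geometry.a_spine * 1.0e-8
    c_spine = el.c_m * 1.0e-6 * a_cm2                    # F
    i_leak = el.g_leak * a_cm2 * (u - el.u_rest) * 1.0e-3
    i_ampa = el.g_ampa * ampa_wave * 1.0e-9 * (u - el.e_ampa) * 1.0e-3
    i_nmda = el.g_nmda * nmda_wave * b_u * 1.0e-9 * (u - el.e_nmda) * 1.0e-3
    if vgcc_enabled:
        i_vgcc = lvgcc_current(u, m_u, h_u, ca, params)
    else:
        i_vgcc = 0.0
    if math.isinf(el.r_c):
        i_coup = 0.0
    else:
        i_coup = (u - u_d) * 1.0e-3 / (el.r_c * 1.0e6)
    du = -(i_leak + i_ampa + i_nmda + i_vgcc + i_coup) / c_spine * 1.0e3

    # dendrite
    if dendrite_mode == "prescribed":
        dud = u_d_slope
    elif dendrite_mode == "co_input":
        b_d = float(mg_block(u_d, params))
        g_syn = el.rho_s * 1.0e-9 * (el.g_ampa * ampa_wave
                                     + el.g_nmda * nmda_wave * b_d)  # S/cm^2
        dud = (-el.g_leak * (u_d - el.u_rest) - g_syn * (u_d - 0.0)) / (el.c_m * 1.0e-6)
    else:  # passive
        dud = -el.g_leak * (u_d - el.u_rest) / (el.c_m * 1.0e-6)
    return du, dud
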