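"""IP3 receptor gating, Ca2+ release flux (ICCR), SERCA uptake and ER leak.

The IP3R open fraction follows a reduced Li-Rinzel-type scheme: fast
activation by IP3 (m1) and Ca2+ (m2) and slow Ca2+-dependent
inactivation through the gating variable h.  The release flux scales
with the channel cluster size N_R and the (fixed) luminal-cytosolic
concentration difference.  SERCA uptake has a Hill-type Ca2+ dependence
with a compensating linear leak that balances it at rest.
"""

from __future__ import annotations

import numpy as np

from .parameters import ParameterSet


def ip3r_open_fraction(ip3, ca, h, params: ParameterSet):
    """Open fraction of the IP3R channel in [0, 1].

    The default ('grouped') form cubes the product of the three gates,
    (m1 m2 h)^3, as in the source gating model; 'h_only' preserves the
    typeset variant m1 m2 h^3.
    """
    er = params.er
    m1 = ip3 / (er.d1 + ip3)
    m2 = ca / (er.d5 + ca)
    if er.open_fraction_exponent == "grouped":
        g = m1 * m2 * h
        return g * g * g
    return m1 * m2 * h ** 3


def h_inf(ca, params: ParameterSet):
    """Steady-state inactivation, K_inh / (K_inh + Ca)."""
    return params.er.k_inh / (params.er.k_inh + ca)


def h_derivative(h, ca, params: ParameterSet):
    """dh/dt = a2 (K_inh - (K_inh + Ca) h); preserves h in [0, 1] for Ca >= 0."""
    er = params.er
    return er.a2 * (er.k_inh - (er.k_inh + ca) * h)


def iccr_flux(open_fraction, ca, params: ParameterSet):
    """Ca2+ release rate (uM/s) through the open IP3R cluster.

    alpha * open * ([Ca]_ER - [Ca]) is the single-channel ion flux
    (ions/s); multiplied by N_R and converted to a cytosolic
    concentration rate through N_a * V_spine.
    """
    er = params.er
    ions_per_s = er.alpha * open_fraction * (er.ca_er - ca) * er.n_r
    liters = params.geometry.v_spine * 1.0e-15
    return ions_per_s / (params.physical.n_avogadro * liters) * 1.0e6


def open_channel_current(params: ParameterSet, delta_ca: float) -> float:
    """Fully-open single-channel Ca2+ current (A) at a given uM difference."""
    return params.er.alpha * delta_ca * params.physical.q_ca


def serca_flux(ca, params: ParameterSet, k_s=None):
    """(uptake, leak) in uM/s: Hill-type SERCA pumping and the linear ER leak."""
    er = params.er
    uptake = er.serca_vmax * ca * ca / (ca * ca + er.serca_k ** 2)
    if k_s is None:
        k_s = er.k_serca_leak
    leak = k_s * (er.ca_er - ca)
    return uptake, leak


def er_net_flux(ip3, ca, h, params: ParameterSet, k_s=None):
    """Net ER contribution J_ER = J_ICCR - uptake + leak (uM/s).

    Callers model the ER-lacking spine by omitting this term entirely
    (J_ER = 0), not by zeroing parameters.
    """
    j_iccr = iccr_flux(ip3r_open_fraction(ip3, ca, h, params), ca, params)
    uptake, leak = serca_flux(ca, params, k_s)
    return j_iccr - uptake + leak


def trimmed_serca_leak(params: ParameterSet, ip3_rest=None) -> float:
    """Effective ER leak rate making the *full* ER term vanish at rest.

    The tabulated k_S balances SERCA uptake alone; the small basal IP3R
    flux present at resting IP3 would still perturb the rest state.  The
    rest-state solver therefore trims the effective leak so that
    J_ICCR - uptake + leak = 0 exactly at (Ca_rest, IP3_rest).
    """
    conc = params.concentrations
    ca0 = conc.ca_rest
    ip3 = conc.ip3_rest if ip3_rest is None else ip3_rest
    h0 = h_inf(ca0, params)
    j_iccr = iccr_flux(ip3r_open_fraction(ip3, ca0, h0, params), ca0, params)
    uptake, _ = serca_flux(ca0, params, k_s=0.0)
    return (uptake - j_iccr) / (params.er.ca_er - ca0)
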