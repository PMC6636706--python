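"""Free-Ca2+ mass balance: influx conversion, buffering and extrusion.

The cytosolic balance is dCa/dt = J_N + J_VGCC + J_ER + J_B - J_out,
with J_B the net buffer release (negative while buffers load) and J_out
the net plasma-membrane extrusion.  Buffers comprise the 9-state
calbindin scheme, first-order immobile (CBP) and slow buffers, and
calmodulin evolved as two independent cooperative 2-site lobes over the
same molecule population.  PMCA and NCX are explicit two-state pump
cycles with constant inward leaks proportional to the unbound pump
state, exactly balancing extrusion at resting Ca2+.

Buffer state layout (19 entries)::

    0-8   calbindin CB(M_i, H_j), index i + 3*j
    9,10  CBP bound, free
    11,12 slow buffer bound, free
    13-15 CaM C-lobe occupancies C0, C1, C2
    16-18 CaM N-lobe occupancies N0, N1, N2

Pump state layout (4 entries): PMCA free, PMCA:Ca, NCX free, NCX:Ca.
"""

from __future__ import annotations

import numpy as np

from .electrical import ghk_driving, mg_block
from .parameters import ParameterSet

N_BUFFER_STATES = 19
N_PUMP_STATES = 4


def nmdar_ca_flux(u, ca, gating, params: ParameterSet, g_nmda_ca=None):
    """Ca2+ influx (uM/s) through the NMDAR cluster (GHK form, Mg2+ blocked).

    ``gating`` is the dimensionless glutamate waveform from the
    electrical module; the Ca2+ component is 10% of the total NMDAR
    conductance expressed as a GHK permeability.
    """
    if g_nmda_ca is None:
        g_nmda_ca = params.electrical.g_nmda_ca
    drive = ghk_driving(u, ca, params.concentrations.ca_ext,
                        params.electrical.ghk_slope)
    return gating * mg_block(u, params) * g_nmda_ca * drive / params.geometry.v_spine


def buffer_derivatives(ca: float, b, params: ParameterSet):
    """Mass-action derivatives of all buffer species and the net Ca2+ flux.

    Returns ``(db, J_B)`` where J_B (uM/s) is the net rate at which the
    buffers *release* free Ca2+ (negative while binding), so free and
    bound calcium changes are equal and opposite.
    """
    k = params.buffering
    db = np.empty(N_BUFFER_STATES)
    bind = 0.0  # net Ca binding rate, uM/s

    # --- calbindin: 9 states, transitions change one site index at a time
    kon_m = (k.k_m0m1 * ca, k.k_m1m2 * ca)
    koff_m = (k.k_m1m0, k.k_m2m1)
    kon_h = (k.k_h0h1 * ca, k.k_h1h2 * ca)
    koff_h = (k.k_h1h0, k.k_h2h1)
    dcb = [0.0] * 9
    for j in range(3):
        for i in range(3):
            s = i + 3 * j
            occ = b[s]
            if i < 2:       # M-site binding i -> i+1
                f = kon_m[i] * occ
                dcb[s] -= f
                dcb[s + 1] += f
                bind += f
            if i > 0:       # M-site unbinding i -> i-1
                f = koff_m[i - 1] * occ
                dcb[s] -= f
                dcb[s - 1] += f
                bind -= f
            if j < 2:       # H-site binding j -> j+1
                f = kon_h[j] * occ
                dcb[s] -= f
                dcb[s + 3] += f
                bind += f
            if j > 0:       # H-site unbinding j -> j-1
                f = koff_h[j - 1] * occ
                dcb[s] -= f
                dcb[s - 3] += f
                bind -= f
    db[0:9] = dcb

    # --- CBP and slow buffer: first-order reversible
    f_cbp = k.cbp_kf * ca * b[10] - k.cbp_kb * b[9]
    db[9] = f_cbp
    db[10] = -f_cbp
    bind += f_cbp
    f_slow = k.slow_kf * ca * b[12] - k.slow_kb * b[11]
    db[11] = f_slow
    db[12] = -f_slow
    bind += f_slow

    # --- calmodulin lobes (independent 3-state chains)
    c0, c1, c2 = b[13], b[14], b[15]
    f01 = k.k_c0c1 * ca * c0 - k.k_c1c0 * c1
    f12 = k.k_c1c2 * ca * c1 - k.k_c2c1 * c2
    db[13] = -f01
    db[14] = f01 - f12
    db[15] = f12
    bind += f01 + f12
    n0, n1, n2 = b[16], b[17], b[18]
    g01 = k.k_n0n1 * ca * n0 - k.k_n1n0 * n1
    g12 = k.k_n1n2 * ca * n1 - k.k_n2n1 * n2
    db[16] = -g01
    db[17] = g01 - g12
    db[18] = g12
    bind += g01 + g12

    return db, -bind


def pump_flux(ca: float, p, params: ParameterSet):
    """Two-state PMCA/NCX cycle derivatives and net extrusion rate J_out (uM/s).

    Cycle: P + Ca -(kf)-> PCa; PCa -(kb)-> P + Ca; PCa -(k3)-> P with the
    Ca2+ ion exported.  A constant inward leak kL per unbound pump
    molecule balances the cycle at resting Ca2+.
    """
    e = params.extrusion
    dp = np.empty(N_PUMP_STATES)
    j_out = 0.0
    for base, kf, kb, k3, kl in ((0, e.pmca_kf, e.pmca_kb, e.pmca_k3, e.pmca_kl),
                                 (2, e.ncx_kf, e.ncx_kb, e.ncx_k3, e.ncx_kl)):
        free, bound = p[base], p[base + 1]
        f_bind = kf * ca * free - kb * bound
        f_export = k3 * bound
        dp[base] = -f_bind + f_export
        dp[base + 1] = f_bind - f_export
        j_out += f_bind - kl * free
    return dp, j_out


def calcium_derivative(j_nmda, j_vgcc, j_er, j_buffer, j_out, j_cascade=0.0):
    """Algebraic Ca2+ balance (uM/s); ``j_er`` must be 0 for the ER- spine.

    ``j_cascade`` is the (small) net Ca2+ binding rate of the signalling
    cascade species (PLC, IP3-kinase), subtracted to keep total calcium
    exactly conserved.
    """
    return j_nmda + j_vgcc + j_er + j_buffer - j_out - j_cascade


# ---------------------------------------------------------------------------
# Equilibrium constructors (used by the rest-state solver)
# ---------------------------------------------------------------------------

def equilibrium_buffers(ca: float, params: ParameterSet) -> np.ndarray:
    """Closed-form buffer equilibrium at clamped free Ca2+."""
    k = params.buffering
    b = np.empty(N_BUFFER_STATES)
    # calbindin: product of independent site-chain weights
    wm = np.array([1.0,
                   k.k_m0m1 * ca / k.k_m1m0,
                   (k.k_m0m1 * ca / k.k_m1m0) * (k.k_m1m2 * ca / k.k_m2m1)])
    wh = np.array([1.0,
                   k.k_h0h1 * ca / k.k_h1h0,
                   (k.k_h0h1 * ca / k.k_h1h0) * (k.k_h1h2 * ca / k.k_h2h1)])
    w = np.outer(wh, wm).ravel()          # index i + 3*j
    b[0:9] = k.cb_total * w / w.sum()
    occ = ca / (ca + k.cbp_kb / k.cbp_kf)
    b[9], b[10] = k.cbp_total * occ, k.cbp_total * (1.0 - occ)
    occ = ca / (ca + k.slow_kb / k.slow_kf)
    b[11], b[12] = k.slow_total * occ, k.slow_total * (1.0 - occ)
    wc = np.array([1.0, k.k_c0c1 * ca / k.k_c1c0,
                   (k.k_c0c1 * ca / k.k_c1c0) * (k.k_c1c2 * ca / k.k_c2c1)])
    b[13:16] = k.cam_total * wc / wc.sum()
    wn = np.array([1.0, k.k_n0n1 * ca / k.k_n1n0,
                   (k.k_n0n1 * ca / k.k_n1n0) * (k.k_n1n2 * ca / k.k_n2n1)])
    b[16:19] = k.cam_total * wn / wn.sum()
    return b


def equilibrium_pumps(ca: float, params: ParameterSet) -> np.ndarray:
    """Stationary pump-cycle occupancies at clamped free Ca2+."""
    e = params.extrusion
    p = np.empty(N_PUMP_STATES)
    for base, kf, kb, k3, total in ((0, e.pmca_kf, e.pmca_kb, e.pmca_k3, e.pmca_total),
                                    (2, e.ncx_kf, e.ncx_kb, e.ncx_k3, e.ncx_total)):
        frac = kf * ca / (kf * ca + kb + k3)
        p[base] = total * (1.0 - frac)
        p[base + 1] = total * frac
    return p


def buffer_totals(b, params: ParameterSet) -> dict:
    """Conserved totals of each buffer population."""
    return {
        "CB": float(np.sum(b[0:9])),
        "CBP": float(b[9] + b[10]),
        "slow": float(b[11] + b[12]),
        "CaM_C": float(np.sum(b[13:16])),
        "CaM_N": float(np.sum(b[16:19])),
    }
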