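"""mGluR -> Gq -> PLCbeta -> IP3/DAG signalling and IP3 degradation.

Glutamate binds group-I mGluR, catalysing Gq activation; free Gq-alpha
(GTP) binds PLCbeta, which - once both Ca2+ and G-alpha are bound -
hydrolyses PIP2 into IP3 and DAG.  PLC acts as a GTPase activator for
its bound G-alpha.  IP3 is degraded by a Ca2+-activated 3-kinase (IP3K,
binding two Ca2+ ions in a single kinetic step, as the uM^-2 s^-1 rate
unit dictates) and by a 5-phosphatase (IP5P).  A constitutive IP3 source
(see :func:`basal_ip3_balance`) maintains the resting IP3 level against
this degradation.

The network is declared in :func:`reaction_table`, which is the single
auditable description of the topology; the hand-coded fast derivative
path is tested for exact agreement with the table-driven evaluator.
PIP2 (millimolar pool) is treated as buffered/constant.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import root

from .parameters import ParameterSet

#: Species names, in state-vector order.
SPECIES = (
    "R",            # 0  free mGluR
    "RL",           # 1  glutamate-bound mGluR
    "RG",           # 2  mGluR:Gq precoupled
    "RLG",          # 3  glutamate:mGluR:Gq (active GEF)
    "Gq",           # 4  heterotrimeric Gq-GDP
    "Ga",           # 5  free G-alpha-GTP
    "GaGDP",        # 6  free G-alpha-GDP
    "Gbg",          # 7  free G-beta-gamma
    "PLC",          # 8  PLC(beta)
    "PLC_Ca",       # 9  Ca:PLC
    "PLC_G",        # 10 Ga:PLC
    "PLC_Ca_G",     # 11 Ca:Ga:PLC
    "PLC_Ca_P",     # 12 Ca:PLC:PIP2 (substrate loaded)
    "PLC_Ca_G_P",   # 13 Ca:Ga:PLC:PIP2 (active complex)
    "IP3",          # 14
    "DAG",          # 15
    "K",            # 16 IP3 3-kinase
    "K_Ca2",        # 17 Ca2-activated IP3K
    "K_Ca2_IP3",    # 18 IP3K substrate complex
    "P5",           # 19 IP3 5-phosphatase
    "P5_IP3",       # 20 IP5P substrate complex
)
N_SPECIES = len(SPECIES)
IDX = {name: i for i, name in enumerate(SPECIES)}
I_IP3 = IDX["IP3"]


@dataclass(frozen=True)
class Reaction:
    """One elementary step; 'Ca', 'PIP2' and 'glu' are external reactants."""

    rate_symbol: str
    reactants: tuple
    products: tuple
    kf: float
    kb: float = 0.0   # 0 for irreversible steps


def reaction_table(params: ParameterSet) -> list:
    """The declarative reaction network with rate values filled in."""
    c = params.cascade
    return [
        Reaction("a1", ("glu", "R"), ("RL",), c.a1f, c.a1b),
        Reaction("a2", ("glu", "RG"), ("RLG",), c.a2f, c.a2b),
        Reaction("a3", ("RL", "Gq"), ("RLG",), c.a3f, c.a3b),
        Reaction("a4", ("R", "Gq"), ("RG",), c.a4f, c.a4b),
        Reaction("a5", ("RLG",), ("RL", "Ga", "Gbg"), c.a5),
        Reaction("a6", ("Gq",), ("Ga", "Gbg"), c.a6),
        Reaction("a7", ("Ga",), ("GaGDP",), c.a7),
        Reaction("a8", ("GaGDP", "Gbg"), ("Gq",), c.a8),
        Reaction("b1", ("PLC", "Ca"), ("PLC_Ca",), c.b1f, c.b1b),
        Reaction("b2", ("PLC_Ca", "Ga"), ("PLC_Ca_G",), c.b2f, c.b2b),
        Reaction("b3", ("PLC", "Ga"), ("PLC_G",), c.b3f, c.b3b),
        Reaction("b4", ("PLC_G", "Ca"), ("PLC_Ca_G",), c.b4f, c.b4b),
        Reaction("b5", ("PLC_Ca_P", "Ga"), ("PLC_Ca_G_P",), c.b5f, c.b5b),
        Reaction("b6", ("PLC_G",), ("PLC", "GaGDP"), c.b6),
        Reaction("b7", ("PLC_Ca_G_P",), ("PLC_Ca_G", "IP3", "DAG"), c.b7),
        Reaction("b8", ("PLC_Ca", "PIP2"), ("PLC_Ca_P",), c.b8f, c.b8b),
        Reaction("b9", ("PLC_Ca_G", "PIP2"), ("PLC_Ca_G_P",), c.b9f, c.b9b),
        Reaction("b10", ("PLC_Ca_G",), ("PLC_Ca", "GaGDP"), c.b10),
        Reaction("b11", ("PLC_Ca_G_P",), ("PLC_Ca_P", "GaGDP"), c.b11),
        Reaction("b12", ("DAG",), (), c.b12),
        Reaction("c1", ("K", "Ca", "Ca"), ("K_Ca2",), c.c1f, c.c1b),
        Reaction("c2", ("K_Ca2", "IP3"), ("K_Ca2_IP3",), c.c2f, c.c2b),
        Reaction("c3", ("K_Ca2_IP3",), ("K_Ca2",), c.c3),
        Reaction("c4", ("P5", "IP3"), ("P5_IP3",), c.c4f, c.c4b),
        Reaction("c5", ("P5_IP3",), ("P5",), c.c5),
    ]


def format_reaction_table(params: ParameterSet) -> str:
    """Human-readable reaction listing for audit."""
    lines = []
    for r in reaction_table(params):
        arrow = "<->" if r.kb else "->"
        lines.append(f"{r.rate_symbol:>4}:  {' + '.join(r.reactants) or '0'} "
                     f"{arrow} {' + '.join(r.products) or '0'}   "
                     f"kf={r.kf:g}" + (f" kb={r.kb:g}" if r.kb else ""))
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# Glutamate drive
# ---------------------------------------------------------------------------

def glutamate_pulse(t, params: ParameterSet, pulse_times=(0.0,)):
    """Cleft glutamate (uM) at the mGluR: alpha functions normalized to G_max.

    Each pulse contributes G_max (dt/tau) e^{1 - dt/tau}, peaking at
    G_max one time constant after onset; pulses in a train sum.
    """
    c = params.cascade
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    for t0 in np.atleast_1d(pulse_times):
        dt = t - t0
        mask = dt >= 0.0
        if np.any(mask):
            d = dt[mask] if t.ndim else dt
            val = c.g_max * (d / c.tau_glu) * np.exp(1.0 - d / c.tau_glu)
            if t.ndim:
                out[mask] += val
            elif mask:
                out += val
    return out if t.ndim else float(out)


# ---------------------------------------------------------------------------
# Derivatives
# ---------------------------------------------------------------------------

def cascade_derivatives(y, glu: float, ca: float, params: ParameterSet,
                        ip3_source: float = 0.0):
    """Mass-action derivatives of the cascade and its net Ca2+ uptake.

    Returns ``(dy, j_ca_bound)`` where ``j_ca_bound`` (uM/s) is the net
    rate at which cascade species sequester free Ca2+ (PLC Ca-binding
    and the two-Ca2+ activation of IP3K).
    """
    c = params.cascade
    (r, rl, rg, rlg, gq, ga, gagdp, gbg, plc, plc_ca, plc_g, plc_ca_g,
     plc_ca_p, plc_ca_g_p, ip3, dag, kin, kin_ca2, kin_ca2_ip3, p5,
     p5_ip3) = y

    pip2 = c.pip2_total
    ca2 = ca * ca

    v_a1 = c.a1f * glu * r - c.a1b * rl
    v_a2 = c.a2f * glu * rg - c.a2b * rlg
    v_a3 = c.a3f * rl * gq - c.a3b * rlg
    v_a4 = c.a4f * r * gq - c.a4b * rg
    v_a5 = c.a5 * rlg
    v_a6 = c.a6 * gq
    v_a7 = c.a7 * ga
    v_a8 = c.a8 * gagdp * gbg
    v_b1 = c.b1f * plc * ca - c.b1b * plc_ca
    v_b2 = c.b2f * plc_ca * ga - c.b2b * plc_ca_g
    v_b3 = c.b3f * plc * ga - c.b3b * plc_g
    v_b4 = c.b4f * plc_g * ca - c.b4b * plc_ca_g
    v_b5 = c.b5f * plc_ca_p * ga - c.b5b * plc_ca_g_p
    v_b6 = c.b6 * plc_g
    v_b7 = c.b7 * plc_ca_g_p
    v_b8 = c.b8f * plc_ca * pip2 - c.b8b * plc_ca_p
    v_b9 = c.b9f * plc_ca_g * pip2 - c.b9b * plc_ca_g_p
    v_b10 = c.b10 * plc_ca_g
    v_b11 = c.b11 * plc_ca_g_p
    v_b12 = c.b12 * dag
    v_c1 = c.c1f * kin * ca2 - c.c1b * kin_ca2
    v_c2 = c.c2f * kin_ca2 * ip3 - c.c2b * kin_ca2_ip3
    v_c3 = c.c3 * kin_ca2_ip3
    v_c4 = c.c4f * p5 * ip3 - c.c4b * p5_ip3
    v_c5 = c.c5 * p5_ip3

    dy = np.empty(N_SPECIES)
    dy[0] = -v_a1 - v_a4                                    # R
    dy[1] = v_a1 - v_a3 + v_a5                              # RL
    dy[2] = v_a4 - v_a2                                     # RG
    dy[3] = v_a2 + v_a3 - v_a5                              # RLG
    dy[4] = -v_a3 - v_a4 - v_a6 + v_a8                      # Gq
    dy[5] = v_a5 + v_a6 - v_a7 - v_b2 - v_b3 - v_b5         # Ga
    dy[6] = v_a7 - v_a8 + v_b6 + v_b10 + v_b11              # GaGDP
    dy[7] = v_a5 + v_a6 - v_a8                              # Gbg
    dy[8] = -v_b1 - v_b3 + v_b6                             # PLC
    dy[9] = v_b1 - v_b2 - v_b8 + v_b10                      # PLC_Ca
    dy[10] = v_b3 - v_b4 - v_b6                             # PLC_G
    dy[11] = v_b2 + v_b4 + v_b7 - v_b9 - v_b10              # PLC_Ca_G
    dy[12] = v_b8 - v_b5 + v_b11                            # PLC_Ca_P
    dy[13] = v_b5 + v_b9 - v_b7 - v_b11                     # PLC_Ca_G_P
    dy[14] = v_b7 - v_c2 - v_c4 + ip3_source                # IP3
    dy[15] = v_b7 - v_b12                                   # DAG
    dy[16] = -v_c1                                          # K
    dy[17] = v_c1 + v_c3 - v_c2                             # K_Ca2
    dy[18] = v_c2 - v_c3                                    # K_Ca2_IP3
    dy[19] = -v_c4 + v_c5                                   # P5
    dy[20] = v_c4 - v_c5                                    # P5_IP3

    j_ca_bound = v_b1 + v_b4 + 2.0 * v_c1
    return dy, j_ca_bound


def table_derivatives(y, glu: float, ca: float, params: ParameterSet,
                      ip3_source: float = 0.0):
    """Slow table-driven evaluator (reference for the hand-coded path)."""
    c = params.cascade
    external = {"glu": glu, "Ca": ca, "PIP2": c.pip2_total}
    dy = np.zeros(N_SPECIES)
    j_ca = 0.0
    for r in reaction_table(params):
        fwd = r.kf
        for sp in r.reactants:
            fwd *= external[sp] if sp in external else y[IDX[sp]]
        bwd = 0.0
        if r.kb:
            bwd = r.kb
            for sp in r.products:
                bwd *= external[sp] if sp in external else y[IDX[sp]]
        v = fwd - bwd
        for sp in r.reactants:
            if sp == "Ca":
                j_ca += v
            elif sp not in external:
                dy[IDX[sp]] -= v
        for sp in r.products:
            if sp == "Ca":
                j_ca -= v
            elif sp not in external:
                dy[IDX[sp]] += v
    dy[I_IP3] += ip3_source
    return dy, j_ca


def conserved_totals(y, params: ParameterSet) -> dict:
    """The five conserved species totals implied by the topology."""
    g = {n: y[IDX[n]] for n in SPECIES}
    return {
        "mGluR": g["R"] + g["RL"] + g["RG"] + g["RLG"],
        "Ga": (g["Gq"] + g["RG"] + g["RLG"] + g["Ga"] + g["GaGDP"]
               + g["PLC_G"] + g["PLC_Ca_G"] + g["PLC_Ca_G_P"]),
        "Gbg": g["Gbg"] + g["Gq"] + g["RG"] + g["RLG"],
        "PLC": (g["PLC"] + g["PLC_Ca"] + g["PLC_G"] + g["PLC_Ca_G"]
                + g["PLC_Ca_P"] + g["PLC_Ca_G_P"]),
        "IP3K": g["K"] + g["K_Ca2"] + g["K_Ca2_IP3"],
        "IP5P": g["P5"] + g["P5_IP3"],
    }


# ---------------------------------------------------------------------------
# Stationary states and the basal IP3 balance
# ---------------------------------------------------------------------------

#: Independent unknowns once conservation laws eliminate R, Gq, Gbg, PLC, K, P5.
_FREE = ("RL", "RG", "RLG", "Ga", "GaGDP", "PLC_Ca", "PLC_G", "PLC_Ca_G",
         "PLC_Ca_P", "PLC_Ca_G_P", "K_Ca2", "K_Ca2_IP3", "P5_IP3")
_FREE_IDX = [IDX[n] for n in _FREE]


def _expand(x, ip3: float, params: ParameterSet) -> np.ndarray:
    """Build a full species vector from free unknowns + conservation laws."""
    c = params.cascade
    y = np.zeros(N_SPECIES)
    for v, i in zip(x, _FREE_IDX):
        y[i] = v
    y[I_IP3] = ip3
    rl, rg, rlg = y[IDX["RL"]], y[IDX["RG"]], y[IDX["RLG"]]
    y[IDX["R"]] = c.mglur_total - rl - rg - rlg
    galpha_bound = (rg + rlg + y[IDX["Ga"]] + y[IDX["GaGDP"]]
                    + y[IDX["PLC_G"]] + y[IDX["PLC_Ca_G"]] + y[IDX["PLC_Ca_G_P"]])
    y[IDX["Gq"]] = c.gq_total - galpha_bound
    y[IDX["Gbg"]] = c.gq_total - (y[IDX["Gq"]] + rg + rlg)
    y[IDX["PLC"]] = c.plc_total - (y[IDX["PLC_Ca"]] + y[IDX["PLC_G"]]
                                   + y[IDX["PLC_Ca_G"]] + y[IDX["PLC_Ca_P"]]
                                   + y[IDX["PLC_Ca_G_P"]])
    y[IDX["K"]] = c.ip3k_total - y[IDX["K_Ca2"]] - y[IDX["K_Ca2_IP3"]]
    y[IDX["P5"]] = c.ip5p_total - y[IDX["P5_IP3"]]
    return y


def stationary_state(params: ParameterSet, glu: float, ca: float,
                     ip3_source: Optional[float] = None,
                     ip3_clamp: Optional[float] = None,
                     guess: Optional[np.ndarray] = None) -> np.ndarray:
    """Stationary cascade state under clamped glutamate and Ca2+.

    If ``ip3_clamp`` is given, IP3 is held fixed and no source is needed
    (used to derive the constitutive source).  Otherwise ``ip3_source``
    must be supplied and IP3 is solved alongside the other species.

    Raises RuntimeError if the nonlinear solve does not converge to a
    physical (non-negative) state.
    """
    clamped = ip3_clamp is not None
    if not clamped and ip3_source is None:
        raise ValueError("either ip3_clamp or ip3_source is required")

    if guess is None:
        guess = _relaxed_state(params, glu, ca, ip3_source, ip3_clamp)

    x0 = list(guess[_FREE_IDX])
    if not clamped:
        x0.append(guess[I_IP3])
    x0 = np.asarray(x0)

    def residual(x):
        ip3 = ip3_clamp if clamped else x[-1]
        y = _expand(x[:len(_FREE)], ip3, params)
        dy, _ = cascade_derivatives(y, glu, ca, params,
                                    0.0 if clamped else ip3_source)
        res = dy[_FREE_IDX]
        if not clamped:
            res = np.append(res, dy[I_IP3])
        return res

    sol = root(residual, x0, method="hybr", tol=1e-13)
    ip3 = ip3_clamp if clamped else sol.x[-1]
    y = _expand(sol.x[:len(_FREE)], ip3, params)
    dag_src = params.cascade.b7 * y[IDX["PLC_Ca_G_P"]]
    y[IDX["DAG"]] = dag_src / params.cascade.b12 if params.cascade.b12 > 0 else 0.0
    res = np.max(np.abs(residual(sol.x)))
    if res > 1e-9 or y.min() < -1e-9:
        raise RuntimeError(f"cascade stationarity solve failed: {sol.message}; "
                           f"residual {res:.3g}, min species {y.min():.3g}")
    return np.clip(y, 0.0, None)


def _relaxed_state(params: ParameterSet, glu: float, ca: float,
                   ip3_source, ip3_clamp) -> np.ndarray:
    """Initial stationarity guess by long relaxation of the clamped ODE."""
    c = params.cascade
    y0 = np.zeros(N_SPECIES)
    y0[IDX["R"]] = c.mglur_total
    y0[IDX["Gq"]] = c.gq_total
    y0[IDX["PLC"]] = c.plc_total
    y0[IDX["K"]] = c.ip3k_total
    y0[IDX["P5"]] = c.ip5p_total
    y0[I_IP3] = ip3_clamp if ip3_clamp is not None else params.concentrations.ip3_rest

    def rhs(_t, y):
        dy, _ = cascade_derivatives(y, glu, ca, params,
                                    ip3_source if ip3_source is not None else 0.0)
        if ip3_clamp is not None:
            dy[I_IP3] = 0.0
        return dy

    sol = solve_ivp(rhs, (0.0, 5.0e4), y0, method="LSODA",
                    rtol=1e-10, atol=1e-12)
    if not sol.success:
        raise RuntimeError(f"cascade relaxation failed: {sol.message}")
    return sol.y[:, -1]


def basal_ip3_balance(params: ParameterSet) -> float:
    """Constitutive IP3 production rate (uM/s) pinning resting IP3.

    With glutamate absent and Ca2+ at rest, the stationary cascade is
    solved with IP3 clamped at its resting value; the source is the net
    degradation rate there.  A non-positive result means the network
    overproduces IP3 at rest and is reported as a configuration error.
    """
    conc = params.concentrations
    y = stationary_state(params, glu=0.0, ca=conc.ca_rest,
                         ip3_clamp=conc.ip3_rest)
    dy, _ = cascade_derivatives(y, 0.0, conc.ca_rest, params, 0.0)
    source = -float(dy[I_IP3])
    if source <= 0.0:
        raise RuntimeError(
            f"no positive constitutive IP3 source exists (net basal "
            f"production {-source:.3g} uM/s already exceeds degradation)")
    return source


def basal_state(params: ParameterSet, ip3_source: Optional[float] = None) -> np.ndarray:
    """Basal (no glutamate) stationary cascade with resting IP3."""
    if ip3_source is None:
        ip3_source = basal_ip3_balance(params)
    conc = params.concentrations
    y = stationary_state(params, glu=0.0, ca=conc.ca_rest,
                         ip3_clamp=conc.ip3_rest)
    return y


def ip3_timecourse_latency(params: ParameterSet, protocol=None,
                           ca: Optional[float] = None):
    """Delay (ms) from glutamate onset to the IP3 peak, or None if no event.

    The cascade is integrated in isolation with Ca2+ clamped (at rest by
    default) while a single glutamate pulse (or the first pulse of the
    supplied protocol) drives the receptor.  "No event" (None) is
    returned when IP3 never exceeds baseline by more than 1%.
    """
    ca = params.concentrations.ca_rest if ca is None else ca
    if protocol is not None:
        pulses = np.asarray(protocol.glu_times, dtype=float)
    else:
        pulses = np.array([0.0])
    if pulses.size == 0:
        return None
    onset = float(pulses[0])
    source = basal_ip3_balance(params)
    y0 = basal_state(params, source)

    def rhs(t, y):
        glu = glutamate_pulse(t, params, pulses)
        dy, _ = cascade_derivatives(y, glu, ca, params, source)
        return dy

    t_end = onset + 5.0
    sol = solve_ivp(rhs, (0.0, t_end), y0, method="LSODA",
                    rtol=1e-8, atol=1e-11, dense_output=True)
    ts = np.linspace(onset, t_end, 2500)
    ip3 = sol.sol(ts)[I_IP3]
    baseline = y0[I_IP3]
    if ip3.max() < baseline * 1.01:
        return None
    return float((ts[np.argmax(ip3)] - onset) * 1e3)
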