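"""Calcium/calmodulin-driven bidirectional synaptic weight dynamics.

The plasticity readout is active calmodulin (aCaM): the concentration
of CaM molecules carrying at least one bound Ca2+, computed under lobe
independence.  The weight w relaxes toward an aCaM-dependent target,

    tau_w(aCaM) dw/dt = -w + Omega_w(aCaM),

where Omega_w is a difference of two steep sigmoids producing a
depression plateau (-0.5) between the LTD threshold theta_D and the LTP
threshold theta_P, and potentiation (+0.5 asymptote) above theta_P.
tau_w decreases from hours at rest to seconds at strong CaM activation,
reproducing the experimental induction/persistence time scales.
"""

from __future__ import annotations

from typing import Callable, Optional, Sequence, Tuple

import numpy as np

from .parameters import CalibrationError, ParameterSet


def active_cam(cam_states, params: ParameterSet):
    """Active calmodulin (uM): molecules with >= 1 bound Ca2+.

    Under lobe independence, aCaM = CaM_total (1 - p(C0) p(N0)) with
    p(X0) the unbound fraction of each lobe.  ``cam_states`` holds the
    lobe occupancies (C0, C1, C2, N0, N1, N2), each lobe population
    summing to CaM_total.
    """
    total = params.buffering.cam_total
    if total <= 0.0:
        return 0.0 * np.asarray(cam_states[0])
    c0 = np.asarray(cam_states[0], dtype=float)
    n0 = np.asarray(cam_states[3], dtype=float)
    out = total * (1.0 - (c0 / total) * (n0 / total))
    return float(out) if out.ndim == 0 else out


def omega(acam, params: ParameterSet):
    """Steady-state weight target Omega_w(aCaM) in (-0.5, 1)."""
    p = params.plasticity
    a = np.asarray(acam, dtype=float)
    up = 1.0 / (1.0 + np.exp(np.clip(-p.beta_p * (a - p.theta_p), -700, 700)))
    down = 0.5 / (1.0 + np.exp(np.clip(-p.beta_d * (a - p.theta_d), -700, 700)))
    out = up - down
    return float(out) if out.ndim == 0 else out


def tau_w(acam, params: ParameterSet):
    """Weight relaxation time constant (s), monotone decreasing in aCaM."""
    p = params.plasticity
    a = np.asarray(acam, dtype=float)
    scaled = 2.0 * a / (p.theta_d + p.theta_p)
    out = p.tau_w_base + p.tau_w_amp / (p.tau_w_floor
                                        + scaled ** p.tau_w_exponent)
    return float(out) if out.ndim == 0 else out


def weight_derivative(w, acam, params: ParameterSet):
    """dw/dt = (-w + Omega_w(aCaM)) / tau_w(aCaM)."""
    return (-w + omega(acam, params)) / tau_w(acam, params)


def integrate_weight(t: np.ndarray, acam: np.ndarray, params: ParameterSet,
                     w0: float = 0.0) -> np.ndarray:
    """Integrate the weight ODE along a sampled aCaM trace.

    Uses the exact exponential step of the locally-linear ODE on each
    sampling interval (midpoint values of Omega and tau), which is what
    makes scanning plasticity thresholds over precomputed trajectories
    cheap: the biophysical state does not depend on w.
    """
    t = np.asarray(t, float)
    a_mid = 0.5 * (np.asarray(acam[:-1], float) + np.asarray(acam[1:], float))
    om = omega(a_mid, params)
    tw = tau_w(a_mid, params)
    decay = np.exp(-np.diff(t) / tw)
    w = np.empty(len(t))
    w[0] = w0
    wk = w0
    for k in range(len(t) - 1):
        wk = om[k] + (wk - om[k]) * decay[k]
        w[k + 1] = wk
    return w


def final_weight(t, acam, params: ParameterSet, w0: float = 0.0) -> float:
    """Net weight change at the end of a stimulation trace (w starts at 0)."""
    return float(integrate_weight(t, acam, params, w0)[-1])


def calibrate_thresholds(params: ParameterSet, protocol_family: str,
                         targets: Tuple[float, float],
                         acam_peak: Optional[Callable[[float], float]] = None,
                         check_step: Optional[float] = None,
                         **run_kwargs) -> Tuple[float, float]:
    """Set (theta_D, theta_P) from the ER- response at the target stimuli.

    theta_D is the maximal steady-state aCaM attained at the LTD
    boundary stimulus and theta_P that at the LTP boundary, so the
    resulting weight-change curve changes sign at the targets.

    Parameters
    ----------
    protocol_family : {'rate', 'stdp_doublet', 'stdp_triplet'}
    targets : (float, float)
        (f_D, f_P) in Hz for 'rate', (dt_D, dt_P) in ms for STDP.
    acam_peak : callable, optional
        Precomputed map from induction variable to peak steady-state
        aCaM (ER- spine); if omitted it is measured by simulation.
    check_step : float, optional
        Grid step for the local monotonicity check around each target
        (skipped when None).
    """
    lo, hi = targets
    if lo == hi:
        raise CalibrationError("degenerate thresholds: targets coincide")
    if protocol_family == "rate" and not hi > lo:
        raise CalibrationError("rate targets must satisfy f_D < f_P")

    if acam_peak is None:
        from . import analysis
        acam_peak = analysis.acam_peak_function(params, protocol_family,
                                                er=False, **run_kwargs)

    a_lo, a_hi = acam_peak(lo), acam_peak(hi)
    if check_step:
        for target, value in ((lo, a_lo), (hi, a_hi)):
            below, above = acam_peak(target - check_step), acam_peak(target + check_step)
            if not (below <= value <= above or below >= value >= above):
                raise CalibrationError(
                    f"aCaM response is non-monotone around target {target} "
                    f"({below:.3g}, {value:.3g}, {above:.3g})")
    theta_d, theta_p = float(a_lo), float(a_hi)
    if not theta_p > theta_d:
        raise CalibrationError(
            f"calibrated thresholds are not ordered: theta_D={theta_d:.3g}, "
            f"theta_P={theta_p:.3g}")
    return theta_d, theta_p
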