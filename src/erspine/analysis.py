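"""Derived metrics and experiment orchestration.

Pure functions over trajectories and weight-change curves: ICCR latency
and peak-ratio detection, stationary IP3R open-probability maps,
rate/STDP plasticity curves with their ER+/ER- differential metrics,
and seeded sensitivity sampling of the plasticity thresholds.

Because the synaptic weight does not feed back on the biophysics, the
expensive simulations are cached as aCaM traces and the weight equation
is re-integrated offline for each choice of plasticity thresholds; that
is what makes threshold calibration and the sensitivity sweeps cheap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
from scipy.signal import find_peaks

from . import engine, er_store, mglur_cascade, plasticity, protocols
from .parameters import ParameterSet

#: weight-change magnitude below which no plasticity is considered induced
DW_TOLERANCE = 0.01


# ---------------------------------------------------------------------------
# Trajectory metrics
# ---------------------------------------------------------------------------

def _onset(traj: engine.Trajectory) -> float:
    if not traj.protocol.glu_times:
        raise ValueError("trajectory has no glutamate events")
    return float(traj.protocol.glu_times[0])


def ca_peaks(t: np.ndarray, ca: np.ndarray, rest: float,
             onset: float = 0.0, rel_prominence: float = 0.05):
    """Indices of Ca2+ peaks after onset.

    The first local maximum after the stimulus defines the reference
    amplitude; subsequent peaks count only if their prominence is at
    least ``rel_prominence`` of that first peak's height above rest.
    """
    sel = t >= onset
    idx = np.flatnonzero(sel)
    pk, props = find_peaks(ca[sel], prominence=1e-6)
    if len(pk) == 0:
        return []
    first_height = ca[idx[pk[0]]] - rest
    if first_height <= 0:
        return []
    keep = [pk[0]]
    for q, prom in zip(pk[1:], props["prominences"][1:]):
        if prom >= rel_prominence * first_height:
            keep.append(q)
    return [int(idx[q]) for q in keep]


def iccr_delay(traj: engine.Trajectory, rel_prominence: float = 0.05):
    """Delay (ms) from glutamate onset to the second Ca2+ peak, or None.

    The second peak is the ER-release transient; "no event" (None) is
    returned when no second local maximum of sufficient prominence
    exists (e.g. the ER- spine).  Raises if even the first (NMDAR)
    peak is missing.
    """
    onset = _onset(traj)
    rest = traj.params.concentrations.ca_rest
    peaks = ca_peaks(traj.t, traj.ca, rest, onset, rel_prominence)
    if not peaks:
        raise ValueError("trace lacks a first Ca2+ peak")
    if len(peaks) < 2:
        return None
    return float((traj.t[peaks[1]] - onset) * 1e3)


def peak_ratio(traj: engine.Trajectory, rel_prominence: float = 0.05):
    """Second-to-first Ca2+ peak amplitude ratio (heights above rest), or None."""
    onset = _onset(traj)
    rest = traj.params.concentrations.ca_rest
    peaks = ca_peaks(traj.t, traj.ca, rest, onset, rel_prominence)
    if not peaks:
        raise ValueError("trace lacks a first Ca2+ peak")
    if len(peaks) < 2:
        return None
    first = traj.ca[peaks[0]] - rest
    second = traj.ca[peaks[1]] - rest
    return float(second / first)


def delayed_release(traj: engine.Trajectory, min_delay: float = 0.1,
                    min_amplitude: float = 0.01) -> bool:
    """Whether a delayed ER Ca2+ transient occurs (works without NMDAR).

    True when free Ca2+ exhibits a local maximum at least ``min_delay``
    seconds after glutamate onset whose height above rest exceeds
    ``min_amplitude`` (uM).
    """
    onset = _onset(traj)
    rest = traj.params.concentrations.ca_rest
    sel = traj.t >= onset + min_delay
    pk, _ = find_peaks(traj.ca[sel], height=rest + min_amplitude,
                       prominence=min_amplitude)
    return len(pk) > 0


def steady_window_max(traj: engine.Trajectory, channel: str = "acam",
                      window_frac: float = 0.2) -> float:
    """Maximum steady-state amplitude during a train.

    Evaluated over the last ``window_frac`` of the stimulation period
    (first to last glutamate event plus one inter-event interval),
    skipping the initial transient.
    """
    glu = np.asarray(traj.protocol.glu_times)
    if len(glu) == 0:
        raise ValueError("protocol has no stimulation events")
    if len(glu) > 1:
        period_end = glu[-1] + (glu[-1] - glu[0]) / (len(glu) - 1)
    else:
        period_end = traj.t[-1]
    t0 = glu[0] + (1.0 - window_frac) * (period_end - glu[0])
    sel = (traj.t >= t0) & (traj.t <= period_end)
    values = traj.acam if channel == "acam" else getattr(traj, channel)
    return float(values[sel].max())


# ---------------------------------------------------------------------------
# Stationary IP3R open-probability map
# ---------------------------------------------------------------------------

def steady_state_popen_map(ca_grid, glu_grid, params: ParameterSet) -> np.ndarray:
    """P_open of the IP3R at cascade stationarity on a (glu, Ca) grid.

    For each clamped glutamate and Ca2+ level the cascade (with its
    constitutive IP3 source) is solved to stationarity; the open
    probability uses the stationary IP3 and h at its Ca-dependent
    steady state.  Non-convergent cells are flagged as NaN.

    Returns an array of shape (len(glu_grid), len(ca_grid)).
    """
    source = engine.basal_ip3_source(params)
    out = np.full((len(glu_grid), len(ca_grid)), np.nan)
    for i, glu in enumerate(glu_grid):
        guess = None
        for j, ca in enumerate(ca_grid):
            try:
                y = mglur_cascade.stationary_state(
                    params, glu=float(glu), ca=float(ca),
                    ip3_source=source, guess=guess)
                guess = y
            except RuntimeError:
                guess = None
                continue
            ip3 = y[mglur_cascade.I_IP3]
            h = er_store.h_inf(ca, params)
            out[i, j] = er_store.ip3r_open_fraction(ip3, float(ca), h, params)
    return out


def popen_optimal_ca(params: ParameterSet,
                     ca_grid: Optional[np.ndarray] = None,
                     glu_grid: Optional[Sequence[float]] = None) -> float:
    """Clamped Ca2+ (uM) at which the stationary P_open is maximal."""
    if ca_grid is None:
        ca_grid = np.geomspace(0.01, 3.0, 61)
    if glu_grid is None:
        glu_grid = np.geomspace(0.1, 100.0, 5)
    pmap = steady_state_popen_map(ca_grid, glu_grid, params)
    if np.all(np.isnan(pmap)):
        raise RuntimeError("no stationary solution on the grid")
    flat = np.nanargmax(pmap)
    _, j = np.unravel_index(flat, pmap.shape)
    return float(ca_grid[j])


# ---------------------------------------------------------------------------
# Plasticity curves
# ---------------------------------------------------------------------------

@dataclass
class PlasticityCurve:
    """Net weight change versus the induction variable for one model."""

    grid: np.ndarray          # Hz (rate) or ms (STDP)
    dw: np.ndarray
    kind: str                 # 'rate' | 'stdp_doublet' | 'stdp_triplet'
    er: bool
    meta: dict = field(default_factory=dict)


def _protocol_for(family: str, value: float, n_events: int):
    if family == "rate":
        return protocols.rate_train(float(value), n_spikes=n_events)
    if family == "stdp_doublet":
        return protocols.stdp_train(float(value), n_pairings=n_events, n_bap=1)
    if family == "stdp_triplet":
        return protocols.stdp_train(float(value), n_pairings=n_events, n_bap=2)
    raise ValueError(f"unknown protocol family {family!r}")


def acam_traces(params: ParameterSet, family: str, grid, er: bool,
                n_events: int, cache: Optional[dict] = None) -> Dict[float, tuple]:
    """Map induction-variable -> (t, aCaM trace, trajectory) for a grid.

    The trajectories carry everything needed to re-integrate the weight
    equation for arbitrary thresholds.
    """
    out = {}
    for value in grid:
        key = (family, float(value), er, n_events, params.digest(),
               float(params.er.n_r))
        if cache is not None and key in cache:
            out[float(value)] = cache[key]
            continue
        traj = engine.run(_protocol_for(family, value, n_events), params, er=er)
        entry = (traj.t, traj.acam, traj)
        if cache is not None:
            cache[key] = entry
        out[float(value)] = entry
    return out


def acam_peak_function(params: ParameterSet, family: str, er: bool = False,
                       n_events: int = 100, traces: Optional[dict] = None,
                       window_frac: float = 0.2):
    """Callable induction-variable -> peak steady-state aCaM.

    When ``traces`` (a grid of precomputed trajectories) is provided,
    values between grid points are linearly interpolated instead of
    simulated on demand.
    """
    if traces is not None:
        xs = np.array(sorted(traces))
        ys = np.array([steady_window_max(traces[x][2], "acam", window_frac)
                       for x in xs])
        return lambda v: float(np.interp(v, xs, ys))

    def measure(value: float) -> float:
        traj = engine.run(_protocol_for(family, value, n_events), params, er=er)
        return steady_window_max(traj, "acam", window_frac)
    return measure


def curve_from_traces(traces: Dict[float, tuple], params: ParameterSet,
                      thresholds: Tuple[float, float], kind: str,
                      er: bool) -> PlasticityCurve:
    """Weight-change curve for given thresholds from precomputed traces."""
    theta_d, theta_p = thresholds
    local = params.copy(theta_D=theta_d, theta_P=theta_p)
    xs = np.array(sorted(traces))
    dw = np.array([plasticity.final_weight(traces[x][0], traces[x][1], local)
                   for x in xs])
    return PlasticityCurve(grid=xs, dw=dw, kind=kind, er=er,
                           meta={"theta_D": theta_d, "theta_P": theta_p,
                                 "params": params.digest()})


def plasticity_curve(params: ParameterSet, family: str, grid,
                     thresholds: Tuple[float, float], er: bool = False,
                     n_events: int = 900,
                     cache: Optional[dict] = None) -> PlasticityCurve:
    """Net weight change Delta-w over an induction-variable grid."""
    traces = acam_traces(params, family, grid, er, n_events, cache)
    return curve_from_traces(traces, params, thresholds, family, er)


# ---------------------------------------------------------------------------
# Threshold shifts and window widths
# ---------------------------------------------------------------------------

def _interp_crossing(x0, x1, y0, y1, level):
    return x0 + (level - y0) * (x1 - x0) / (y1 - y0)


def rate_thresholds(curve: PlasticityCurve, tol: float = DW_TOLERANCE):
    """(f_D, f_P) of a rate curve: LTD onset and the LTD->LTP zero crossing.

    f_D is where the curve first drops below -tol (plasticity onset);
    f_P is the subsequent upward zero crossing, linearly interpolated
    between grid points.  Either is None when the feature is absent.
    """
    x, y = curve.grid, curve.dw
    f_d = f_p = None
    for k in range(len(x) - 1):
        if f_d is None and y[k] >= -tol > y[k + 1]:
            f_d = _interp_crossing(x[k], x[k + 1], y[k], y[k + 1], -tol)
        if f_d is not None and y[k] < 0.0 <= y[k + 1]:
            f_p = _interp_crossing(x[k], x[k + 1], y[k], y[k + 1], 0.0)
            break
    if f_d is None and len(y) and y[0] < -tol:
        f_d = float(x[0])
    return f_d, f_p


def window_widths(curve: PlasticityCurve, tol: float = DW_TOLERANCE):
    """(LTD width, LTP width) of an STDP curve, in grid units.

    The widths are the measure of the induction-variable set where the
    linearly-interpolated curve lies below -tol (LTD) or above +tol (LTP).
    """
    x, y = curve.grid, curve.dw
    widths = []
    for sign in (-1.0, 1.0):
        z = sign * y - tol          # > 0 inside the window
        length = 0.0
        for k in range(len(x) - 1):
            z0, z1 = z[k], z[k + 1]
            dx = x[k + 1] - x[k]
            if z0 > 0 and z1 > 0:
                length += dx
            elif z0 > 0 >= z1:
                length += dx * z0 / (z0 - z1)
            elif z1 > 0 >= z0:
                length += dx * z1 / (z1 - z0)
        widths.append(float(length))
    return tuple(widths)


def threshold_shifts(curve_minus: PlasticityCurve,
                     curve_plus: PlasticityCurve,
                     tol: float = DW_TOLERANCE):
    """Differential plasticity metrics between ER- and ER+ curves.

    For rate curves: (Delta f_D, Delta f_P), the shifts of the LTD and
    LTP threshold frequencies (ER+ minus ER-); a missing crossing makes
    that component None ("undefined").  For STDP curves: (Delta_D,
    Delta_P), the changes of the LTD/LTP window widths.
    """
    if not np.array_equal(curve_minus.grid, curve_plus.grid):
        raise ValueError("curves must share one grid")
    if curve_minus.kind == "rate":
        fd0, fp0 = rate_thresholds(curve_minus, tol)
        fd1, fp1 = rate_thresholds(curve_plus, tol)
        dfd = None if fd0 is None or fd1 is None else fd1 - fd0
        dfp = None if fp0 is None or fp1 is None else fp1 - fp0
        return dfd, dfp
    w0 = window_widths(curve_minus, tol)
    w1 = window_widths(curve_plus, tol)
    return w1[0] - w0[0], w1[1] - w0[1]


# ---------------------------------------------------------------------------
# Sensitivity sampling
# ---------------------------------------------------------------------------

@dataclass
class SensitivitySample:
    """One random draw of plasticity thresholds and its differential outcome."""

    index: int
    threshold_lo: float       # f_D (Hz) or dt_D (ms) drawn for the ER- spine
    threshold_hi: float       # f_P (Hz) or dt_P (ms)
    n_r: float
    dca_epsp: Optional[float]
    shift_d: Optional[float]  # Delta f_D or Delta_D
    shift_p: Optional[float]  # Delta f_P or Delta_P
    seed: int


def sensitivity_sample(params: ParameterSet, family: str, n_draws: int,
                       seed: int,
                       lo_range: Tuple[float, float],
                       hi_range: Tuple[float, float],
                       n_r_values: Sequence[float] = (10, 20, 30, 40, 50),
                       grid: Optional[np.ndarray] = None,
                       n_events: int = 100,
                       max_failure_frac: float = 0.05):
    """Randomly sample plasticity thresholds and measure the ER effect.

    Per draw: ER- thresholds are drawn uniformly from ``lo_range`` and
    ``hi_range`` and an IP3R cluster size from ``n_r_values``; the
    thresholds are converted to (theta_D, theta_P) through the ER-
    peak-aCaM map, the ER- and ER+ weight-change curves are evaluated
    on ``grid`` and the differential shift pair recorded.  Fully
    reproducible given ``seed``; biophysical trajectories are shared
    across draws (they do not depend on the thresholds).
    """
    rng = np.random.default_rng(seed)
    if grid is None:
        if family == "rate":
            grid = np.concatenate([np.arange(0.5, 8.1, 0.5),
                                   np.arange(9.0, 20.1, 1.0)])
        else:
            grid = np.arange(-60.0, 80.1, 10.0)

    cache: dict = {}
    minus_traces = acam_traces(params, family, grid, False, n_events, cache)
    peak_fn = acam_peak_function(params, family, traces=minus_traces)
    plus_traces = {}
    for n_r in n_r_values:
        p_nr = params.copy(N_R=float(n_r))
        plus_traces[float(n_r)] = acam_traces(p_nr, family, grid, True,
                                              n_events, cache)

    samples, failures = [], 0
    for k in range(int(n_draws)):
        lo = float(rng.uniform(*lo_range))
        hi = float(rng.uniform(*hi_range))
        n_r = float(rng.choice(np.asarray(n_r_values, float)))
        try:
            theta_d, theta_p = peak_fn(lo), peak_fn(hi)
            if theta_p <= theta_d:
                raise RuntimeError("unordered thresholds")
            cm = curve_from_traces(minus_traces, params, (theta_d, theta_p),
                                   family, er=False)
            cp = curve_from_traces(plus_traces[n_r], params,
                                   (theta_d, theta_p), family, er=True)
            sd, sp = threshold_shifts(cm, cp)
            samples.append(SensitivitySample(
                index=k, threshold_lo=lo, threshold_hi=hi, n_r=n_r,
                dca_epsp=None, shift_d=sd, shift_p=sp, seed=seed))
        except RuntimeError:
            failures += 1
            samples.append(SensitivitySample(
                index=k, threshold_lo=lo, threshold_hi=hi, n_r=n_r,
                dca_epsp=None, shift_d=None, shift_p=None, seed=seed))
    if n_draws and failures > max_failure_frac * n_draws:
        raise RuntimeError(f"{failures}/{n_draws} sensitivity draws failed")
    return samples
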