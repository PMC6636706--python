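"""Stimulation protocols as deterministic event schedules.

A protocol is a pair of sorted event-time arrays (glutamate pulses and
bAP onsets) plus flags selecting the dendritic drive (synchronous
co-input for rate protocols, prescribed bAP waveform for STDP) and
whether the L-VGCC participates.  A 0.1 s pre-stimulus settling window
precedes every protocol so integration starts from the solver's rest
state with margin.

Timing conventions: the glutamate event reference is pulse onset; the
bAP waveform peaks at its onset, so "peak of the (second) bAP" equals
its event time.  Positive spike-timing difference dt means glutamate
precedes the bAP.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Tuple

import numpy as np

SETTLE = 0.1               # s of pre-stimulus settling
PAIRING_RATE = 5.0         # Hz, STDP pairing presentation rate
BAP_BURST_INTERVAL = 0.010  # s between bAPs in a burst (triplet)


@dataclass(frozen=True)
class StimulusProtocol:
    """Timed glutamate and bAP events plus protocol flags."""

    glu_times: Tuple[float, ...]
    bap_times: Tuple[float, ...]
    co_input: bool
    vgcc: bool
    duration: float
    label: str
    # output sampling hints for the integrator
    dense_rate: float = 1000.0   # Hz, within dense_window after each event
    dense_window: float = 2.0    # s
    sparse_rate: float = 20.0    # Hz elsewhere

    def __post_init__(self):
        for name in ("glu_times", "bap_times"):
            times = getattr(self, name)
            arr = tuple(float(t) for t in times)
            object.__setattr__(self, name, arr)
            if any(t < 0.0 or t > self.duration for t in arr):
                raise ValueError(f"{name} outside [0, duration]")
            if list(arr) != sorted(arr):
                raise ValueError(f"{name} must be sorted ascending")
        if self.co_input and self.bap_times:
            raise ValueError("dendritic co-input and bAP drive are mutually exclusive")

    @property
    def events(self) -> np.ndarray:
        """Union of event onsets (forced integrator mesh points)."""
        return np.unique(np.concatenate([
            np.asarray(self.glu_times, float),
            np.asarray(self.bap_times, float)]))

    def serialize(self) -> str:
        """One event per line: time(s) and kind, for audit and replay."""
        rows = [(t, "glu") for t in self.glu_times]
        rows += [(t, "bap") for t in self.bap_times]
        rows.sort()
        head = (f"# label={self.label} duration={self.duration:.6g} "
                f"co_input={int(self.co_input)} vgcc={int(self.vgcc)}")
        return "\n".join([head] + [f"{t!r}\t{kind}" for t, kind in rows])


def unitary_epsp(duration: float = 3.0) -> StimulusProtocol:
    """A single glutamate pulse at the spine head (no co-input, no bAP).

    The default 3 s window leaves room for ER Ca2+ release, which can
    trail the pulse by up to about a second.
    """
    return StimulusProtocol(glu_times=(SETTLE,), bap_times=(),
                            co_input=False, vgcc=False,
                            duration=max(duration, SETTLE + 0.5),
                            label="unitary_epsp")


def single_bap(duration: float = 1.0) -> StimulusProtocol:
    """One bAP with no glutamate (used for VGCC calibration)."""
    return StimulusProtocol(glu_times=(), bap_times=(SETTLE,),
                            co_input=False, vgcc=True,
                            duration=duration, label="single_bap",
                            dense_rate=5000.0, dense_window=0.2)


def rate_train(f: float, n_spikes: int = 900, margin: float = 3.0) -> StimulusProtocol:
    """Regular glutamate train at f Hz with synchronous dendritic co-input.

    Event times are computed as k/f (no cumulative drift).  The L-VGCC
    is disabled: the modest spine depolarization in this setting does
    not recruit it.
    """
    if f <= 0.0:
        raise ValueError("stimulation frequency must be positive")
    if n_spikes < 1:
        raise ValueError("n_spikes must be >= 1")
    times = tuple(SETTLE + k / f for k in range(n_spikes))
    return StimulusProtocol(
        glu_times=times, bap_times=(), co_input=True, vgcc=False,
        duration=times[-1] + margin, label=f"rate_{f:g}Hz_{n_spikes}",
        dense_rate=1000.0, dense_window=min(2.0, 1.0 / f))


def stdp_train(dt: float, n_pairings: int = 100, n_bap: int = 2,
               margin: float = 1.5) -> StimulusProtocol:
    """Pre/post pairing blocks at 5 Hz for STDP induction.

    Parameters
    ----------
    dt : float
        Spike-timing difference in ms between glutamate onset and the
        peak of the (second) bAP; positive when glutamate leads.
        Restricted to [-100, 100] ms.
    n_bap : {1, 2}
        bAPs per pairing (doublet / triplet); burst bAPs are 10 ms apart.
    """
    if abs(dt) > 100.0:
        raise ValueError("spike timing difference must lie in [-100, 100] ms")
    if n_bap not in (1, 2):
        raise ValueError("n_bap must be 1 or 2")
    if n_pairings < 1:
        raise ValueError("n_pairings must be >= 1")
    dt_s = dt * 1.0e-3
    period = 1.0 / PAIRING_RATE
    # offset keeps every event inside its block even for dt = -100 ms
    offset = 0.12
    glu, bap = [], []
    for k in range(n_pairings):
        t_glu = SETTLE + offset + k * period
        glu.append(t_glu)
        t_last = t_glu + dt_s
        bap.append(t_last)
        if n_bap == 2:
            bap.append(t_last - BAP_BURST_INTERVAL)
    return StimulusProtocol(
        glu_times=tuple(glu), bap_times=tuple(sorted(bap)),
        co_input=False, vgcc=True,
        duration=SETTLE + offset + (n_pairings - 1) * period + margin,
        label=f"stdp_{'triplet' if n_bap == 2 else 'doublet'}_{dt:+g}ms_{n_pairings}",
        dense_rate=5000.0, dense_window=0.12, sparse_rate=200.0)


def parse(text: str, *, co_input: bool, vgcc: bool, duration: float,
          label: str = "replayed") -> StimulusProtocol:
    """Rebuild a protocol from its serialized event list."""
    glu, bap = [], []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        t_str, kind = line.split()
        (glu if kind == "glu" else bap).append(float(t_str))
    return StimulusProtocol(glu_times=tuple(sorted(glu)),
                            bap_times=tuple(sorted(bap)),
                            co_input=co_input, vgcc=vgcc,
                            duration=duration, label=label)
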