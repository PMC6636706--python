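"""Model constants for the ER-bearing CA1 spine simulator.

All quantities are stored in a fixed package-wide unit convention:

========================  =========================
time                      s
voltage                   mV
concentration             uM (except where noted)
electrical conductance    nS
Ca2+ "permeability"       um^3/s (GHK-type conductances)
volume                    um^3, area um^2
flux                      uM/s
coupling resistance       MOhm
membrane capacitance      uF/cm^2, leak S/cm^2
========================  =========================

Configuration files use the symbols and units printed in the source
tables (e.g. ``g_N`` in pS, time constants in ms); :data:`CONFIG_KEYS`
maps each config key to its internal field and unit conversion.
"""

from __future__ import annotations

import copy
import hashlib
import json
import math
from dataclasses import dataclass, field, fields as dc_fields
from typing import Optional

import yaml


class ConfigError(ValueError):
    """Malformed or unknown configuration input."""


class ValidationError(ValueError):
    """A parameter set violates a model invariant."""


class CalibrationError(RuntimeError):
    """A calibration root-find failed to converge or bracket."""


# ---------------------------------------------------------------------------
# Parameter groups
# ---------------------------------------------------------------------------

@dataclass
class Physical:
    """Physical constants (SI except temperature)."""

    n_avogadro: float = 6.023e23      # mol^-1
    q_ca: float = 3.2e-19             # C per Ca2+ ion (2e)
    gas_constant: float = 8.314       # J mol^-1 K^-1
    faraday: float = 96485.0          # C mol^-1
    temperature_c: float = 30.0       # deg C

    @property
    def temperature_k(self) -> float:
        return self.temperature_c + 273.15


@dataclass
class Geometry:
    v_spine: float = 0.06             # um^3, spherical spine head
    er_volume_ratio: float = 0.1      # ER-to-spine-head volume ratio
    a_spine: float = 0.0              # um^2, derived: sphere surface area

    def finalize(self) -> None:
        self.a_spine = (36.0 * math.pi) ** (1.0 / 3.0) * self.v_spine ** (2.0 / 3.0)


@dataclass
class Electrical:
    c_m: float = 1.0                  # uF/cm^2
    g_leak: float = 2.0e-4            # S/cm^2
    u_rest: float = -70.0             # mV
    r_c: float = 100.0                # MOhm, spine neck resistance
    # AMPAR
    g_ampa: float = 0.5               # nS
    tau_ampa_rise: float = 0.2e-3     # s
    tau_ampa_decay: float = 2.0e-3    # s
    e_ampa: float = 0.0               # mV
    # NMDAR
    g_nmda: float = 0.065             # nS (65 pS)
    tau_nmda_rise: float = 5.0e-3     # s
    tau_nmda_decay: float = 50.0e-3   # s
    e_nmda: float = 0.0               # mV
    nmda_ca_fraction: float = 0.1     # fraction of NMDAR current carried by Ca2+
    mg_b0: float = 0.28               # Mg-block sigmoid: 1/(1 + b0*exp(-slope*u))
    mg_slope: float = 0.062           # mV^-1
    ghk_slope: float = 0.078          # mV^-1, 2F/RT at ~30 C (printed value used verbatim)
    # L-type VGCC gating
    u_m: float = -20.0                # mV
    k_m: float = 5.0                  # mV
    tau_m: float = 0.08e-3            # s
    u_h: float = -65.0                # mV
    k_h: float = -7.0                 # mV
    tau_h: float = 300.0e-3           # s
    # GHK-type VGCC conductance, um^3/s.  The default reproduces the
    # calibration rule "peak VGCC Ca2+ influx during one bAP equals peak
    # NMDAR Ca2+ influx during one EPSP" under the default parameter set
    # (see calibrate_gLVGCC, which recomputes it from scratch).
    g_lvgcc: float = 4.8317e-2
    # bAP waveform
    v0_bap: float = 67.0              # mV above rest
    tau_bap_fast: float = 3.0e-3      # s
    tau_bap_slow: float = 40.0e-3     # s
    bap_fast_frac: float = 0.7
    bap_slow_frac: float = 0.3
    # Co-active synaptic input density on the dendritic compartment
    rho_s: float = 5.0e5              # cm^-2
    # derived
    g_nmda_ca: float = 0.0            # um^3/s, GHK Ca2+ conductance of NMDAR cluster


@dataclass
class Buffering:
    # Calbindin D28-k: two medium (M) and two high (H) affinity sites.
    k_m0m1: float = 174.0             # uM^-1 s^-1
    k_m1m2: float = 87.0              # uM^-1 s^-1
    k_m1m0: float = 35.8              # s^-1
    k_m2m1: float = 71.6              # s^-1
    k_h0h1: float = 22.0              # uM^-1 s^-1
    k_h1h2: float = 11.0              # uM^-1 s^-1
    k_h1h0: float = 2.6               # s^-1
    k_h2h1: float = 5.2               # s^-1
    # Endogenous immobile buffer (CBP), first-order
    cbp_kf: float = 247.0             # uM^-1 s^-1
    cbp_kb: float = 524.0             # s^-1
    # Endogenous slow buffer (10x slower than CBP)
    slow_kf: float = 24.7             # uM^-1 s^-1
    slow_kb: float = 52.4             # s^-1
    # Calmodulin, independent C (high affinity) and N (low affinity) lobes,
    # each binding up to two Ca2+ cooperatively.
    k_c0c1: float = 6.8               # uM^-1 s^-1
    k_c1c2: float = 6.8               # uM^-1 s^-1
    k_c1c0: float = 68.0              # s^-1
    k_c2c1: float = 10.0              # s^-1
    k_n0n1: float = 108.0             # uM^-1 s^-1
    k_n1n2: float = 108.0             # uM^-1 s^-1
    k_n1n0: float = 4150.0            # s^-1
    k_n2n1: float = 800.0             # s^-1
    # Totals
    cb_total: float = 45.0            # uM
    cbp_total: float = 80.0           # uM
    slow_total: float = 40.0          # uM
    cam_total: float = 50.0           # uM


@dataclass
class Extrusion:
    """PMCA / NCX two-state pump cycles with compensating inward leaks.

    The cycle is P + Ca -(kf)-> PCa, PCa -(kb)-> P + Ca, PCa -(k3)-> P
    (Ca2+ exported).  The leak runs at ``kl`` per *unbound* pump molecule,
    set so the cycle is exactly balanced at resting Ca2+ (the printed
    3.33 / 10 s^-1 are the rounded values of this balance); ``None``
    means "derive from the balance condition".
    """

    pmca_kf: float = 150.0            # uM^-1 s^-1
    pmca_kb: float = 15.0             # s^-1
    pmca_k3: float = 12.0             # s^-1
    pmca_kl: Optional[float] = None   # s^-1, derived unless overridden
    ncx_kf: float = 300.0             # uM^-1 s^-1
    ncx_kb: float = 300.0             # s^-1
    ncx_k3: float = 600.0             # s^-1
    ncx_kl: Optional[float] = None    # s^-1
    pmca_density: float = 1000.0      # um^-2
    ncx_density: float = 140.0        # um^-2
    # derived cytosolic concentrations (uM)
    pmca_total: float = 0.0
    ncx_total: float = 0.0


@dataclass
class Cascade:
    """mGluR -> Gq -> PLCbeta -> IP3/DAG kinetics plus IP3 degradation."""

    tau_glu: float = 1.0e-3           # s, alpha-function time constant
    g_max: float = 300.0              # uM, peak glutamate at the mGluR
    # mGluR5 / Gq activation (a-rates)
    a1f: float = 11.1                 # uM^-1 s^-1  Glu + R
    a2f: float = 11.1                 # uM^-1 s^-1  Glu + R:Gq
    a3f: float = 2.0                  # uM^-1 s^-1  Glu:R + Gq
    a4f: float = 2.0                  # uM^-1 s^-1  R + Gq
    a1b: float = 2.0                  # s^-1 (scaled down 50x from source model)
    a2b: float = 2.0                  # s^-1 (scaled down 50x)
    a3b: float = 100.0                # s^-1
    a4b: float = 100.0                # s^-1
    a5: float = 116.0                 # s^-1  G-protein activation by Glu:R:Gq
    a6: float = 0.001                 # s^-1  constitutive Gq activation
    a7: float = 0.02                  # s^-1  GTP hydrolysis on free G-alpha
    a8: float = 6.0                   # s^-1  heterotrimer reassociation
    # PLC activation and PIP2 hydrolysis (b-rates)
    b1f: float = 300.0                # uM^-1 s^-1  PLC + Ca
    b2f: float = 900.0                # uM^-1 s^-1  PLC:Ca + Ga
    b3f: float = 800.0                # uM^-1 s^-1  PLC + Ga
    b4f: float = 1200.0               # uM^-1 s^-1  PLC:Ga + Ca
    b5f: float = 1200.0               # uM^-1 s^-1  PLC:Ca:PIP2 + Ga
    b1b: float = 100.0                # s^-1
    b2b: float = 30.0                 # s^-1
    b3b: float = 40.0                 # s^-1
    b4b: float = 6.0                  # s^-1
    b5b: float = 6.0                  # s^-1
    b6: float = 2.0                   # s^-1   GAP on PLC:Ga
    b7: float = 160.0                 # s^-1   GAP on PLC:Ca:Ga
    b8f: float = 1.0                  # uM^-1 s^-1  PLC:Ca + PIP2
    b9f: float = 1.0                  # uM^-1 s^-1  PLC:Ca:Ga + PIP2
    b8b: float = 170.0                # s^-1
    b9b: float = 170.0                # s^-1
    b10: float = 8.0                  # s^-1   GAP on PLC:Ca:Ga:PIP2
    b11: float = 2.0                  # s^-1   hydrolysis kcat (scaled down 4x)
    b12: float = 8.0                  # s^-1   DAG clearance
    # IP3 3-kinase (Ca2+-activated, binds 2 Ca2+ in one kinetic step)
    c1f: float = 1111.0               # uM^-2 s^-1
    c1b: float = 100.0                # s^-1
    c2f: float = 100.0                # uM^-1 s^-1
    c2b: float = 80.0                 # s^-1
    c3: float = 20.0                  # s^-1
    # IP3 5-phosphatase
    c4f: float = 9.0                  # uM^-1 s^-1
    c4b: float = 72.0                 # s^-1
    c5: float = 18.0                  # s^-1
    # Species totals (uM)
    mglur_total: float = 0.3
    plc_total: float = 0.8
    pip2_total: float = 4000.0        # treated as a buffered (constant) pool
    gq_total: float = 1.0
    ip3k_total: float = 0.9
    ip5p_total: float = 1.0


@dataclass
class ERStore:
    d1: float = 0.8                   # uM, IP3 half-activation of IP3R
    d5: float = 0.3                   # uM, Ca half-activation of IP3R
    k_inh: float = 0.2                # uM, Ca inhibition constant (h gate)
    a2: float = 2.7                   # uM^-1 s^-1, h-gate rate constant
    alpha: float = 937.5              # uM^-1 s^-1 per channel (0.15 pA at 0.5 mM)
    n_r: float = 30.0                 # IP3R cluster size (10-50)
    serca_vmax: float = 1.0           # uM/s  (V_S)
    serca_k: float = 0.2              # uM    (K_S)
    k_serca_leak: Optional[float] = None  # s^-1, derived unless overridden
    ca_er: float = 250.0              # uM, fixed luminal Ca2+
    # 'grouped' -> (m1*m2*h)^3 (source-model form, default);
    # 'h_only'  -> m1*m2*h^3 (as the flux equation is typeset).
    open_fraction_exponent: str = "grouped"


@dataclass
class Concentrations:
    ca_rest: float = 0.05             # uM (50 nM)
    ip3_rest: float = 0.1             # uM
    ca_ext: float = 2000.0            # uM (2 mM)


@dataclass
class Plasticity:
    beta_p: float = 60.0              # uM^-1
    beta_d: float = 60.0              # uM^-1
    theta_p: float = 4.0              # uM; nominal, protocol calibration resets it
    theta_d: float = 2.0              # uM
    tau_w_base: float = 1.0           # s
    tau_w_amp: float = 10.0           # s
    tau_w_floor: float = 0.001
    tau_w_exponent: float = 2.0


@dataclass
class ParameterSet:
    """Complete model parameterization with derived quantities."""

    physical: Physical = field(default_factory=Physical)
    geometry: Geometry = field(default_factory=Geometry)
    electrical: Electrical = field(default_factory=Electrical)
    buffering: Buffering = field(default_factory=Buffering)
    extrusion: Extrusion = field(default_factory=Extrusion)
    cascade: Cascade = field(default_factory=Cascade)
    er: ERStore = field(default_factory=ERStore)
    concentrations: Concentrations = field(default_factory=Concentrations)
    plasticity: Plasticity = field(default_factory=Plasticity)

    def __post_init__(self) -> None:
        self.finalize()

    # -- derived quantities -------------------------------------------------

    def finalize(self) -> "ParameterSet":
        """Recompute all derived fields from the primary ones."""
        self.geometry.finalize()
        phys, geo, ext, conc = (self.physical, self.geometry,
                                self.extrusion, self.concentrations)
        # pump surface counts -> cytosolic concentrations (uM)
        count_to_um = 1.0e6 / (phys.n_avogadro * geo.v_spine * 1.0e-15)
        ext.pmca_total = ext.pmca_density * geo.a_spine * count_to_um
        ext.ncx_total = ext.ncx_density * geo.a_spine * count_to_um
        # leak per unbound pump that balances the cycle at resting Ca
        ca0 = conc.ca_rest
        if ext.pmca_kl is None:
            ext.pmca_kl = ext.pmca_k3 * ext.pmca_kf * ca0 / (ext.pmca_kb + ext.pmca_k3)
        if ext.ncx_kl is None:
            ext.ncx_kl = ext.ncx_k3 * ext.ncx_kf * ca0 / (ext.ncx_kb + ext.ncx_k3)
        # SERCA compensating leak (balances uptake alone; the rest-state
        # solver may further trim the effective value, see engine.find_rest)
        if self.er.k_serca_leak is None:
            self.er.k_serca_leak = derive_serca_leak(self)
        # NMDAR GHK Ca2+ conductance, um^3/s
        self.electrical.g_nmda_ca = self.nmda_ca_permeability(self.electrical.g_nmda)
        return self

    def nmda_ca_permeability(self, g_nmda_ns: float) -> float:
        """GHK Ca2+ permeability (um^3/s) of the NMDAR cluster.

        g_Ca = fraction * (g_N / [Ca]_ext) * RT / (4 F^2), converted to
        the package volume/time units.
        """
        phys = self.physical
        g_si = g_nmda_ns * 1.0e-9                       # S
        ca_ext_si = self.concentrations.ca_ext * 1.0e-3  # mol/m^3
        rt_4f2 = phys.gas_constant * phys.temperature_k / (4.0 * phys.faraday ** 2)
        m3_per_s = self.electrical.nmda_ca_fraction * (g_si / ca_ext_si) * rt_4f2
        return m3_per_s * 1.0e18                         # um^3/s

    # -- bookkeeping ---------------------------------------------------------

    @property
    def g_n_ps(self) -> float:
        """NMDAR conductance in pS (boundary unit)."""
        return self.electrical.g_nmda * 1.0e3

    def copy(self, **overrides: float) -> "ParameterSet":
        """Deep copy, optionally applying flat config-key overrides."""
        new = copy.deepcopy(self)
        new.__dict__.pop("_erspine_cache", None)  # derived-state cache is stale
        for key, value in overrides.items():
            _apply_key(new, key, value)
        new.er.k_serca_leak = None if "k_S" not in overrides else new.er.k_serca_leak
        if "kL_PMCA" not in overrides:
            new.extrusion.pmca_kl = None
        if "kL_NCX" not in overrides:
            new.extrusion.ncx_kl = None
        new.finalize()
        new.validate()
        return new

    def to_config(self) -> dict:
        """Flat config dictionary in table (printed) units."""
        out = {}
        for key, (section, attr, scale) in CONFIG_KEYS.items():
            value = getattr(getattr(self, section), attr)
            if isinstance(value, str) or value is None:
                out[key] = value
            else:
                out[key] = value / scale
        return out

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_config(), fh, sort_keys=True)

    def digest(self) -> str:
        payload = json.dumps(self.to_config(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    # -- validation ----------------------------------------------------------

    def validate(self) -> "ParameterSet":
        """Check model invariants; raise ValidationError naming the field."""
        positive = {
            "geometry.v_spine": self.geometry.v_spine,
            "geometry.a_spine": self.geometry.a_spine,
            "electrical.c_m": self.electrical.c_m,
            "electrical.g_leak": self.electrical.g_leak,
            "electrical.r_c": self.electrical.r_c,
            "electrical.g_ampa": self.electrical.g_ampa,
            "electrical.tau_ampa_rise": self.electrical.tau_ampa_rise,
            "electrical.tau_ampa_decay": self.electrical.tau_ampa_decay,
            "electrical.tau_nmda_rise": self.electrical.tau_nmda_rise,
            "electrical.tau_nmda_decay": self.electrical.tau_nmda_decay,
            "concentrations.ca_rest": self.concentrations.ca_rest,
            "concentrations.ip3_rest": self.concentrations.ip3_rest,
            "concentrations.ca_ext": self.concentrations.ca_ext,
            "er.ca_er": self.er.ca_er,
            "er.d1": self.er.d1,
            "er.d5": self.er.d5,
            "er.k_inh": self.er.k_inh,
            "er.alpha": self.er.alpha,
            "cascade.tau_glu": self.cascade.tau_glu,
            "buffering.cb_total": self.buffering.cb_total + 1e-300,
            "plasticity.beta_p": self.plasticity.beta_p,
            "plasticity.beta_d": self.plasticity.beta_d,
        }
        for name, value in positive.items():
            if not (value > 0.0):
                raise ValidationError(f"{name} must be strictly positive (got {value})")
        nonneg = {
            "er.n_r": self.er.n_r,
            "er.serca_vmax": self.er.serca_vmax,
            "electrical.g_nmda": self.electrical.g_nmda,
            "buffering.cam_total": self.buffering.cam_total,
        }
        for name, value in nonneg.items():
            if value < 0.0:
                raise ValidationError(f"{name} must be non-negative (got {value})")
        if not self.plasticity.theta_p > self.plasticity.theta_d:
            raise ValidationError(
                "plasticity.theta_p must exceed plasticity.theta_d "
                f"(theta_P={self.plasticity.theta_p}, theta_D={self.plasticity.theta_d})")
        if not self.electrical.tau_ampa_decay > self.electrical.tau_ampa_rise:
            raise ValidationError("electrical.tau_ampa_decay must exceed tau_ampa_rise")
        if not self.electrical.tau_nmda_decay > self.electrical.tau_nmda_rise:
            raise ValidationError("electrical.tau_nmda_decay must exceed tau_nmda_rise")
        if self.er.ca_er <= self.concentrations.ca_rest:
            raise ValidationError("er.ca_er must exceed concentrations.ca_rest")
        if self.er.open_fraction_exponent not in ("grouped", "h_only"):
            raise ValidationError(
                "er.open_fraction_exponent must be 'grouped' or 'h_only'")
        # sphere-consistency of the derived area
        a_exact = (36.0 * math.pi) ** (1.0 / 3.0) * self.geometry.v_spine ** (2.0 / 3.0)
        if abs(self.geometry.a_spine - a_exact) > 1e-10 * a_exact:
            raise ValidationError("geometry.a_spine inconsistent with v_spine")
        return self


# ---------------------------------------------------------------------------
# Config-key registry (flat keys, printed units) -> internal fields
# ---------------------------------------------------------------------------

_MS = 1.0e-3   # config ms -> internal s
_PS = 1.0e-3   # config pS -> internal nS
_MM = 1.0e3    # config mM -> internal uM

CONFIG_KEYS = {
    # physical
    "N_a": ("physical", "n_avogadro", 1.0),
    "q_Ca": ("physical", "q_ca", 1.0),
    "R": ("physical", "gas_constant", 1.0),
    "F": ("physical", "faraday", 1.0),
    "T": ("physical", "temperature_c", 1.0),
    # geometry
    "V_spine": ("geometry", "v_spine", 1.0),
    "er_volume_ratio": ("geometry", "er_volume_ratio", 1.0),
    # electrical
    "C_m": ("electrical", "c_m", 1.0),
    "g_L": ("electrical", "g_leak", 1.0),
    "u_rest": ("electrical", "u_rest", 1.0),
    "R_C": ("electrical", "r_c", 1.0),
    "g_A": ("electrical", "g_ampa", 1.0),
    "tau_A_r": ("electrical", "tau_ampa_rise", _MS),
    "tau_A_d": ("electrical", "tau_ampa_decay", _MS),
    "E_A": ("electrical", "e_ampa", 1.0),
    "g_N": ("electrical", "g_nmda", _PS),
    "tau_N_r": ("electrical", "tau_nmda_rise", _MS),
    "tau_N_d": ("electrical", "tau_nmda_decay", _MS),
    "E_N": ("electrical", "e_nmda", 1.0),
    "nmda_ca_fraction": ("electrical", "nmda_ca_fraction", 1.0),
    "u_m": ("electrical", "u_m", 1.0),
    "k_m": ("electrical", "k_m", 1.0),
    "tau_m": ("electrical", "tau_m", _MS),
    "u_h": ("electrical", "u_h", 1.0),
    "k_h": ("electrical", "k_h", 1.0),
    "tau_h": ("electrical", "tau_h", _MS),
    "g_L_VGCC": ("electrical", "g_lvgcc", 1.0),
    "V_0": ("electrical", "v0_bap", 1.0),
    "tau_f": ("electrical", "tau_bap_fast", _MS),
    "tau_s": ("electrical", "tau_bap_slow", _MS),
    "rho_S": ("electrical", "rho_s", 1.0),
    # calbindin
    "k_M0M1": ("buffering", "k_m0m1", 1.0),
    "k_M1M2": ("buffering", "k_m1m2", 1.0),
    "k_M1M0": ("buffering", "k_m1m0", 1.0),
    "k_M2M1": ("buffering", "k_m2m1", 1.0),
    "k_H0H1": ("buffering", "k_h0h1", 1.0),
    "k_H1H2": ("buffering", "k_h1h2", 1.0),
    "k_H1H0": ("buffering", "k_h1h0", 1.0),
    "k_H2H1": ("buffering", "k_h2h1", 1.0),
    "kf_CBP": ("buffering", "cbp_kf", 1.0),
    "kb_CBP": ("buffering", "cbp_kb", 1.0),
    "kf_slow": ("buffering", "slow_kf", 1.0),
    "kb_slow": ("buffering", "slow_kb", 1.0),
    "k_C0C1": ("buffering", "k_c0c1", 1.0),
    "k_C1C2": ("buffering", "k_c1c2", 1.0),
    "k_C1C0": ("buffering", "k_c1c0", 1.0),
    "k_C2C1": ("buffering", "k_c2c1", 1.0),
    "k_N0N1": ("buffering", "k_n0n1", 1.0),
    "k_N1N2": ("buffering", "k_n1n2", 1.0),
    "k_N1N0": ("buffering", "k_n1n0", 1.0),
    "k_N2N1": ("buffering", "k_n2n1", 1.0),
    "CB_total": ("buffering", "cb_total", 1.0),
    "CBP_total": ("buffering", "cbp_total", 1.0),
    "slow_total": ("buffering", "slow_total", 1.0),
    "CaM_total": ("buffering", "cam_total", 1.0),
    # extrusion
    "kf_PMCA": ("extrusion", "pmca_kf", 1.0),
    "kb_PMCA": ("extrusion", "pmca_kb", 1.0),
    "k3_PMCA": ("extrusion", "pmca_k3", 1.0),
    "kL_PMCA": ("extrusion", "pmca_kl", 1.0),
    "kf_NCX": ("extrusion", "ncx_kf", 1.0),
    "kb_NCX": ("extrusion", "ncx_kb", 1.0),
    "k3_NCX": ("extrusion", "ncx_k3", 1.0),
    "kL_NCX": ("extrusion", "ncx_kl", 1.0),
    "rho_PMCA": ("extrusion", "pmca_density", 1.0),
    "rho_NCX": ("extrusion", "ncx_density", 1.0),
    # cascade
    "tau_glu": ("cascade", "tau_glu", _MS),
    "G_max": ("cascade", "g_max", 1.0),
    "a1f": ("cascade", "a1f", 1.0), "a2f": ("cascade", "a2f", 1.0),
    "a3f": ("cascade", "a3f", 1.0), "a4f": ("cascade", "a4f", 1.0),
    "a1b": ("cascade", "a1b", 1.0), "a2b": ("cascade", "a2b", 1.0),
    "a3b": ("cascade", "a3b", 1.0), "a4b": ("cascade", "a4b", 1.0),
    "a5": ("cascade", "a5", 1.0), "a6": ("cascade", "a6", 1.0),
    "a7": ("cascade", "a7", 1.0), "a8": ("cascade", "a8", 1.0),
    "b1f": ("cascade", "b1f", 1.0), "b2f": ("cascade", "b2f", 1.0),
    "b3f": ("cascade", "b3f", 1.0), "b4f": ("cascade", "b4f", 1.0),
    "b5f": ("cascade", "b5f", 1.0),
    "b1b": ("cascade", "b1b", 1.0), "b2b": ("cascade", "b2b", 1.0),
    "b3b": ("cascade", "b3b", 1.0), "b4b": ("cascade", "b4b", 1.0),
    "b5b": ("cascade", "b5b", 1.0),
    "b6": ("cascade", "b6", 1.0), "b7": ("cascade", "b7", 1.0),
    "b8f": ("cascade", "b8f", 1.0), "b9f": ("cascade", "b9f", 1.0),
    "b8b": ("cascade", "b8b", 1.0), "b9b": ("cascade", "b9b", 1.0),
    "b10": ("cascade", "b10", 1.0), "b11": ("cascade", "b11", 1.0),
    "b12": ("cascade", "b12", 1.0),
    "c1f": ("cascade", "c1f", 1.0), "c1b": ("cascade", "c1b", 1.0),
    "c2f": ("cascade", "c2f", 1.0), "c2b": ("cascade", "c2b", 1.0),
    "c3": ("cascade", "c3", 1.0),
    "c4f": ("cascade", "c4f", 1.0), "c4b": ("cascade", "c4b", 1.0),
    "c5": ("cascade", "c5", 1.0),
    "mGluR_total": ("cascade", "mglur_total", 1.0),
    "PLC_total": ("cascade", "plc_total", 1.0),
    "PIP2_total": ("cascade", "pip2_total", _MM),
    "Gq_total": ("cascade", "gq_total", 1.0),
    "IP3K_total": ("cascade", "ip3k_total", 1.0),
    "IP5P_total": ("cascade", "ip5p_total", 1.0),
    # ER store
    "d1": ("er", "d1", 1.0),
    "d5": ("er", "d5", 1.0),
    "K_inh": ("er", "k_inh", 1.0),
    "a2": ("er", "a2", 1.0),
    "alpha": ("er", "alpha", 1.0),
    "N_R": ("er", "n_r", 1.0),
    "V_S": ("er", "serca_vmax", 1.0),
    "K_S": ("er", "serca_k", 1.0),
    "k_S": ("er", "k_serca_leak", 1.0),
    "Ca_ER": ("er", "ca_er", 1.0),
    "open_fraction_exponent": ("er", "open_fraction_exponent", 1.0),
    # concentrations
    "Ca_rest": ("concentrations", "ca_rest", 1.0),
    "IP3_rest": ("concentrations", "ip3_rest", 1.0),
    "Ca_ext": ("concentrations", "ca_ext", _MM),
    # plasticity
    "beta_P": ("plasticity", "beta_p", 1.0),
    "beta_D": ("plasticity", "beta_d", 1.0),
    "theta_P": ("plasticity", "theta_p", 1.0),
    "theta_D": ("plasticity", "theta_d", 1.0),
    "tau_w_base": ("plasticity", "tau_w_base", 1.0),
    "tau_w_amp": ("plasticity", "tau_w_amp", 1.0),
    "tau_w_floor": ("plasticity", "tau_w_floor", 1.0),
    "tau_w_exponent": ("plasticity", "tau_w_exponent", 1.0),
}

#: Flux-equation symbols that are constants (not state variables), each
#: resolving to exactly one configuration key.  Used by the symbol
#: inventory test.
SYMBOL_INVENTORY = {
    # membrane equation
    "C_m": "C_m", "g_L": "g_L", "u_rest": "u_rest", "R_C": "R_C",
    "g_A": "g_A", "tau_A_r": "tau_A_r", "tau_A_d": "tau_A_d", "E_A": "E_A",
    "g_N": "g_N", "tau_N_r": "tau_N_r", "tau_N_d": "tau_N_d", "E_N": "E_N",
    "u_m": "u_m", "k_m": "k_m", "tau_m": "tau_m",
    "u_h": "u_h", "k_h": "k_h", "tau_h": "tau_h",
    "g_L_VGCC": "g_L_VGCC", "q_Ca": "q_Ca", "N_a": "N_a",
    "Ca_ext": "Ca_ext",
    # bAP drive
    "V_0": "V_0", "tau_f": "tau_f", "tau_s": "tau_s", "rho_S": "rho_S",
    # calcium balance
    "V_spine": "V_spine", "R": "R", "F": "F", "T": "T",
    # ER release and uptake
    "d1": "d1", "d5": "d5", "K_inh": "K_inh", "a2": "a2",
    "alpha": "alpha", "N_R": "N_R", "Ca_ER": "Ca_ER",
    "V_S": "V_S", "K_S": "K_S", "k_S": "k_S",
    # glutamate drive
    "tau_glu": "tau_glu", "G_max": "G_max",
    # plasticity rule
    "beta_P": "beta_P", "beta_D": "beta_D",
    "theta_P": "theta_P", "theta_D": "theta_D",
}


def _apply_key(params: ParameterSet, key: str, value) -> None:
    if key not in CONFIG_KEYS:
        raise ConfigError(f"unknown configuration key: {key!r}")
    section, attr, scale = CONFIG_KEYS[key]
    if isinstance(value, str) or value is None:
        setattr(getattr(params, section), attr, value)
    else:
        setattr(getattr(params, section), attr, float(value) * scale)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def default_parameters() -> ParameterSet:
    """The full default parameter set with derived fields populated."""
    return ParameterSet().validate()


def load_config(document) -> ParameterSet:
    """Build a validated ParameterSet from a flat config document.

    Parameters
    ----------
    document
        A mapping of config keys to values, a YAML string, or a path to a
        YAML file.  Unknown keys are rejected; missing keys fall back to
        the defaults.
    """
    if document is None:
        data = {}
    elif isinstance(document, dict):
        data = document
    else:
        text = str(document)
        if "\n" not in text and not text.lstrip().startswith("{"):
            try:
                with open(text) as fh:
                    text = fh.read()
            except OSError as exc:
                raise ConfigError(f"cannot read config file {document!r}: {exc}")
        try:
            data = yaml.safe_load(text) or {}
        except yaml.YAMLError as exc:
            raise ConfigError(f"malformed configuration document: {exc}")
        if not isinstance(data, dict):
            raise ConfigError("configuration document must be a mapping")
    params = ParameterSet()
    overridden = set(data)
    for key, value in data.items():
        _apply_key(params, key, value)
    # re-derive anything not explicitly pinned by the document
    if "kL_PMCA" not in overridden:
        params.extrusion.pmca_kl = None
    if "kL_NCX" not in overridden:
        params.extrusion.ncx_kl = None
    if "k_S" not in overridden:
        params.er.k_serca_leak = None
    params.finalize()
    params.validate()
    return params


def derive_serca_leak(params: ParameterSet) -> float:
    """SERCA-balancing ER leak rate k_S (s^-1).

    Solves k_S * ([Ca]_ER - Ca_rest) = V_S * Ca_rest^2 / (Ca_rest^2 + K_S^2),
    i.e. the linear leak exactly offsets SERCA uptake at resting Ca2+.
    """
    ca0 = params.concentrations.ca_rest
    if params.er.ca_er <= ca0:
        raise ValidationError("er.ca_er must exceed resting Ca2+ to derive k_S")
    uptake = params.er.serca_vmax * ca0 ** 2 / (ca0 ** 2 + params.er.serca_k ** 2)
    return uptake / (params.er.ca_er - ca0)


def calibrate_gN(params: ParameterSet, target_dca: float,
                 rtol: float = 0.01) -> float:
    """NMDAR conductance (pS) whose unitary-EPSP peak Ca2+ rise equals target.

    The calibration runs the ER-disabled spine (the ER- reference used
    throughout) with a single glutamate pulse and root-finds on the peak
    free-Ca2+ increment over rest.  Monotonicity of the peak in g_N is
    assumed and asserted on the search bracket.

    Parameters
    ----------
    target_dca : float
        Desired peak increment in uM, in [0.05, 2].
    """
    from . import engine, protocols  # deferred: engine depends on this module

    if not (0.05 <= target_dca <= 2.0):
        raise CalibrationError(f"target {target_dca} uM outside [0.05, 2] uM")

    proto = protocols.unitary_epsp(duration=1.2)

    def peak(g_ps: float) -> float:
        trial = params.copy(g_N=g_ps)
        traj = engine.run(proto, trial, er=False)
        return float(traj.ca.max() - trial.concentrations.ca_rest)

    lo, hi = 5.0, 400.0
    f_lo, f_hi = peak(lo), peak(hi)
    expansions = 0
    while not (f_lo <= target_dca <= f_hi):
        if f_lo > target_dca:
            lo /= 10.0
            f_lo = peak(lo)
        else:
            hi *= 10.0
            f_hi = peak(hi)
        expansions += 1
        if expansions > 1:
            raise CalibrationError(
                f"could not bracket target {target_dca} uM "
                f"(peaks {f_lo:.4g}..{f_hi:.4g} for g_N {lo:.4g}..{hi:.4g} pS)")
    if not f_hi > f_lo:
        raise CalibrationError("peak Ca2+ is not increasing in g_N on the bracket")

    from scipy.optimize import brentq
    g_star = brentq(lambda g: peak(g) - target_dca, lo, hi,
                    rtol=rtol * 0.5, xtol=1e-3)
    achieved = peak(g_star)
    if abs(achieved - target_dca) > rtol * target_dca:
        raise CalibrationError(
            f"calibration residual {achieved:.4g} vs target {target_dca:.4g} uM")
    return float(g_star)


def calibrate_gLVGCC(params: ParameterSet, rtol: float = 0.01) -> float:
    """VGCC conductance (um^3/s) matching peak bAP Ca2+ influx to the NMDAR's.

    Sets g_L-VGCC so that the maximum L-VGCC Ca2+ influx rate during a
    single bAP (no glutamate) equals the maximum NMDAR Ca2+ influx rate
    during a single EPSP (no bAP).  The VGCC flux feedback on voltage is
    negligible at these magnitudes, making the peak essentially linear in
    g_L-VGCC; a proportional update plus a verification run enforces the
    tolerance.
    """
    from . import engine, protocols

    if params.electrical.g_nmda <= 0.0:
        raise CalibrationError("g_N must be positive to define the target influx")

    epsp = protocols.unitary_epsp(duration=0.8)
    traj_epsp = engine.run(epsp, params, er=False)
    target = float(traj_epsp.fluxes()["j_nmda"].max())
    if target <= 0.0:
        raise CalibrationError("zero NMDAR influx target; cannot calibrate VGCC")

    bap = protocols.single_bap(duration=0.8)

    def peak_vgcc(g: float) -> float:
        trial = params.copy(g_L_VGCC=g)
        traj = engine.run(bap, trial, er=False)
        return float(traj.fluxes()["j_vgcc"].max())

    g = params.electrical.g_lvgcc if params.electrical.g_lvgcc > 0 else 1e-3
    for _ in range(8):
        p = peak_vgcc(g)
        if p <= 0.0:
            raise CalibrationError("VGCC influx peak is non-positive")
        if abs(p - target) <= rtol * target:
            return float(g)
        g *= target / p
    raise CalibrationError(
        f"VGCC calibration did not converge (last peak {p:.4g}, target {target:.4g})")
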