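# Model and methods

`erspine` simulates the coupled electrical and calcium dynamics of a
single CA1 dendritic spine head that may contain endoplasmic reticulum
(ER), and the early synaptic plasticity those dynamics drive.  The
model is a deterministic, single-compartment ("well-mixed") ODE system
of about fifty state variables.

## Compartment and membrane potential

The spine head is a sphere of fixed volume V_spine = 0.06 μm³,
resistively coupled to a parent dendrite through a neck resistance
R_C = 100 MΩ.  The spine membrane carries a passive leak (C_m = 1
μF cm⁻², g_L = 2·10⁻⁴ S cm⁻²), AMPAR and NMDAR synaptic currents with
linear I–V relations, and a high-voltage-activated L-type Ca²⁺ current
described by a Goldman–Hodgkin–Katz (GHK) flux with m²h gating.  The
NMDAR conductance carries the voltage-dependent Mg²⁺ block
B(u) = 1/(1 + 0.28·e^(−0.062u)).  Receptor conductances are unnormalized
differences of exponentials (AMPA: 0.2/2 ms; NMDA: 5/50 ms) that sum
over pulses in a train.

The dendritic compartment runs in one of three modes, selected by the
protocol:

* **passive** – a leaky compartment relaxing to rest (unitary inputs);
* **co-input** – a per-unit-area passive compartment driven by the
  synchronous synaptic conductance density ρ_S·(g_AMPA(t) +
  g_NMDA(t)·B(u_d)) with ρ_S = 5·10⁵ cm⁻² (rate protocols).  The
  feedback current from the single spine onto the (much larger)
  dendrite is neglected.  With the tabulated ρ_S this circuit
  depolarizes the spine head by ≈15 mV per input, the calibration
  target for synchronous Schaffer-collateral activation;
* **prescribed** – the dendritic voltage follows the injected bAP
  waveform V₀·θ(t)(0.7·e^(−t/3ms) + 0.3·e^(−t/40ms)), V₀ = 67 mV (STDP
  protocols).  The waveform peaks at its onset, so "the time of the bAP
  peak" equals the bAP event time.  The dendrite state is integrated
  with the waveform's analytic slope and re-pinned to the exact profile
  at every event boundary, which keeps the θ-step out of the error
  estimator.

The L-VGCC participates only in protocols containing bAPs; during rate
protocols the few-mV spine depolarization does not recruit it.  Its
conductance is calibrated so the peak VGCC Ca²⁺ influx during one bAP
equals the peak NMDAR Ca²⁺ influx during one EPSP (the frozen default
4.8317·10⁻² μm³ s⁻¹ satisfies this rule for the default parameter set;
`calibrate_gLVGCC` recomputes it from scratch and a test verifies the
round trip).

## Calcium handling

Free cytosolic Ca²⁺ follows
dCa/dt = J_N + J_VGCC + J_ER + J_B − J_out − J_casc, with

* **J_N** – NMDAR Ca²⁺ influx: 10% of the NMDAR conductance expressed
  as a GHK permeability g_N^Ca = 0.1·(g_N/[Ca]_ext)·RT/(4F²) at 30 °C.
  GHK driving terms use the printed slope 0.078 mV⁻¹ verbatim and a
  series expansion for |0.078u| < 10⁻⁴ so the flux is continuous
  through u = 0.
* **J_B** – net buffer release.  Calbindin-D28k (45 μM) is the full
  9-state scheme over two medium- and two high-affinity sites; the
  printed first/second-step rates are taken as already containing the
  two-identical-site statistical factors.  An immobile buffer (CBP,
  80 μM) and a 10× slower buffer (40 μM) are first-order.  Calmodulin
  (50 μM) is evolved as two independent cooperative two-site lobes (C
  and N) over the same molecule population.
* **J_out** – PMCA and NCX as explicit two-state cycles (not
  quasi-steady-state) with surface densities 1000 and 140 μm⁻²
  converted to concentrations through A_spine/(N_A·V_spine).  Each pump
  carries a constant inward leak per *unbound* pump molecule that
  exactly balances the cycle at 50 nM; the defaults use the exact
  balance values (10/3 and 10 s⁻¹), of which the tabulated 3.33/10 are
  the rounded forms.
* **J_casc** – the (small) net Ca²⁺ sequestration by cascade species
  (PLC Ca-binding, the two-Ca²⁺ activation of IP3K), included so total
  calcium is exactly conserved.

## mGluR–IP₃ cascade

Glutamate pulses are α-functions with τ = 1 ms normalized to a 300 μM
peak at the perisynaptic mGluR.  The cascade topology — mGluR–Gq
activation, PLCβ activation by Ca²⁺ and Gα, PIP₂ hydrolysis to IP₃ and
DAG, and IP₃ degradation by Ca²⁺-activated IP₃-3-kinase and
IP₃-5-phosphatase — is declared in a single auditable reaction table
(`mglur_cascade.reaction_table`); a table-driven evaluator is kept as
the reference implementation for the hand-coded fast path.

Two reconstruction decisions matter and were resolved against the
model's observable behaviour:

1. **Catalysis requires both Ca²⁺ and Gα on PLC.**  A Gα-free catalytic
   branch at the printed 8 s⁻¹ would produce ≈0.8 μM/s of basal IP₃ and
   pin resting IP₃ near 0.35 μM, contradicting the 0.1 μM resting
   level; with catalysis confined to the Ca·Gα·PLC·PIP₂ complex the
   resting level is maintained by a small constitutive source (derived
   so the basal cascade is exactly stationary at IP₃ = 0.1 μM; ≈0.17
   μM/s under defaults).
2. **b7 = 160 s⁻¹ is the hydrolysis rate; b11 = 2 s⁻¹ is the GTPase
   (GAP) step on the active complex.**  The two deliberately slowed
   parameter groups — glutamate unbinding (a1b = a2b = 2 s⁻¹) and the
   GAP step (b11 = 2 s⁻¹) — are then precisely the receptor and Gα
   lifetimes (≈0.5 s each) whose convolution places the IP₃ transient a
   few hundred milliseconds after the pulse.  Restoring the unscaled
   source-model values shortens the IP₃ latency several-fold, as
   expected.

PIP₂ (4 mM) is treated as a buffered, constant pool; DAG is produced,
tracked and cleared at b12 = 8 s⁻¹ but has no signalling consumers.

## ER store

IP₃R gating follows the reduced Li–Rinzel-type scheme: activation
variables m₁ = IP₃/(d₁+IP₃), m₂ = Ca/(d₅+Ca) and a slow inactivation
gate dh/dt = a₂(K_inh − (K_inh+Ca)h).  The open fraction defaults to
the grouped cube (m₁m₂h)³, the source-model form; the typeset variant
m₁m₂h³ is available through `open_fraction_exponent = "h_only"`.  With
the h-only form the basal flux at resting IP₃ would exceed all resting
clearance by orders of magnitude, which corroborates the grouped
default.  Release scales with the cluster size N_R (10–50, default 30)
and a per-channel flux coefficient α = 937.5 μM⁻¹s⁻¹ (0.15 pA per open
channel at a 0.5 mM gradient); the luminal concentration is fixed at
250 μM.  SERCA uptake is Hill-type (V_S = 1 μM/s, K_S = 0.2 μM) with a
linear compensating leak.

The tabulated leak k_S balances SERCA alone.  Because a small basal
IP₃R flux exists at resting IP₃, the rest-state solver additionally
trims the *effective* leak so that the whole ER term vanishes at rest;
the trim is logged.  Under defaults the trimmed coefficient is slightly
negative (−1.4·10⁻³ s⁻¹), i.e. the balance term acts as a weak extra
uptake — it is a stationarity device, not a physical leak.  The
ER-lacking spine is modelled by omitting the ER term entirely, so a
spine with N_R = 0 and V_S = 0 is identical to it term-by-term (a
regression test asserts trajectory equality).

## Plasticity rule

The readout is active calmodulin, aCaM = CaM_tot·(1 − p(C₀)p(N₀)):
molecules carrying at least one bound Ca²⁺, computed under lobe
independence.  The weight obeys τ_w(aCaM)·dw/dt = −w + Ω_w(aCaM) with
Ω_w a difference of two sigmoids (slopes 60 μM⁻¹) crossing −0.5
(depression) between θ_D and θ_P and +0.5 (potentiation) above θ_P.
The relaxation time is reconstructed as

    τ_w = 1 + 10 / (0.001 + (2·aCaM/(θ_D+θ_P))^p),   p = 2,

which reproduces the constraining time scales: ≈10⁴ s (hours) at zero
activation, ≈11 s at mid-band activation, minutes in the LTD band; the
exponent p is exposed in the configuration.

Thresholds are calibrated per protocol family on the ER-lacking spine:
θ_D (θ_P) is the maximal steady-state aCaM attained at the LTD (LTP)
boundary stimulus — e.g. 1 and 15 Hz for rate-dependent plasticity, or
∓35 ms for triplet STDP.  Under defaults the 1 Hz calibration yields
θ_D ≈ 1.9 μM, consistent with the 2 μM working value used in the
low-frequency depression analyses.  Since w does not feed back on the
biophysics, trajectories are simulated once and the scalar weight ODE
is re-integrated offline (exact exponential steps on each sampling
interval) for any thresholds; an engine-vs-offline consistency test
bounds the sampling error.

## Protocols and numerics

Protocols are deterministic event schedules (times computed as k/f, no
cumulative drift) with a 0.1 s settling window.  STDP pairings are
presented at 5 Hz; Δt is the interval from glutamate onset to the peak
of the (second) bAP, positive when glutamate leads, with burst bAPs 10
ms apart.

The full system is integrated with LSODA (default rtol 10⁻⁶, absolute
tolerances 10⁻⁹ μM for concentrations and 10⁻⁶ mV for voltages) in
per-event segments, with event onsets as forced mesh points.  Output is
sampled densely (1–5 kHz) in a window after each event and sparsely
elsewhere.  Derived flux channels are recomputed exactly from state
snapshots rather than integrated separately.  The rest state is
assembled from closed-form buffer/pump equilibria, a Newton solve of
the cascade stationarity on conservation-reduced coordinates, and the
leak trim; its full-system residual is verified below 10⁻⁹.  The rest
state is defined with the L-VGCC disengaged; in bAP protocols the
channel's sub-nM residual window current is simply integrated.

Problem sizes: the test suite and sampling analyses use scaled
stimulation — 10–150 stimuli per train, coarse induction-variable grids
(0.5–1 Hz and 10 ms steps), and IP₃R cluster sizes drawn from the
lattice {10, 30, 50} — and assert the qualitative invariants
(differential LTD enhancement, frequency-dependent suppression of the
ER contribution, LTD-window broadening exceeding LTP-window broadening).
Full published-scale sweeps (900 stimuli, 0.1 Hz / 1 ms grids, 5000
draws) are available through the CLI's `--scale paper` mode.

## What the model does and does not capture

The simulator reproduces the paper-scale phenomenology of a single
average ER⁺ spine: delayed store release (≈460 ms at the calibrated
operating point), its non-monotonic dependence on input rate, and the
selective enhancement of depression.  It does not model spatial
gradients or spine–dendrite Ca²⁺ diffusion, luminal depletion
([Ca²⁺]_ER fixed), stochastic single-channel IP₃R gating, or the
downstream CaMKII/phosphatase network (abstracted into Ω_w).  Conclusions
about real synapses inherit those idealizations: passing tests show the
implementation realizes this model faithfully, not that the model
exhausts spine biology.

## Known limitations

* The cascade topology is a reconstruction from the printed rate
  inventory and scheme figure; alternative arrow placements that
  preserve the resting state and the IP₃ latency are conceivable.
* The steady-state window for "maximum steady-state amplitude" during
  trains is the last 20% of the stimulation period (the source does not
  state its window); the choice is recorded in outputs.
* Threshold calibration matches peak aCaM at the boundary stimuli;
  near-threshold weight changes at scaled-down train lengths are small,
  so window-width metrics use a ±0.01 dead band on Δw.
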