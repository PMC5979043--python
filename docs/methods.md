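# Methods

## Model overview and assumptions

The model represents one synapse enwrapped by an astroglial perisynaptic
cradle (PsC).  Six compartments: synapse, perisynaptic extracellular
space (PsECS, the 30 nm shell between terminal and cradle), the cradle
itself, the thin process (25 µm × 100 nm cylinder), the astrocyte soma
and the global extracellular space (GECS).  Soma and GECS concentrations
are fixed boundary conditions; the PsECS and PsC are well-mixed (no
spatial gradients within a compartment).  Only K⁺, Na⁺ and glutamate are
tracked; Cl⁻ and Ca²⁺ dynamics, NKCC1 and NCX are outside the model's
scope, which restricts its validity to extracellular K⁺ below ~10 mM.

State variables: astrocyte membrane potential `V_A`, `[K⁺]_PsC`,
`[Na⁺]_PsC`, `[K⁺]_PsECS`, `[Glu]_PsECS`, and the presynaptic neurone's
Hodgkin–Huxley variables `V_Neu, n, m, h`.  Concentration rates are
current sums divided by `z·F·Vol` of the receiving compartment; `V_A`
integrates the total membrane current over `C_m·SA_PsC`.  The process
hopping current transfers ions between PsC and soma without crossing the
perisynaptic membrane, so it enters the concentration budgets but not
the voltage equation.  One sign convention holds throughout: a positive
current means the ion *leaves* the named compartment; each channel's
sign is assigned from its physiology (the pump imports K⁺ / exports Na⁺,
the glutamate transporter exports K⁺ / imports Na⁺ and glutamate).

## Membrane and process currents

Geometry: the cradle is a half-cylindrical shell (lateral areas `π r l`,
half-disc cross sections, half-annulus volume), the process a full
cylinder.  These conventions reproduce the reference morphology table to
four significant figures; the synapse volume, PsECS volume and
PsECS–GECS contact area are not derivable from the printed lengths and
are carried as literal values (flagged in logs).

* **Kir**: `g_Kir [K⁺]_PsECS (V_A − E_Kir) SA_PsC`.  The reversal is the
  instantaneous K⁺ Nernst potential between PsECS and PsC **plus a
  +25 mV offset** (`kir_reversal_mode="nernst_offset"`, the default).
  This reading keeps the channel weakly inward at rest, lets its driving
  force track the growing K⁺ microdomain (its uptake genuinely
  diminishes as `[K⁺]_PsC` rises), and is the reading whose
  rest-calibrated background conductance lands closest to the tabulated
  one.  A fixed +25 mV reversal and a bare-Nernst reversal are retained
  as configuration options and covered by tests.
* **Background K⁺/Na⁺**: ohmic channels against the PsECS/PsC Nernst
  potentials.  Their conductances are free parameters fixed by the
  resting condition (below).
* **NKA**: magnitude `F·P_max·Hill₁.₅(Na_i)·MM(K_e)·SA_PsC`, ×2 for K⁺
  (inward), ×3 for Na⁺ (outward).  `P_max` is a turnover rate in
  mol m⁻² s⁻¹ (an ampere result requires a rate).
* **EAAT1/2**: signed transport rate
  `J = −I_mg·(1 − exp(r_g(s_g − [Glu]_e)))·SA_PsC` with
  `I_mg = (1/6)(−α(exp(−β(V_A − V_rev)) − 1))`; per forward cycle 1 K⁺
  out, 3 Na⁺ in, 1 glutamate removed from the PsECS.  Two parameter
  profiles exist (below).
* **Poole–Frenkel process current**: cations trapped in wells of depth
  `φ_w` (eV) escape thermally; the field along the process lowers the
  barrier by `√(Q|ΔV|/(l π ε))`.  `ΔV = V_A − V_m − V_r` with `V_r` the
  soma/PsC Nernst potential; the magnitude of `ΔV` enters the barrier
  (avoiding complex roots under reverse drive) and the current carries
  the sign of `ΔV`.  The potential along the process is assumed linear,
  wells non-overlapping.  `ε_r = 0.82` is used verbatim although it is
  below vacuum permittivity — a warning is logged once.
* **PsECS→GECS leak**: `g_ECS·(RT/F)ln([K⁺]_PsECS/[K⁺]_GECS)·SA` — a
  gradient-controlled, logarithmically saturating channel.

## Presynaptic neurone and its K⁺ coupling

The neurone is the classic squid-axon Hodgkin–Huxley model translated by
−5 mV so it rests near −70 mV.  Gating kinetics are kept at the
classical calibration temperature: Q10-scaling them to 310 K would
require sub-microsecond steps under forward Euler, and only the spike
count and shape enter the coupling.  The n⁴ delayed-rectifier current
releases K⁺ into the PsECS during each action potential; a neuronal
Na⁺/K⁺-ATPase (cytosolic Na⁺ fixed, K⁺ site the only dynamic regulator)
recovers it.

Two calibrations close the neuronal budget:

1. **Coupling fraction `f` (`release_fraction`)**.  The PsECS holds only
   ~2×10⁻¹⁸ L; coupling the full HH spike charge (~3.1 fC of K⁺) to it
   would raise `[K⁺]_PsECS` by ~16 mM per spike and rule out any steady
   state.  Physically, only part of the terminal surface faces the
   perisynaptic shell.  `f` is fixed by the steady-state balance that
   defines sustained high-frequency activity: at 80 Hz, release equals
   clearance, where the lasting extracellular sinks are the GECS leak
   and the neuronal pump (the astrocyte is a *transient* buffer — its
   pump is limited by cytosolic Na⁺ resupply, and once the microdomain
   fills, the Kir/background channels recirculate the pumped K⁺).  The
   balance is evaluated at 10 mM extracellular K⁺ — the pump's
   half-activation and the upper edge of the model's validity domain —
   and gives f = 6.9×10⁻³.  All terms are closed-form except the
   per-spike charge, measured from one simulated action potential.
2. **Neuronal pump rate** is then set so release and reuptake cancel
   exactly at rest (the tabulated value, with the classic HH fallback
   neurone, is ~150× too small for this; its sign is absorbed into the
   convention).

Protocol stimulation uses a suprathreshold pulse train at the target
rate (one spike per 1 ms pulse).  The classic HH model cannot fire
below ~55 Hz under constant current (type-II onset), so constant-current
drive cannot realize the 20 and 40 Hz protocols; constant-current
calibration is still provided (`calibrate_drive(mode="constant")`, with
a stationarity check that rejects the slowly decelerating near-rheobase
transient) and errors informatively outside its achievable range.

## Resting calibration

With every other channel evaluated at the tabulated initial state, the
background conductances are solved so the total K⁺ and Na⁺ currents
(membrane + process) vanish identically: `g_K = 14.46 S/m²` (the
tabulated 16.9131 leaves a +1.26×10⁻¹⁵ A K⁺ residual, which is logged),
`g_Na = 0.4300 S/m²` (tabulated 0.4293 — nearly self-consistent).  After
calibration the rest state is an exact fixed point: a 6 s unstimulated
run drifts by strictly zero in double precision.

## EAAT parameter profiles

As printed, `r_g·[Glu] ≈ 10⁻¹²` and `β·ΔV ≈ 10⁻³`, so every transporter
current is below 10⁻²⁰ A — no glutamate-driven dynamics at all.  Since
the intended units are not recoverable, the package ships two profiles:

* `as_printed` (default): constants exactly as tabulated; used for the
  K⁺-driven experiments (where glutamate is clamped anyway).
* `rescaled`: the same digits read on shifted scales — `β` as mV⁻¹
  (28.8 V⁻¹) and `r_g` as µM⁻¹ (0.5 M⁻¹) — used for the glutamate-puff
  and combined protocols.  This yields a measurable Na⁺ microdomain
  (+0.085 mM for a 1 mM, 10 s puff) while preserving resting stability;
  stronger readings of `r_g` reverse the transporter at baseline
  glutamate and destroy the resting state.

Every simulation records its profile in the metadata.

## Integration and numerics

Fixed-step forward Euler, Δt = 10 µs (all protocols with spiking) or
100 µs (glutamate puff, no spiking), astrocyte and neurone advanced
synchronously; trajectories are recorded at 1 ms.  Halving Δt changes
the PsC K⁺ trajectory of a full one-minute 40 Hz run by <1% (first-order
convergence; verified in the tests).  The inner loop is numba-compiled
(~1 s per simulated minute); a pure-Python reference implementation of
the derivative and step is kept and held to agreement with the compiled
loop by a unit test.  Peak-current statistics and Kir sign changes are
accumulated at full resolution inside the loop, so 1 ms sampling never
clips a spike-locked peak.  Concentration positivity is enforced by
error (with the failing variable and time), never by silent clipping;
the one sanctioned clip is the glutamate floor at its background value,
standing in for the unmodelled glutamate resupply.  The model contains
no random number source; runs are bit-reproducible.

## Protocols

* `k_driven(rate)`: 0.1 min equilibration, stimulation 0.1→1 min,
  0.2 min observation; glutamate clamped at 1 µM.
* `glu_puff(peak, width)`: extracellular K⁺ clamped at 3 mM; glutamate
  prescribed as a Gaussian centred at the stimulus midpoint with
  σ = width/6 (≈99.7% of the pulse inside the stated width); ≥120 s tail
  to capture the Na⁺ decay.
* `combined(rate, puff)`: pulse-train firing plus an instantaneous
  +100 µM glutamate increment per detected spike; glutamate evolves
  freely with EAAT uptake and the floor as the only removal routes.
* Sweeps (PsC surface area ×{0.75,1,1.25}; pump rate ×{0.2,0.5,1,5};
  well depth 4–15 k_BT) scale the *calibrated* reference system without
  re-calibrating: the resting imbalance a scaled pump creates — net PsC
  K⁺ loss and Na⁺ gain at 0.2× — is the sensitivity phenomenon itself.

## What the simulated conditions do and do not show

The synthetic stimulation emulates sustained cortical firing (20–80 Hz)
with deterministic, perfectly periodic spikes and an idealized glutamate
time course.  Real terminals release stochastically, synapses see
irregular spike trains, and the extracellular space is tortuous rather
than two well-mixed boxes; passing tests therefore demonstrate the
internal consistency and qualitative mechanism (microdomain formation,
process isolation, post-stimulus K⁺ return, sensitivity directions), not
quantitative agreement with any particular experimental recording.

## Known limitations

* The net membrane current is charge-limited: because `C_m dV/dt ≈ 0` on
  slow timescales, net K⁺ uptake equals net Na⁺ export, so the cradle
  microdomain is capped near `[K⁺]_PsC ≈ 113 mM` (the 13.5 mM of
  exportable cytosolic Na⁺) on the one-minute timescale.
* The extracellular steady state during 80 Hz stimulation is approached
  on the timescale of the cytosolic Na⁺ store depletion (~25–30 s with
  the tabulated parameters).
* The membrane-voltage oscillation under combined stimulation is
  spike-locked and sub-millivolt-to-few-millivolt at the calibrated
  release magnitude; the Kir driving force stays single-signed under the
  default parameterization (the tabulated transporter constants are too
  small, under any unit reading that preserves resting stability, to
  reverse it).
* The glutamate-puff Na⁺ decay time is set by the background-Na⁺ and
  pump slopes at rest (τ ≈ 13 s, 5% decay ≈ 36 s); it is insensitive to
  the size of the Na⁺ transient while the response stays linear.
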