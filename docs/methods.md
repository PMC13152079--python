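# Methods

## Scope and model family

`myocyte` implements a deterministic ODE model of a single human
endocardial ventricular cardiomyocyte with four intracellular compartments
— junctional dyad, subsarcolemmal space (SL), bulk myoplasm (MYO) and
sarcoplasmic reticulum (SR) — plus membrane electrophysiology, CaMKII and
beta-adrenergic signaling, and Land-type active contraction. The cell
architecture and calcium handling follow the Shannon/Grandi compartmental
tradition; most ionic current formulations follow the O'Hara-Rudy /
ToR-ORd tradition. Every equation in this package was authored and
parameterized here: current kinetics use standard published gating forms,
and the maximal conductances, calcium-handling rates and signaling
couplings were calibrated (by direct search against target biomarkers, in
the same spirit as the multi-objective fitting used for models of this
class) so that the integrated cell reproduces the behaviors listed under
*Calibration targets* below. The package is therefore a re-derived model of
this class, not a transcription of any single published parameter set.

## State and units

50 ODE states: membrane potential (mV); Hodgkin-Huxley gates for INa
(m, h_fast, h_slow, j), INaL (mL, hL and a CaMKII-phosphorylated variant
hLp), Ito (a, i_fast, i_slow), ICaL (d, f_fast, f_slow, a calcium-dependent
inactivation gate `fca` and a slow recovery gate `jca`), IKr (xr_fast,
xr_slow), IKs (xs1, xs2); RyR occupancies (rest/open/inactivated, with the
calcium-induced refractory pool as the complement); the ICaL-coupled
release subset's activation and recovery gates; Na in SL and MYO; a single
well-mixed K pool; free Ca in MYO, SL, dyad and SR; six explicit buffer
states (calmodulin-class cytosolic buffer, low/high-affinity sarcolemmal
sites in SL and dyad, calsequestrin in SR) plus troponin-C occupancy shared
with the contraction model; CaMKII trapped fraction; PKA activity and six
per-substrate phosphorylation fractions; tropomyosin-blocked and weak/strong
crossbridge fractions. Units: mV, ms, mM, µA/µF; fluxes are reported on
the bulk-myoplasm volume basis; active tension in kPa. State ordering is
frozen in `states.STATE_NAMES` (the manifest used by all trace exports).

Ion bookkeeping is exactly conservative by construction: each transmembrane
current deposits its ions into one named compartment with the
capacitance-to-volume factor Acap/(z·F·V), diffusion moves mass between
compartments with volume-ratio corrections, and the stimulus current is
assigned to potassium. The test suite verifies the algebraic identity at
the RHS level and the time-integrated balance over paced beats.

## Key mechanisms

**Hybrid SR release.** A small ICaL-gated release component (activation
driven by the instantaneous dyadic ICaL, with a calcium-dependent recovery
gate) provides early, well-timed release that primes the dyad; the main
calcium-sensitive RyR population is a four-state scheme (rest, open,
Ca-inactivated, refractory) with Ca²⁺-squared activation and an SR-load
factor `kcasr` that accelerates opening and slows inactivation when the SR
is loaded. Release terminates as the SR depletes (load factor collapses)
and the refractory pool recovers slowly (1/kim, hundreds of ms). Above a
free-SR threshold (2.1 mM) a store-overload term adds Ca-independent
opening drive, so an overloaded SR bleeds back toward the threshold; the
stochastic release variant samples discrete initiation events on top of
this mechanism.

**ICaL.** GHK driving force with activity coefficients and Na/K
sub-fluxes; voltage-dependent inactivation (fast/slow), a dyadic-calcium
CDI gate with asymmetric kinetics (fast inactivation during release, slow
recovery), and a slow voltage-dependent recovery gate `jca` whose time
constant sets restitution steepness and paired-pulse refractoriness.

**NCX.** A well-established single-equation exchanger formulation
(3Na:1Ca, allosteric Ca activation, saturating voltage factor), split
between SL and dyad faces; it reverses at V = 3E_Na − 2E_Ca and shifts
toward reverse mode under Na loading. The allosteric activation constant
is set so the exchanger is nearly silent at diastolic Ca but claims ≈20% of
the calcium clearance during the transient decay.

**INaK.** Saturating pump (3Na:2K) with the classic sigmoidal voltage
factor; its Na affinity and scale set the slow Na dynamics.

**Signaling.** CaMKII uses the calmodulin-trapping description driven by
dyadic Ca (targets: INaL gating, ICaL facilitation, SERCA affinity, RyR
sensitivity). The beta-adrenergic arm is a reduced cascade — agonist →
PKA activity → six first-order substrate phosphorylation fractions (ICaL,
IKs, PLB/SERCA, RyR, NaK pump, TnI/crossbridges) — rather than a full
receptor/cyclase/phosphatase network; at saturating agonist the substrate
levels plateau and the modifiers reproduce the calibrated whole-cell
calcium and contraction effects (CaT amplification, faster reuptake,
larger and faster tension — the tension gain needs an explicit
crossbridge-recruitment coupling: PKA speeds tropomyosin unblocking in
addition to crossbridge cycling). The APD response has the wrong sign in
this parameterization (see *Known limitations*). The switch used
throughout the assays is two-level (off/saturating); a graded agonist
mapping is provided.

**Contraction.** Land-type: cooperative troponin-C binding (which doubles
as the dominant cytosolic Ca buffer), tropomyosin blocking, weak→strong
crossbridge cycling; isometric tension ∝ strong-state occupancy with
length-dependent activation (h(λ) and Ca50(λ)). Isometric mode at λ = 1.1
is the default everywhere; the length API exists but only the
length-dependence signs are asserted.

**Sex variants.** The female preset is a multiplier overlay on the male
set (single source of truth): reduced IKr, IKs, Ito, IK1, slightly reduced
SERCA, increased NCX — composed from reported human/animal sex differences
in repolarizing-current densities and calcium handling. The overlay yields
a longer APD, a smaller CaT and peak tension, and steeper S1-S2
restitution. The CaT/tension reduction is larger than the "slight"
difference seen experimentally because SR load in this model is strongly
coupled to APD (see *Known limitations*).

## Numerical choices

* Stiff adaptive integration (LSODA), rtol 1e-7, per-variable atol (1e-9
  concentrations/buffers, 1e-8 gates, 1e-6 voltage); the stimulus window
  (rectangular, 1 ms, −40 µA/µF ≈ 2× diastolic threshold, frozen in the
  parameter set) is integrated as a separate segment so the solver never
  steps across a discontinuity. Output sampling default 0.5 ms (0.1 ms
  where clearance quadrature needs it). Halving both tolerances moves APD90
  by < 0.1 ms (tested).
* AP clamp is implemented as strong relaxation of V onto the waveform
  (τ = 0.05 ms), giving sub-mV tracking except transiently on the upstroke.
* Derived outputs (currents, fluxes, tension) are recomputed from the state
  history through the same RHS, so traces are internally consistent.
* Clearance fractions integrate J_up, forward-mode NCX extrusion and the
  sarcolemmal pump (trapezoid) from the CaT peak to 95% recovery.
* Detector thresholds are config-exposed (`DetectorConfig`): EAD = positive
  dV/dt episode > 100 ms after the upstroke at V > −40 mV before full
  repolarization; DAD = diastolic depolarization ≥ 1 mV above the
  post-repolarization baseline without stimulus; triggered AP = −40 mV
  crossing with regenerative upstroke (never double-counted as a DAD);
  alternans = ΔAPD > 3 ms or ΔCaT amplitude > 5% of the mean over the
  recorded tail. These were chosen here; they are definitions, not fitted
  quantities.
* Restitution slope: maximum centered finite difference of APD90 vs S2 on
  a dense S2 grid after a converged S1 train (default 20 S1 beats from the
  steady-state snapshot).
* Reporting convention for non-period-1 regimes: some regimes (the
  beta-adrenergic-on state at 1 Hz, pacing at 1.5-2 Hz) converge to stable
  period-3 or higher-period orbits rather than a period-1 beat. Scalar
  biomarkers for such regimes are reported as the median over the last six
  recorded beats, i.e. the typical beat of the orbit; the reproduction
  script and the acceptance tests use this convention throughout.

## Calibration targets and procedure

The baseline male cell at 1 Hz was calibrated by Nelder-Mead direct search
over 16 maximal-rate parameters (log-multipliers) against: APD90 ≈ 285 ms,
diastolic Ca ≈ 100 nM, CaT amplitude ≈ 550 nM, CaT time-to-peak ≈ 40 ms,
CaTD90 ≈ 420 ms, diastolic SR Ca ≈ 1.9 mM, NCX share of transient decay
clearance ≈ 20%, with a strong penalty on 1-Hz APD alternans and a weak
regularization toward the hand-built starting point. Signaling coupling
strengths were then calibrated against the beta-adrenergic whole-cell
effects, and the stimulus amplitude was frozen at ≈2× diastolic threshold.
Everything downstream (drug responses, EADs, DADs, alternans, restitution,
population statistics) is emergent, not separately fitted.

## Steady states and shipped snapshots

`run_to_steady_state` paces until the beat-to-beat change of a monitored
subset (diastolic V, bulk Na, diastolic SR Ca, APD90) falls below
tolerance (default 1e-3 relative; 1000-beat default cap), detecting
period-2 orbits by comparing to two beats back and returning both phases
when alternans is present. The package ships end-diastolic snapshots
(JSON, `myocyte/data/`) for the male preset at 0.5–3 Hz, the female preset
at 1 Hz, and the male preset under saturating beta-adrenergic stimulation;
assays and the reproduction script start from these and re-equilibrate for
tens of beats, which keeps protocol runtimes at seconds-to-minutes on one
CPU. Problem sizes used by the shipped reproduction script (re-equilibration
beat counts, S2 grids, population size) are recorded in the script itself.

## What the model does and does not represent

Calcium is averaged per compartment: there is no subcellular spatial
diffusion, no discrete spark/cluster stochasticity (the stochastic-release
variant adds event-level randomness of initiation, not spatial structure),
and no calcium waves. Drug action is pure pore block (conductance
multipliers); there is no state-dependent binding or trapping. Temperature
is fixed at 310 K. Chloride concentrations are fixed parameters. The
beta-adrenergic cascade is reduced (no receptor desensitization kinetics,
no graded substrate-specific EC50 differences). Tissue-level phenomena
(conduction, reentry) are out of scope. Consequently, passing tests show
that the *cellular* mechanisms and their modulation are reproduced; they do
not validate spatial or organ-level arrhythmia dynamics.

## Known limitations

The behaviors this parameterization reproduces quantitatively are the
calcium-clearance partition, the beta-adrenergic calcium/contraction
folds, steep S1-S2 restitution (max slope > 1, flattening at short S1,
steeper in the female variant), pronounced concordant APD/CaT alternans at
240 ms with beta-adrenergic suppression, and the nonmonotonic CaT- and
force-frequency optima. Behaviors it does **not** reproduce, with the
mechanistic reason:

* **Beta-adrenergic APD shortening.** Saturating stimulation prolongs the
  (median) APD by ~28% instead of shortening it by a few percent. The AP
  dome is bistable between a high-plateau and a collapsed attractor; the
  IKs gain saturates against late ICaL regrowth, and every coupling
  combination that shortens the AP tips the state across the bistability
  into a collapsed or alternating orbit. The beta-adrenergic state is a
  period-3 orbit at 1 Hz.
* **Discrete early afterdepolarizations.** Strong IKr block at slow rates
  produces marked AP prolongation (hundreds of ms to seconds) with
  monotonic repolarization, not EAD oscillations: the plateau sits high,
  where the blocked IKr remnant still dominates the window-current zone
  during the descent, and the CDI gate operates below its midpoint at
  plateau dyadic calcium, so the CDI-ICaL feedback loop has no
  oscillatory gain.
* **Deterministic DAD initiation.** SR overload fills the store but
  diastolic release does not self-trigger (quadratic calcium activation
  has negligible loop gain at diastolic dyadic calcium; the SR-load factor
  saturates below the operating range). Given an initiation event — which
  the stochastic store-overload variant supplies — the full DAD and
  triggered-AP phenomenology follows, with SR release accompanying each
  event.
* **Alternans mechanism.** Alternans here is voltage-driven (ICaL
  recovery), so it does not persist under AP clamp and SERCA reduction
  abolishes rather than promotes it; its onset is at 240 ms rather than
  250-260 ms.
* **SR-load rate dependence** peaks at 1 Hz instead of rising monotonically
  to 3 Hz.
* The calcium-transient time to peak (~90 ms) is at the slow end of the
  experimental envelope.
* Sodium equilibrates over many hundreds of beats; snapshots absorb this,
  but very long protocols at high rates drift slowly in Na.
* The female overlay reduces CaT and tension more than the "slightly
  smaller" difference reported experimentally, because SR load is strongly
  APD-coupled in this model.
* Biomarker extractors assume a captured beat; during failed 1:1 capture
  the per-beat APD series contains NaNs and assays flag loss of capture
  rather than interpolating.

The acceptance test suite asserts the target behaviors at their nominal
values; the tests covering the unreproduced behaviors above fail and are
intentionally left failing rather than weakened.
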