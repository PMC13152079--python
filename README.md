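# myocyte

A human ventricular cardiomyocyte simulator for studying cellular
arrhythmia mechanisms.

Cardiac arrhythmias are driven by a small set of cellular behaviors —
early and delayed afterdepolarizations (EADs/DADs), APD and calcium-transient
alternans, and steep restitution of action-potential duration — all of which
emerge from the interplay of membrane currents, intracellular calcium
cycling, sympathetic signaling and contraction. `myocyte` implements a
deterministic ODE model of a single human endocardial myocyte for
researchers who need these mechanisms and their modulation (drug block,
β-adrenergic stimulation, SERCA activity, sex differences) in one coherent,
scriptable cell.

## The model

The cell is divided into four compartments — junctional dyad, subsarcolemmal
space (SL), bulk myoplasm and sarcoplasmic reticulum (SR) — with 50 ODE
states: membrane potential V and Hodgkin–Huxley gates for
I_Na, I_NaL, I_to, I_CaL, I_Kr, I_Ks; Na⁺, K⁺ and Ca²⁺ concentrations with
explicit buffer states; a hybrid SR-release scheme (a small
I_CaL-gated release component priming a calcium-sensitive RyR population
with Ca-induced inactivation, a refractory pool and SR-load-dependent
gating); SERCA uptake and leak; NCX (3Na:1Ca) and the Na/K pump (3Na:2K);
CaMKII (calmodulin-trapping) and a reduced β-adrenergic cascade
(agonist → PKA → per-substrate phosphorylation of I_CaL, I_Ks, PLB/SERCA,
RyR, I_NaK, TnI/crossbridges); and Land-type crossbridge mechanics producing
isometric active tension. Ion bookkeeping is exactly conservative:
dX_total/dt equals the signed sum of transmembrane currents scaled by
A_cap/(zFV), verified to machine precision in the test suite.

Units: mV, ms, mM, µA/µF; tension in kPa. A stiff adaptive solver (LSODA,
rtol 1e-7) integrates the system; ~0.1 s per beat on one CPU core.

An optional stochastic variant samples spontaneous SR-release initiation
events from a store-overload-dependent hazard, for DAD studies that need
beat-to-beat variability.

## A worked example

```
python examples/01_baseline_beat.py
```

prints, for one steady-state beat of the baseline (male endocardial) cell
paced at 1 Hz:

```
APD90               309.6 ms
resting V           -88.8 mV
CaT diastolic        67.9 nM
CaT amplitude       448.1 nM
CaT time-to-peak     91.0 ms
CaTD90              441.4 ms
peak tension         42.2 kPa
SR Ca (diast.)       1.12 mM

cytosolic Ca removal during the transient decay:
  SERCA 79.7%  NCX 20.09%  sarcolemmal Ca pump 0.25%
```

The first block is the standard electrophysiology / calcium / contraction
biomarker set: AP duration at 90% repolarization, the free cytosolic
calcium transient (diastolic level, amplitude, kinetics), peak isometric
tension and the diastolic SR calcium load. The final line partitions
calcium removal during the transient decay between SERCA (refilling the
SR), the Na/Ca exchanger and the sarcolemmal calcium pump (both extruding
calcium from the cell) — the ~80/20/0.25 split characteristic of large
mammals.

Other examples: `02_sympathetic_stimulation.py` (β-adrenergic effects on
CaT, tension and reuptake), `03_arrhythmia_mechanisms.py` (drug-block AP
prolongation, stochastic DADs, alternans, S1-S2 restitution),
`04_population_of_models.py` (population sampling, biomarker calibration,
per-model restitution slopes).

A thin CLI mirrors the assays:

```
myocyte biomarkers --rate 1 --beats 100
myocyte assay restitution
myocyte assay dad --stochastic --trials 10 --seed 3
myocyte drug-panel
myocyte population calibrate --size 20 --seed 1
```

## Library layout

| module | contents |
| --- | --- |
| `myocyte.parameters` | parameter registry, male/female presets, multiplier targets (drug block) |
| `myocyte.model` | stiff pacing engine, `Trace`, steady-state runner |
| `myocyte.currents` / `calcium` / `signaling` / `contraction` | domain views over the compiled right-hand side |
| `myocyte.biomarkers` | APD/CaT/tension metrics, EAD/DAD/alternans detectors, clearance fractions |
| `myocyte.protocols` | drug panel, EAD/DAD/alternans assays, AP clamp, S1-S2 restitution, rate sweep |
| `myocyte.populations` | population sampling, calibration filtering, susceptibility scans |
| `myocyte.stochastic` | stochastic store-overload release variant |
| `myocyte.io` | trace CSV/HDF5 round-trip, run configs, synthetic detector fixtures |

Steady-state snapshots for the shipped presets live in `myocyte/data/` and
are regenerated with `python scripts/make_snapshots.py`.

See `docs/methods.md` for the model description, numerical choices,
calibration procedure, and a frank list of which behaviors this
parameterization does and does not reproduce.

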