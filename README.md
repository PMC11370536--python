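# cohlex

Biochemical reaction-network modelling of interphase cohesin loop extrusion.

In mammalian interphase nuclei, cohesin extrudes chromatin loops under the
control of three transiently binding regulators: NIPBL (loader and extrusion
activator), PDS5 (NIPBL competitor and WAPL recruiter) and WAPL (unloader).
`cohlex` implements a five-state mass-action model of this cycle,

```
FREE  →  RN  ⇌  R  ⇌  RP  ⇌  RW  →  FREE
 load            (regulator exchange)    unload
```

where a loaded cohesin is bare (R) or carries exactly one regulator (RN, RP,
RW), loading requires NIPBL, unloading proceeds from the WAPL-bound state,
and extrusion occurs only while NIPBL-bound. All eight transition rates are
inferred — with no fitting to Hi-C — from six FRAP/abundance numbers per
cell line: copy number, chromatin-bound fraction φ and mean residence time τ
for RAD21 (the cohesin proxy), NIPBL, PDS5 and WAPL. The package is aimed at
chromosome-organization researchers who want to turn such biophysical
measurements into quantitative predictions of extrusion kinetics and 3D
genome folding.

## What it does

* **Topology enumeration and pruning** (`cohlex.network`,
  `cohlex.inference`): enumerate all 24 orderings of the four loaded states
  in an irreversible-load/irreversible-unload cycle, solve the 8-constraint
  linear rate system for each (regulator release flux = bound/τ per species,
  cohesin unloading flux = loaded/τ, stationary flux balance per state),
  discard candidates with non-positive rates, then discard candidates that
  fail the observed directions of the cohesin bound-fraction change under
  90% regulator depletions. A catalogue of alternative topologies
  (regulator excursions, strict PDS5+WAPL co-binding, reversible acyclic
  families) is built in.
* **Kinetics** (`cohlex.kinetics`): nonlinear steady states with shared free
  regulator pools, mass-action ODE integration, mean first-passage residence
  times, per-state transition frequencies, and in silico depletion scans
  with intrinsic rate constants frozen at the wild-type inference.
* **Stochastic engine** (`cohlex.kmc`): discrete-time kinetic Monte Carlo
  for complex ensembles and single binding windows, with exact exponential
  per-step survival.
* **1D lattice extrusion** (`cohlex.lattice`): multi-state extruders on a
  2.5 kb-per-site lattice; only NIPBL-bound extruders translocate, all
  loaded extruders block (collisions without bypass); loop coverage,
  collided fraction and a largest-cluster percolation score.
* **3D polymer model** (`cohlex.polymer`): bead-spring chain (50 nm ≙ 2.5 kb
  per bead, 20% volume fraction, bounded soft repulsion) driven by lattice
  extruder bonds, with an MSD-based calibration of the physical duration of
  one integration step.
* **Observables** (`cohlex.observables`): contact-frequency-versus-distance
  curves P(s), the goodness-of-fit R² = 1 − Σ(P_ref−P)²/Σ(P_ref−P̄_ref)²
  over [50 kb, 10 Mb], and in silico confocal microscopy with a Pearson
  "vermicelli" colocalization score.

## Worked example

```python
from cohlex import (builtin_topologies, solve_rates, solve_steady_state,
                    wild_type_totals, predict_depletion, DepletionSpec,
                    lattice_time_mapping)

rates = solve_rates(builtin_topologies()["five_state"], "hela_wt")
ss = solve_steady_state(rates, wild_type_totals())
print(f"bound fraction        {ss.bound_fraction:.4f}")
print(f"residence time        {ss.residence_time:.1f} s")
print(f"active/loaded ratio   {ss.active_to_loaded_ratio:.4f}")
print(f"lattice step tau_1d   {lattice_time_mapping(ss.active_to_loaded_ratio):.3f} s")

pred = predict_depletion(rates, wild_type_totals(), DepletionSpec({"WAPL": 0.9}))
print(f"90% dWAPL: bound {pred.bound_fraction:.3f}, "
      f"residence fold {pred.residence_time_s / ss.residence_time:.2f}")
```

prints

```
bound fraction        0.6500
residence time        822.0 s
active/loaded ratio   0.2587
lattice step tau_1d   1.294 s
90% dWAPL: bound 0.934, residence fold 9.28
```

i.e. the inferred rates reproduce the wild-type inputs exactly (closure),
~26% of loaded cohesin is actively extruding — which, with the in vitro
extrusion speed of 1 kb/s, fixes the lattice timestep near 1.3 s — and
depleting 90% of WAPL is predicted to raise the chromatin-bound fraction of
cohesin from 0.65 to 0.93 while lengthening its residence time roughly
nine-fold.

The same functionality is exposed on the command line:

```
cohlex prune                      # 24 cycles -> 8 physical -> 1 survivor
cohlex steady-state               # wild-type observables as JSON
cohlex deplete --species PDS5 --levels 0:0.99:0.025 --out scan.csv
cohlex simulate-lattice --sites 10000 --extruders 335 --seed 1
```

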