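# Methods

## Model

Cohesin is treated as a well-mixed chemical species over five states: free
(FREE) and chromatin-loaded with zero or one regulator bound (R, RN, RP,
RW). Under mass action the populations obey

dX/dt = Σ_in k·[source] − Σ_out k·[X],

where first-order steps (regulator unbinding, unloading) have constant
rates and second-order steps (loading, regulator binding, regulator
exchange) have rates proportional to the free nucleoplasmic pool of the
incoming regulator. Exchange steps (e.g. RP → RW) are composite: under the
mutual-exclusivity assumption no co-bound intermediate exists, so the
incoming regulator is consumed and the outgoing one released in a single
second-order event. The strict co-binding variant relaxes exactly this
assumption by introducing an RPW state.

Assumptions inherited from the biology: RAD21 proxies the core complex;
regulators bind only chromatin-loaded cohesin; regulators bind mutually
exclusively (except in the co-binding variant); PDS5A/B are amalgamated;
networks have four loaded states and eight transitions.

## Rate inference

Given per-protein copy number N, bound fraction φ and residence time τ, the
wild-type state populations follow directly from φ·N (each regulator's bound
copies occupy its state; the bare-loaded population is the remainder of
loaded RAD21; a negative remainder is a hard inconsistency error). The eight
rates then solve eight linear constraints:

1. per regulator, release flux = bound population / τ (Little's law; for a
   single-state regulator this is exactly "total exit rate = 1/τ", and it
   generalizes unchanged to the co-binding variant where PDS5 spans two
   states);
2. cohesin unloading flux = loaded population / τ_RAD21 (the stationarity
   identity for the mean binding window);
3. stationary flux balance at every loaded state.

The linear system is solved numerically per topology (the same rational
functions a symbolic solution would give, evaluated in floating point); a
rate ≤ 1e−12 s⁻¹ counts as unphysical to guard against sign flips from
floating-point cancellation. Intrinsic second-order constants are effective
rates divided by the wild-type free pool.

For the five-state cycle and the builtin table the rates are, in s⁻¹ at the
wild-type state: load 2.259e−3, RN→R 1.389e−2, R→RN 1.331e−2, R→RP
2.471e−2, RP→R 7.435e−3, RP→RW 6.850e−3, RW→RP 1.305e−2, unload 9.176e−3.

## Pruning

Stage 1 keeps topologies whose eight rates are all strictly positive (8 of
the 24 cycle orderings for the builtin table). Stage 2 freezes the intrinsic
constants, rescales one regulator total by (1 − depletion), re-solves the
nonlinear steady state and demands the experimentally observed directions of
the cohesin bound-fraction change: down for ΔNIPBL, up for ΔPDS5 and ΔWAPL.
The depletion level defaults to 0.9, matching RNAi efficiencies; one cycle
survives (FREE→RN⇌R⇌RP⇌RW→FREE). The model computes a *decrease* of the
per-extruder extrusion rate under ΔNIPBL (0.50× at 90%), consistent with the
reduced ATP-hydrolysis activity seen when NIPBL is scarce.

## Steady states and depletions

With free pools given, the state chain is linear and its stationary
distribution is one 5×5 linear solve; the free pools in turn follow from
conservation. The solver iterates this pair with damped fixed-point updates
(initial damping 0.5, halved on overshoot) to a population tolerance of
1e−12 relative, polishes with one exact solve, and verifies that the maximal
net flux per state is below 1e−10 of throughput; a bounded least-squares
root finder on the three free pools is the fallback. Depletions rescale
species totals with intrinsic rates frozen; all nonlinearity of the response
enters through free-pool re-equilibration. Fold changes are reported against
the wild type of the same topology.

The mean binding window is computed both as loaded population over unloading
flux and as the mean first-passage time from the loading entry state to
FREE (linear solve over the loaded subnetwork); the two agree to 1e−8 at
stationarity and the test suite asserts this identity.

Predicted depletion responses of the five-state model (from the builtin
table): 90% ΔWAPL raises the bound fraction by 43.6% and the residence time
9.3-fold; 90% ΔPDS5 raises them by 16.4% and 2.74-fold; 60% ΔNIPBL lowers
the bound fraction by 40%. The per-state entry frequency into RN, evaluated
from entry flux per binding window over the residence time, is 0.216 per
minute; this flux-based value is reported as computed and is somewhat below
rounded literature statements of ~0.3 per minute, which we do not tune
toward.

## Stochastic engine

The discrete-time KMC uses the exact per-step exit probability
1 − exp(−k_tot τ), partitioned proportionally to the outgoing rates, which
removes the O(k τ) bias of the linearized scheme; the timestep is rejected
at construction if any state's exit probability exceeds 0.1. Default
coupling freezes effective rates at the deterministic steady state of the
simulated condition ("rates homogeneous across complexes"); the shared-pool
coupling recomputes free pools from the ensemble each step and is the
correct comparison for equilibration transients from a fully unloaded
population, where pools differ strongly from their stationary values. One
seeded generator drives a run; identical seeds give bitwise identical event
logs.

## Lattice model

Sites are l = 2.5 kb; an extruder occupies two sites. Per step: (i) a KMC
biochemical update per extruder — loading places both legs on a uniformly
chosen free adjacent pair (rejection sampling from uniform site draws, up to
64 tries, deferred to the next step if crowded); (ii) every leg of every
RN-state extruder advances one site outward iff the target site is free.
Legs move independently in a fresh random permutation each step (removes
directional bias); non-RN loaded extruders block but do not move; chains
have reflecting ends (a ring boundary is available for finite-size studies).
The physical step is τ_1d = 2 l · ([RN]/[R]loaded) / v with the in vitro
speed v = 1 kb/s, giving 1.29 s at the wild-type ratio of 25.9%.

The percolation score builds clusters (union-find) over the relation "a leg
occupies a site adjacent to another extruder's leg" and reports the largest
cluster size over the loaded count. In scaled-down systems the score is
bounded by the largest single chain, so percolation scans use one chain.

## Polymer model

One lattice site ↔ one bead of b = 50 nm. Forces: harmonic backbone and
extruder bonds (stiffness 20 kT/b², rest length b — the extruder-bond
constants are not independently constrained, so they match the backbone),
and a bounded polynomial repulsion U = A(1 − (r/r_c)²)³ for r < r_c with
A = 6 kT, r_c = b, which keeps chain crossings rare but possible, as
appropriate at 2.5 kb resolution. The chain lives in a periodic cube sized
to a 20% bead volume fraction. Integration is overdamped Brownian dynamics
with dimensionless step 0.005; the deterministic drift (not the noise) is
clamped at 0.35 b per step purely as a blow-up guard. The friction default
(0.27 in kT·step/b² units) is a mobility calibration: it places the
free-chain Rouse MSD coefficient near 0.3 b² per √step so that matching the
experimental chromatin diffusion law D ≈ 0.01 µm²/s^0.5 dates one
integration step at ≈ 5 ms, hence ≈ 250 integration steps per 1.25 s lattice
step. `calibrate_time` performs this inversion from any measured MSD curve,
pinning the exponent at the reference value (0.5 Rouse, or 0.675 for the
short-time super-Rousean regime under extrusion) and warning if the freely
fitted exponent deviates by more than 0.15.

Extruder bonds are refreshed from the lattice trajectory every
`steps_per_lattice_update` steps (desk-scale default 25–50; 250 at the
calibrated production coupling).

## Observables

P(s): monomer pairs within R_c = 2.3 b ≈ 115 nm (the typical Hi-C capture
radius) count as contacts; probabilities are normalized per valid pair per
log-spaced separation bin, so system size cancels to leading order. The
goodness of fit R² = 1 − Σ(P_ref − P)²/Σ(P_ref − P̄_ref)² is evaluated on
the reference grid over [50 kb, 10 Mb] (4950 log-spaced bins for
full-scale comparisons), with the model interpolated in log-log space; the
resampling rule is this package's choice, as comparisons to 10 kb-binned
reference curves need one.

In silico microscopy: 100 nm voxels, 50 per axis (5 µm field), Gaussian PSF
σ = 250 nm. The DNA channel rasterizes all monomers; the cohesin channel
rasterizes loaded-extruder midpoints (midpoint rather than both legs, to
avoid double counting) plus uniformly placed diffusive cohesins matching the
unloaded population of the condition. No intensity threshold is applied
before the Pearson correlation. The score averages over frames;
diffusive-placement randomness is seeded.

## Scaled-down study conditions

Production conditions are ~6,700 extruders on 200,000 sites (500 Mb) with
5,000 conformations. The test-suite and acceptance runs use proportional
subsystems at the same per-site extruder density — 1/20 scale (10,000
sites, 335 extruders) for the density measurement; 7.5 Mb with 100
extruders for coupled morphology ensembles; 15,000 lattice steps with 3,000
steps burn-in for time averages (the loading autocorrelation time is ~640
steps, so this yields ~15 effective samples) — sizes chosen so each
simulation finishes in seconds to a minute on one core. Intensive
quantities (per-Mb density, occupancies, P(s) shape, score directions)
transfer across scale; absolute P(s) shoulder positions and the small
ΔPDS5 vermicelli enhancement are at the edge of resolution at these sizes,
so tests assert directions and separations rather than production-scale
magnitudes, and the ΔPDS5 vermicelli check asserts membership in the
vermicelli-forming group rather than strict exceedance of wild type.

## What the synthetic generators do and do not emulate

`fixtures.random_rateset` draws log-uniform intrinsic rates bracketing the
measured regime and is used for forward-inverse round trips (rates → steady
state → synthetic measurement table → recovered rates, agreement < 1e−8
relative) and ODE-endpoint checks; it does not emulate measurement noise —
uncertainty propagation from FRAP error bars is out of scope. The lattice
and polymer generators emulate homogeneous loading and uniform rates only:
no CTCF barriers, no locus-specific loading, no transcription coupling, no
sister-chromatid cohesion. Passing tests therefore validate the kinetic and
structural machinery under the model's own assumptions, not the fidelity of
those assumptions to any particular locus.

## Known limitations

* The nonlinear depletion responses are exact for the model but compared
  against rounded literature statements; the model's 90% ΔPDS5 residence
  fold is 2.74, above the commonly quoted "two-fold".
* The Brownian-dynamics thermostat reproduces equilibrium structure and
  long-time scaling, not hydrodynamics or the short-time inertial dynamics
  of the DPD scheme it stands in for; the time mapping absorbs the mobility
  difference.
* Desk-scale polymer ensembles (≤ 10 Mb) truncate the P(s) shoulder near
  the chain length; quantitative R² > 0.99 comparisons require full-scale
  ensembles and an external reference curve (supported via CSV import, not
  shipped).
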