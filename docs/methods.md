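# Methods

## Model

Lipids are represented at MARTINI resolution (~4 heavy atoms per bead).
POPC is 12 beads: a charged choline bead (Q0, +1 e), a charged phosphate
bead (Qa, −1 e), two glycerol beads (Na), and two 4-bead hydrocarbon
tails; the palmitoyl tail is four saturated C1 beads, the oleoyl tail
carries one unsaturated C3 bead with a kinked (120°) angle term. The
ISUCA-derived lipids replace the phosphocholine head with a 3-bead
imidazole ring (one SC4 and two SP1 ring beads bonded in a triangle) over
the same glycerol/tail scaffold, 13 beads total, in three tail variants:
di-palmitoyl ("2 Pal"), di-oleoyl ("2 Ol"), and mixed ("Pal-Ol").
Protonation — the membrane's pH response — switches the protonatable ring
bead to a charged SQd type carrying +1 e; the species is otherwise
unchanged. Water is a single P4 bead standing for four real water
molecules; 30% of solvent beads are BP4 antifreeze particles, which
interact with water at a larger sigma to frustrate the artificial
crystallization of the 4:1 mapped solvent. The Cl⁻ counterion is a single
charged Qa-type particle.

All interaction parameters are config data, never code. The bundled
`data/martini_cg.yaml` uses the MARTINI v2 interaction-level ladder
(epsilon from 5.6 down to 2.0 kJ/mol on sigma 4.7 Å, with the oversized
super-repulsive level at 6.2 Å and reduced 4.3 Å / 75% wells for
ring-ring pairs). The matrix is a best-effort transcription restricted to
the bead alphabet used here. The bonded terms of the imidazole headgroup
(ring bonds, ring-glycerol linkage) are **placeholders** flagged
`supplementary_required: true`; they are plausible (stiff short ring
bonds, standard linker angles) but should be replaced with values
parameterized against atomistic simulations before any production use.
The loader expands aliases and ring rules into a complete explicit
symmetric pair matrix at load time; a missing pair is an error, never a
silent default.

## System construction

Bilayers are assembled directly in the bilayer state (self-assembly would
cost far more simulation time than the measurements themselves): each
leaflet is a jittered square lattice, species shuffled over sites by the
seeded RNG, heads outward and tails zig-zagging toward the midplane,
mirror-symmetric counts across leaflets. Solvent fills the two slabs
above and below on an adaptively densified jittered grid (exact bead
count, ≥3.5 Å spacing, ≥3.2 Å clearance from lipids); counterions replace
randomly chosen plain water beads one-for-one, so bead bookkeeping stays
exact. The nine study systems are registered by name with their
compositions and box dimensions; the pure-POPC lateral box is
62.4 × 62.4 Å with a 90 Å normal. Identical seeds reproduce identical
configurations bit for bit.

## Engine

Velocity-Verlet integration in an orthorhombic periodic box, internal
units Å / ps / amu / kJ/mol. Nonbonded terms: Lennard-Jones 12-6 with the
*potential* shifted to zero at the 12.5 Å cutoff (forces are left
untruncated below the cutoff, so the potential is continuous and the
residual force step at the cutoff is part of the documented integration
noise); harmonic bonds `k/2 (r−r0)²`; cosine-harmonic angles
`k/2 (cosθ−cosθ0)²`; first and second bonded neighbors are excluded from
nonbonded interactions. Electrostatics use classic (non-mesh) Ewald
summation with tinfoil boundaries, relative dielectric 15, splitting
parameter and k-space extent chosen from a target accuracy (default
1e-4); excluded intramolecular pairs are corrected with the erf term. The
neighbor list is a periodic k-d tree with a 2 Å Verlet skin, rebuilt when
any displacement exceeds half the skin.

Temperature control is a Nosé–Hoover thermostat (single chain, coupling
time 1 ps, the standard practical realization of the extended-system
thermostat family). Pressure control is weak-coupling box rescaling,
semi-isotropic by default — the lateral plane couples as one degree of
freedom and the normal independently, which is what lets the area per
lipid equilibrate; an extended-system piston was rejected because its
usual formulation is isotropic-only and bilayers require the
semi-isotropic mode. Per-step scale factors are clamped at 2% for
stability. The instantaneous pressure tensor is kinetic plus pairwise
virial (angle terms decomposed over their two arms; the reciprocal-space
Ewald virial uses the standard k-space tensor).

Because coarse-grained dynamics run on a smoothed energy landscape,
trajectory times are conventionally multiplied by an effective-time
factor of 4 before any time-dependent quantity is reported; the factor is
carried by the trajectory object and applied in the diffusion fit, so
doubling it halves D by construction.

Energy minimization wraps L-BFGS over bead coordinates (gradient = −force)
and never returns a configuration with higher energy than its input; it
is guarded by a descent test and a brute-force grid oracle on the
Lennard-Jones trimer.

## Analysis

* **APL**: per-frame `Lx·Ly / N_leaflet`; defined by division (a lateral
  area divided by a per-leaflet count), which reproduces the 67 Å² worked
  example for a 62.4 Å box with 58 lipids.
* **Leaflets**: a lipid belongs to the side of the bilayer midplane (mean
  z of all lipid beads) its head beads sit on, re-evaluated per frame;
  stable for non-flipping membranes.
* **Hydrophobic thickness**: distance between the mean C1 planes of the
  two leaflets. This operationalizes a quantity usually drawn only
  schematically; a density-profile oracle (half-max edges of the tail-bead
  z histogram) agrees within 1 Å on synthetic bilayers and guards the
  choice.
* **P2**: exact sample mean of `(3cos²θ−1)/2`; per-bond (c1-c2, c2-c3,
  c3-c4) and end-to-end (C1→C4) variants grouped by species and chain
  kind. Verified against naive double-loop oracles to 1e-12.
* **MSD/D**: lipid centers of mass, unwrapped by nearest-image continuity
  (valid while no bead moves more than half a box length between frames),
  per-leaflet COM drift removed and the MSD rescaled by M/(M−1) so that
  independent walkers stay unbiased. Lags run to a quarter of the
  trajectory — the variance of a time-origin-averaged MSD grows roughly
  linearly with lag, so longer lags add noise, not information. The slope
  is fitted over the 10–50% window of the maximal lag by weighted least
  squares (weights ∝ number of independent intervals per lag), divided
  by 4, and converted with 1 Å²/ns = 1e-7 cm²/s. Uncertainty is the WLS
  slope error; APL/thickness uncertainties are the frame SD plus a
  5-block standard error of the mean.

## Synthetic data

The generator emulates exactly the features the analysis measures and
nothing else: C1 planes at ±thickness/2; box area = APL × lipids per
leaflet; tail bonds at fixed polar tilts with a per-tail uniform random
azimuth (so per-bond P2 equals its closed form exactly, and the C1→C4 P2
follows in closed form from the planar vector sum); independent 2-D
Gaussian walks (variance 2DΔt per axis) for the lipid centers; times
generated directly on the effective clock. It deliberately omits
inter-lipid correlations, undulations, protrusions, solvent and any
coupling between order and diffusion — so the closure tests certify the
*analysis machinery*, not the realism of the force field. Passing them
says the pipeline measures what it claims on data whose truth is known;
it says nothing about how well the placeholder ISUCA parameters reproduce
a real membrane.

## Numerical choices and problem sizes

The test suite and the acceptance script run desk-scale problems chosen
as the package's own verification sizes: 64-bead Lennard-Jones gases for
conservation checks (3000/6000 steps for the step-halving drift oracle),
a 500-bead toy for thermostat accuracy (310 K within 2% over the
production half), a 216-bead super-dilute lattice gas for the ideal-gas
pressure identity, a two-charge cell against a brute-force lattice sum
for Ewald (the direct spherical-image sum converges to the
vacuum-boundary energy, which exceeds the tinfoil result by
2π|M|²/(3V) — the comparison accounts for this exactly), and
58-lipid-per-leaflet / 2000-frame synthetic ensembles for the metric
closures. Full production protocols (microsecond effective times on the
116-lipid systems) are supported by the same code paths but are
multi-hour runs; `examples/reduced_popc_run.py` provides a reduced
version whose expected outcome is the experimental APL bracket 62–68 Å²
and a fluid-phase D of order 1e-7 cm²/s.

## Known limitations

* The ISUCA headgroup bonded parameters are placeholders; quantitative
  structural predictions for the ISUCA species await the parameterized
  values (drop-in replacement in the YAML config).
* The nonbonded matrix is a transcription of the published level table,
  not a validated re-derivation; trajectory-level agreement with any
  specific production code is not expected — correctness is established
  at the property level (conservation laws, limits, closures).
* Orthorhombic boxes only; no bond constraints or virtual sites; the
  bilayer normal is fixed to z (no tilt correction, planar membranes
  only).
* Leaflet assignment assumes no lipid flips; wrapped-coordinate analysis
  assumes the bilayer does not straddle the periodic z boundary (the
  builder centers it).
* Weak-coupling pressure control does not sample a rigorous isothermal-
  isobaric ensemble; for the relaxation-type runs here that trade-off is
  acceptable and conventional.
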