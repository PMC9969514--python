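# Methods

## Model and units

The model is a bead-level DPD representation of alkyl ethoxylate
surfactants in water, parameterised at 25 °C only (the repulsion
amplitudes encode solubilities at that temperature; nothing in the model
responds correctly to changing k_BT, so the temperature is not a dial).
Reduced units: bead mass 1, k_BT = 1, r_c = 1.  The physical length scale
follows from the water mapping — two H2O per bead, pure water at
rho r_c^3 = 3 — giving N_A r_c^3 = 0.108 L/mol and r_c = 5.64 A.  One DPD
time unit tau = 100 steps at the standard dt = 0.01.

Interactions:

- Soft repulsion, U = (A_ij R_ij/2)(1 - r/R_ij)^2, i.e. force
  F = A_ij(1 - r/R_ij).  Some sources write the prefactor without the 1/2;
  we use the force convention above because it is the one consistent with
  the model's own pressure anchor (a pure water box at rho=3, A=25 measures
  P = 23.7, which is also the NPT set point).  Cross cutoffs follow
  R_ij = (R_ii + R_jj)/2 exactly; the shipped table is validated against
  the rule on load.
- Harmonic bonds with r_0 = 0.1(n_i + n_j) - 0.01 (heavy atoms n per bead)
  and k_b = 150.  The engine's default bond energy is U = (k_b/2)(r-r_0)^2
  — the convention of the major mesoscale engines' "harm" bond style.  The
  empirical anchors decide: with this convention an equilibrium surfactant
  solution gives mean bonded separations 0.456 (alkyl-alkyl) and 0.63
  (ether-ether) against the reference 0.45/0.66, while the literal
  k_b(r-r_0)^2 form gives 0.43/0.60 and misses the ether anchor.  The
  literal form remains available (`bond_half_factor=False`).  Note the
  realized lengths exceed r_0 because the nonbonded repulsion is retained
  between bonded beads.
- Harmonic angles U = (k_a/2)(theta - theta_0)^2 with theta in radians and
  k_a in energy/rad^2; the table stores degrees and converts.  The core
  angle table covers the six triplets occurring in CnEm chains with m >= 3.
  Parameterised solutes (octanol, diethyl ether, 2-hexyloxyethanol) and
  short heads (m = 1, 2) contain triplets outside that table; the data file
  carries a clearly separated `angle_extensions` block in which each such
  triplet mirrors its closest terminal-analog core entry (e.g. CC-CC-OH
  uses the CC-CC-E parameters).  Strict lookups can exclude the extensions,
  in which case those species fail loudly at build time.

Solute fragmentations (heavy-atom conserving, unit-tested): octanol =
CH3 + 3xCH2CH2 + CH2OH; diglyme = 3xCH2OCH2; diethyl ether =
CH3 + CH2OCH2 + CH3; 2-hexyloxyethanol = CH3 + 2xCH2CH2 + CH2OCH2 + CH2OH.

The CnEm bead sequence is CH3, (CH2CH2)x(n/2-1), (CH2OCH2)x(m-1), CH2OH
(n/2 + m beads).  This mapping under-counts the ethoxylate block's heavy
atoms by one C2H4O relative to the real molecule; weight fractions are
therefore computed from the true molecular formula C_{n+2m}H_{2(n+2m)+2}O_{m+1}
(wt % axes are experimental, chemical quantities), never from bead counts.
A water bead weighs 36.03 g/mol.

## Dynamics

Pairwise thermostat: dissipative force -gamma w_D(r)(e.v_ij)e and random
force sigma w_R(r) zeta e with w_D = w_R^2, w_R = 1 - r/r_d,
sigma^2 = 2 gamma k_BT, gamma = 4.5, and a single global cutoff
r_d = max R_ii = 1.1160.  zeta is a uniform zero-mean unit-variance
variate from a counter-based hash keyed on (seed, step, i, j), so the same
number is seen by both partners and rebuilding the pair list in any order
reproduces the trajectory bit-for-bit.

Integrator: Shardlow-style splitting.  Each step first applies the
pairwise stochastic update — an explicit then an implicit half-step of the
relative-velocity Ornstein-Uhlenbeck process sharing one random number,
which makes the per-pair stationary kinetic variance exact for any dt —
then ordinary velocity Verlet for the conservative, bonded and angular
forces.  A velocity-Verlet variant with dissipative-force recomputation
was implemented first and measured; it showed an O(gamma dt) temperature
bias (about -1.5 % at the standard parameters) traceable to the splitting
of the random impulse across half-kicks, and the splitting scheme replaced
it.  Measured anchors at dt = 0.01: ideal DPD gas kT = 0.996, interacting
water kT = 1.000, P = 23.65.

Neighbour search: linked cells with a half stencil at the global cutoff
(1.116), falling back to an O(n^2) double loop when fewer than three cells
fit along an axis; both paths are verified against a brute-force oracle to
1e-10.  Minimum image throughout (valid because the cutoff is always below
half the box).

Pressure estimator: P = (2 KE + sum r_ij . F_ij)/(3V) with the virial
restricted to conservative, bond and angle forces.  Dissipative and random
contributions are excluded; whether the reference estimator includes them
is not documented upstream, and the pure-water anchor (23.7 at rho=3)
is met without them.

Constant pressure: isotropic Langevin piston on the box volume,
W dV'/dt = (P - P0) - gamma_p W V' + noise with noise variance
2 gamma_p k_BT dt / W, positions scaled affinely, velocities untouched (so
momentum conservation is exact).  Piston mass defaults to W = K/(V omega^2)
with a water-like bulk-modulus guess K = 45 and omega = 2 pi / (5 tau),
friction gamma_p = 2 omega — near-critical damping of volume relaxation;
both are recorded in run metadata and configurable.  A pure-water box at
P = 23.7 relaxes to rho = 3.00 +/- 0.02.

Initial configurations are ideal-gas random (molecules grown as random
walks at the nominal bond length); the soft potentials tolerate overlaps,
so no insertion machinery is needed.

## Analysis

Mesophase order parameter: hydrophobic beads (CH3, CH2CH2) are deposited
cloud-in-cell on a periodic grid (target spacing 0.25 r_c, actual spacing
snapped to divide the box), smeared with a wrapped Gaussian of sigma = 0.4
r_c, and triangulated with marching cubes on the wrap-padded grid.  The
order tensor M is the facet-area-weighted average of n n^T; tr M = 1 by
construction.  The isosurface level defaults to half the bulk in-aggregate
density, estimated as the modal field value among cells above the global
mean — the upstream analysis level is undocumented, so the level is a
config value and the eigenvalues are insensitive to it on clean structures.
Eigenvalues are monitored per frame and as running averages over a 100-tau
window (raw series are noisy: mesophases undulate and bridge).

Classification is deliberately soft (hard eigenvalue cutoffs do not
survive undulating, imperfect mesophases): lamellar when mu_3 >= 0.75 and
mu_2 <= 0.15; hexagonal when mu_1 <= 0.18 and mu_2 ~ mu_3 >= 0.3; when all
three eigenvalues agree within 0.12 the call is decided by aggregate
evidence — a single space-filling aggregate reads as concentrated
isotropic (L1 high), many small aggregates read as I1 when the micelle
centroids' structure factor has a sharp peak (score = tallest off-zero
peak / N_mic, threshold 0.5; FCC fixtures score ~0.99, random ~0.34) and
as dilute L1 otherwise; anything else is transitional.  Aggregate shapes
come from gyration-tensor eigenvalue ratios (rod when l3/l2 >= 4, slab
when l2/l1 >= 4).  All thresholds are config values; every call carries
its evidence so a human can override, which mirrors how such assignments
are made in practice.  Classification refuses unequilibrated series
(running-average drift test).

Micelles: two molecules aggregate when any pair of their hydrophobic
beads is within r_cl = 1.0 r_c (configurable; the upstream criterion's
cutoff is not restated there), transitively closed.  Clustering equals an
O(n^2) union-find oracle on every tested configuration.  N_cut = 6
separates free surfactant from micelles.  The CMC is the mean free
surfactant weight percent over the steady-state window; steadiness is
detected from non-overlapping 1e4-tau block averages (drift test across
the tail, then first block within 3 standard errors of the tail mean), and
the error is a block bootstrap.

Log P: an elongated box (aspect >= 2) of water + octanol + a small solute
load; per frame, the octanol-bead density profile along the long axis is
thresholded at the midpoint of its two plateaus, a 2 r_c buffer on each
side of the interfaces is excluded from both phases, and
log P = log10(c_oct/c_wat) with c = solute molecules per phase volume
(molarity; the ratio is what matters).  A phase with zero observations
over the whole window yields a bound, not a number.  Water as a solute is
a special case: the tracer is indistinguishable from the solvent, so the
estimate uses the total water concentration in each phase.

## Synthetic fixtures

The generators produce the ideal limits of the phase taxonomy (flat
bilayer stacks, cylinders on a hexagonal lattice, identical spherical
micelles on FCC or random positions), pre-demixed biphasic boxes, and
small reference systems (pure water; a single bonded pair/trimer immersed
in a water bath so the pairwise thermostat can thermalize every degree of
freedom — an isolated dimer conserves angular momentum and would not
sample the Boltzmann bond distribution).  All fixtures hit rho r_c^3 = 3
within 1 % and are bit-reproducible from (spec, seed).  They emulate
geometry, not thermodynamics: passing the classifier on them shows the
order parameter and decision logic are correct, not that the force field
stabilises those phases — that is what the (cluster-scale) phase-map
experiments are for.

## Problem sizes and scope of the shipped checks

The desk-scale suite uses ~200-3000-bead boxes and 1e4-2.4e4-step runs:
large enough that the water pressure (23.7 +/- 0.3), thermostat (kT within
2 %), bond-length anchors (0.45/0.66) and Boltzmann distribution tests
(KS < 0.02 against quadrature at 1e4 samples) are sharp, small enough to
run in minutes.  The production protocols — 81000-bead phase maps for
>= 2e5 tau with 10-wt%-grid-plus-midpoint refinement, CMC boxes built as
4 x the experimental aggregation number of molecules (~7e5 beads for C8E4)
for >= 4e5 tau, and long biphasic log P runs — are encoded with their
expected outcomes in `scripts/experiments.py` and a scaled-down smoke
variant in `scripts/phase_smoke.py`; they are compute-scale experiments,
not tests.

## Known limitations

- 25 °C only; no clouding/temperature physics by construction.
- No electrostatics and no many-body (density-dependent) DPD; the model is
  known to produce spurious micellar-cubic (I1) windows for some long-head
  surfactants that such extensions might cure.
- The gyroid/bicontinuous V1 region is not resolved: the classifier
  reports transitional behaviour between H1 and L_alpha rather than
  pretending to identify V1 or perforated-lamellar structures.
- Aggregation numbers from boxes with a few hundred surfactants
  underestimate experimental N_agg (heavy tails of the size distribution
  are not sampled); CMCs are robust much earlier than N_agg.
- The Langevin-piston parameters are heuristics tuned for water-like
  compressibility; unusual compositions may need a heavier piston.
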