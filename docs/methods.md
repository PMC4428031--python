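# Methods

## Model

`rodcoil` simulates dilute mixtures of amphiphilic rod-coil diblock
copolymers (R_mC_n) and rigid homopolymers (R_x) with a coarse-grained
bead-spring model in reduced units: bead diameter sigma = 1, bead mass
m = 1, k_B = 1.  Solvent is implicit; solvophobicity is encoded in the
nonbonded interactions.

**Bonded terms.**  Bond stretching is harmonic, U_b = (1/2) k_b (r − r0)²,
with k_b = 10⁴ for all bonds, r0 = 0.75 sigma for R–R bonds and 1.0 sigma
for C–C bonds and the R–C junction (the junction is treated as belonging to
the flexible side).  Bending is cosine-harmonic on every triple of
consecutive R beads, U_a = (1/2) k_a (cos θ − cos θ0)², with k_a = 10⁴ and
θ0 = 0.1° (θ is the angle between consecutive bond vectors; θ0 is kept
slightly nonzero so the gradient is defined at perfect alignment).  Coils
carry no bending term and no angle spans the R–C junction.  Both harmonic
prefactors use the 1/2 convention; at k = 10⁴ the observables are
insensitive to the factor-of-two convention, and both prefactors are
configurable.

Note that the cosine-harmonic form is *quartic* around θ0 ≈ 0: joint
angles fluctuate by ~9° at T = 3 even with k_a = 10⁴, so "rigid" rods are
in fact slightly flexible — a 20-bead homopolymer's end-to-end distance
averages ~96% of its straight contour.  This is a property of the model,
not an artifact; the analysis layer offers piecewise subaxes for exactly
this reason.

**Nonbonded terms.**  All bead pairs except directly bonded (1–2) ones
interact through the 12:6 Lennard-Jones potential with sigma = 1 and
pair-class cutoffs: C–C and R–C are truncated at 2^(1/6) sigma and shifted
to zero there (WCA, purely repulsive, epsilon = 1), while R–R keeps the
attractive tail to 2.5 sigma and is plainly truncated, so the well depth
equals eps_RR exactly.  eps_RR is the control parameter of the phase
behavior (experimentally it plays the role of inverse temperature for
polypeptide mixtures whose coil solubility drops on heating).  The
truncation discontinuity at 2.5 sigma is −0.016 eps_RR and is tolerated
under the thermostat.  1–3 pairs do interact; at r0 = 0.75 the 1–3
distance (1.5 sigma) lies inside the R–R cutoff, which contributes a
constant cohesive background along rods.

## Dynamics

Beads follow underdamped Langevin dynamics, m dv/dt = F − Γ0 v + W(t),
with the noise tied to Γ0 and T by the fluctuation-dissipation relation.
Defaults: dt = 0.004, T = 3.0, Γ0 = 1.0 (Γ0 is not dictated by the model
definition; equilibrium structure, the quantity of interest, is
independent of it).  The integrator is the BAOAB splitting with the
Ornstein-Uhlenbeck substep solved exactly; it keeps configurational and
kinetic averages accurate at ω dt = dt·sqrt(k_b/m) = 0.4, and the runner
warns above ω dt = 0.5.  An inertialess Euler-Maruyama scheme
(`scheme="overdamped"`) is available; it requires dt ≪ Γ0/k for stiff
springs and is intended for soft test systems.

Neighbor search uses a linked-cell build of a Verlet pair list with a
0.4 sigma skin, rebuilt when any bead has moved more than half the skin;
the cell grid is capped near N^(1/3) cells per side so dilute systems in
very large boxes do not pay for empty cells.  Periodic boundaries with
minimum image throughout.  Every source of randomness flows from a single
integer seed (initial packing jitter, Maxwell-Boltzmann velocities,
thermostat noise), and trajectories are bitwise reproducible for a fixed
seed on a fixed software stack.  A runaway guard raises an explicit error
if coordinates go non-finite or the kinetic temperature exceeds 10⁴ T.

Production conditions are 660 R7C3 + 4 R150 chains (7200 beads, number
density 0.0021) in a 150³ box for 5×10⁶ steps (20000 time units); desk
defaults are smaller (see below).

## Initial configurations

`build_mixture` places homopolymers as straight parallel rods through the
box center on a 1-sigma square lattice (the bundle template) and
copolymers as straight chains parallel to the bundle on concentric
2-sigma lattice shells, stacked in z layers, with 0.05 sigma seeded
jitter; velocities are Maxwell-Boltzmann.  All bonds start at their rest
lengths (within 10⁻⁶) and all angles straight (within 10⁻³ rad), and no
pair is closer than 0.75 sigma; violations raise a packing error naming
the density.  Whether copolymers start parallel or random relative to the
bundle is not dictated by the model; parallel is the default and the
relaxation time to forget the initial condition is the reason the
production runs are long.

## Structure analysis

* **Clusters / unimers.**  Chains are linked single-linkage when any of
  their hydrophobic (R) beads approach within 1.5 sigma under minimum
  image; coil coronas are ignored.  The unimer fraction counts copolymer
  chains in singleton clusters (homopolymers excluded from numerator and
  denominator).
* **Bundle axis.**  Principal direction of the homopolymer beads
  (chain-unwrapped, centroid-aligned across images); optionally split
  into 2–3 piecewise subaxes over equal axial intervals for slightly
  flexible fibers.  Rod-block centers are re-imaged to the periodic image
  nearest the axis before any axial/azimuthal coordinate is computed.
* **Order parameter.**  S = max over directors d of
  ⟨(3 (u_i·d)² − 1)/2⟩ over rod-block unit vectors u_i.  The maximizer is
  the leading eigenvector of the Q-tensor (3/2)⟨u u⟩ − (1/2)I, so S is
  computed by eigen-decomposition; equivalence with a brute-force
  director grid search is property-tested.
* **Twist profile and P2.**  cos θ_i = u_i·u_d against the axial position
  of each rod-block center, binned at 1 sigma (bead resolution).  A
  sinusoid A cos(2π z / P + φ) + c is fitted by a period scan plus local
  refinement; P2 is the period.  The estimate is *indeterminate* (not a
  number) when the profile spans less than one period, has amplitude
  below 0.2, or fit R² below 0.4.
* **Screw pitch P1.**  Azimuthal phase φ_j of rod centers about the axis
  is modeled as φ = k z + φ0; k maximizes the helical order function
  H(k) = |⟨exp i(φ_j − k z_j)⟩| over both handednesses, and
  P1 = 2π/|k|.  H ∈ [0, 1] doubles as fit quality (threshold 0.5);
  degenerate geometries (rods on the axis, axial span < 4 sigma, no
  coherent winding) are indeterminate.  Only |P1| is reported: the model
  is achiral, so left- and right-handed helices occur with equal
  probability.
* **Morphology label.**  Ordered rules with declared thresholds
  (`ClassifierConfig`): unimers if the unimer fraction exceeds 0.9;
  abacus if the axial density of aggregated rod centers segments into
  ≥ 3 discrete disks (contiguous occupied blobs holding ≥ 4 rods each,
  single-bin holes bridged) whose inter-disk gaps carry < 10% of the
  in-disk density, with at most 30% of copolymers free (disks absorb the
  chains); helix if P1 is determinate with quality ≥ 0.5 and at most 30%
  of copolymers are free (a sparsely coated fiber shedding many free
  chains is a plain fiber even when its coating admits a winding fit);
  plain fiber otherwise.  These operational rules are this package's
  contribution; the reference phase behavior was classified by visual
  inspection.

## Synthetic fixtures

The generators in `rodcoil.fixtures` produce geometric ground truth —
an ideal helix (known P1 and local twist period P2, optional Gaussian
positional noise), an ideal abacus (disks of near-parallel rods with
empty gaps), dispersed unimers, and isotropic rod sets — as ordinary
frames in the same extended-XYZ dialect the simulator writes.  They make
every analysis operator testable in milliseconds and are geometric only:
no energetics, no thermal ensemble, no excluded volume.  Passing their
tests validates the *estimators*, not the thermodynamics of the
self-assembly; the reduced-scale sweep below is the check on the actual
dynamics.

## Desk-scale study conditions

Full production runs (7200 beads × 5×10⁶ steps) take days of CPU time, so
the package's test surface uses reduced systems chosen once: 100 R7C3
copolymers with one R40 homopolymer in a 72-sigma box (number density
0.0028, close to the production 0.0021) for 2×10⁵ steps per sweep point.
Sweep points report metrics from the final frame and the morphology label
by majority vote over the production half of the snapshots, because the
labels of coarsening intermediates flicker frame to frame.

What this scale does and does not show.  The condensed-to-dispersed
transitions reproduce cleanly: strong attraction (eps_RR ≥ 2.2) condenses
all copolymers onto the bundle in an ordered wrapped morphology, at 1.6 a
sparse plain fiber sheds roughly half its chains, and at 1.3 everything
disperses into unimers, with the unimer fraction growing monotonically
throughout.  The helix-region point (2.2) shows coherent winding with a
determinate screw pitch P1 ≈ 17 sigma.  What does *not* resolve at this
scale is the abacus-versus-helix distinction within the condensed region:
2×10⁵–6×10⁵ steps (800–2400 time units, versus 20000 in production) leave
the aggregate in beaded intermediates whose rod order parameter stays at
S ≈ 0.2–0.5 — far below the S > 0.7 signature of equilibrated abacus
disks — so both high-eps points typically classify as abacus-like beads.
Quantitative P1/P2 values and their trends versus phi and eps_RR are
likewise noise-dominated here.  Resolving either faithfully needs the
production-scale preset (`n_steps = 5_000_000`, 4 × R150, 660 copolymers,
box 150), which is provided but long-running.

## Numerical choices and limitations

* Pitch estimators return estimate ± uncertainty (curve-fit covariance
  for P2, peak half-width for P1) and an explicit indeterminate state
  rather than a number when the geometry does not support one.
* Axial binning at 1 sigma: bead-diameter resolution.
* Eigen-decomposition ties (degenerate directors, e.g. rods rotating in a
  plane) make u_d arbitrary within the degenerate subspace; the cos θ
  profile's *period* is unaffected, only its phase.
* Per-point sweep seeds come from `SeedSequence(master, spawn_key=(i,))`,
  so extending a value list never reshuffles earlier points.
* The equilibration criterion is left to the user: runs log a
  potential-energy and kinetic-temperature series per snapshot for drift
  diagnostics; no automatic convergence test is applied.
* Not modeled: hydrodynamic interactions, explicit solvent, chirality and
  handedness statistics, polydispersity, electrostatics, constant
  pressure.
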