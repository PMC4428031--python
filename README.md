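# rodcoil

Brownian-dynamics simulation and hierarchical-structure analysis of
**rod-coil block copolymer / rigid homopolymer mixtures**.

Amphiphilic rod-coil diblocks (R_mC_n: a rigid hydrophobic rod block of m
beads plus a flexible hydrophilic coil of n beads — think
PBLG-*b*-PEG) co-assemble with rigid homopolymers (R_x, e.g. α-helical
PBLG) in dilute solution into *hierarchical* aggregates: the homopolymers
pack side-by-side into a bundle, and the copolymers decorate it as
discrete disks (an "abacus"), a helical string, or a plain coating,
depending on the rod-rod attraction ε_RR, the block lengths L_R/L_C, and
the copolymer:homopolymer ratio φ.  This package is for people who want
to simulate that phase behavior and, just as importantly, *measure* it:
every structural descriptor is a first-class, tested estimator.

## Model in brief

Bead-spring chains in reduced units (σ = m = k_B = 1):

* bonds: U_b = ½ k_b (r − r₀)², k_b = 10⁴, r₀ = 0.75 (rod) / 1.0 (coil);
* bending on rod triples: U_a = ½ k_a (cos θ − cos θ₀)², k_a = 10⁴,
  θ₀ = 0.1°;
* nonbonded 12:6 Lennard-Jones with *differential cutoffs*: C-C and R-C
  pairs are WCA-repulsive (cutoff 2^{1/6} σ, shifted), R-R pairs keep the
  attractive tail to 2.5 σ with well depth ε_RR — the single knob that
  plays the role of (inverse) experimental temperature;
* underdamped Langevin dynamics (BAOAB splitting) at T = 3.0 with
  friction Γ₀ = 1.0, dt = 0.004, periodic cubic box.

The analysis layer computes: chain clusters and the unimer fraction; the
bundle axis (optionally piecewise for slightly flexible fibers); the
nematic order parameter S of the rod blocks via the Q-tensor,
S = max_d ⟨(3 (u_i·d)² − 1)/2⟩; the local twisting pitch P₂ (axial period
of the rod packing direction, from the cos θ(z) profile); the screw pitch
P₁ of the helical string (from the azimuthal winding phase); and a
morphology label in {abacus, helix, plain_fiber, unimers}.  See
`docs/methods.md` for every formula, threshold and caveat.

## Worked example

Generate an ideal helical fixture with known geometry, then let the
analysis recover it:

```python
from rodcoil import HelixSpec, make_ideal_helix, classify_morphology

frame = make_ideal_helix(HelixSpec(pitch=17.7, twist_period=17.0,
                                   axial_extent=80.0, noise=0.15, seed=8))
report = classify_morphology(frame)
print(report.label, f"S={report.order_parameter:.3f}")
print(f"P1={report.p1.value:.2f} (quality {report.p1.quality:.2f})")
print(f"P2={report.p2.value:.2f}")
```

prints

```
helix S=0.276
P1=17.69 (quality 0.99)
P2=17.00
```

— the screw pitch (17.7 σ) and twist period (17.0 σ) are recovered within
a fraction of a bead diameter despite the positional noise, and the low S
is exactly what twisting rod packing implies (rods sweep through all
orientations along the string).

Running actual self-assembly, desk scale (a couple of minutes):

```bash
cat > reduced.toml <<'TOML'
[composition]
n_copolymers = 100
rod_beads = 7
coil_beads = 3
homopolymer_beads = 40
n_homopolymers = 1
box_length = 72.0
[forcefield]
eps_rr = 2.2
[run]
n_steps = 200000
snapshot_interval = 20000
TOML
rodcoil simulate --config reduced.toml --seed 7 --out traj.xyz
rodcoil analyze --traj traj.xyz
```

The final frame shows a condensed wrapped aggregate with coherent winding
(P₁ ≈ 17 σ); at 1.6 the same pipeline reports `plain_fiber` (half the
chains dispersed) and at 1.3 `unimers`.  Short desk runs leave the
condensed region in beaded (abacus-like) intermediates — the clean
abacus/helix split needs production-length coarsening (see
`docs/methods.md`).  The whole scan is one command:

```bash
rodcoil sweep --param eps_RR --values 2.6,2.2,1.6,1.3 --config reduced.toml \
        --seed 7 --out sweep_out/
```

Production-scale conditions (660 R₇C₃ + 4 R₁₅₀, box 150, 5×10⁶ steps) are
the config defaults with `n_steps = 5000000`; expect days of CPU time.

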