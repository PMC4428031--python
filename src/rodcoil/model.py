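"""Molecule and system types for rod-coil copolymer / rigid homopolymer mixtures.

The coarse-grained model follows the standard bead-spring picture of an
amphiphilic R_mC_n diblock (a rigid, hydrophobic rod block of m R beads
followed by a flexible, hydrophilic coil block of n C beads) mixed with rigid
R_x homopolymer chains that act as the bundle template.  All lengths are in
units of the bead diameter sigma, energies in units of the Lennard-Jones
epsilon of the repulsive pairs, masses in bead masses, and k_B = 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

# Bead species codes.  Homopolymer R beads are chemically identical to
# copolymer R beads (both hydrophobic) but keep a distinct label so analysis
# can separate the bundle template from the copolymer corona.
SPECIES_ROD = 0    # copolymer rod (R) bead
SPECIES_COIL = 1   # copolymer coil (C) bead
SPECIES_HOMO = 2   # homopolymer rod (R) bead

SPECIES_LABELS = {SPECIES_ROD: "R", SPECIES_COIL: "C", SPECIES_HOMO: "H"}
LABEL_SPECIES = {v: k for k, v in SPECIES_LABELS.items()}

ROD_BOND_LENGTH = 0.75
COIL_BOND_LENGTH = 1.0


class PackingError(RuntimeError):
    """Raised when an initial configuration cannot be packed without overlap."""


@dataclass(frozen=True)
class ChainSpec:
    """Composition of one molecule.

    A copolymer is ``n_rod_beads`` R beads followed by ``n_coil_beads`` C
    beads; a homopolymer has ``n_coil_beads == 0``.  Rod bonds rest at
    0.75 sigma, coil bonds (including the rod-coil junction) at 1.0 sigma.
    """

    n_rod_beads: int
    n_coil_beads: int = 0
    rod_bond_length: float = ROD_BOND_LENGTH
    coil_bond_length: float = COIL_BOND_LENGTH

    def __post_init__(self) -> None:
        if self.n_rod_beads < 2:
            raise ValueError(
                f"a chain with a rod block needs at least 2 R beads, got {self.n_rod_beads}"
            )
        if self.n_coil_beads < 0:
            raise ValueError("n_coil_beads must be non-negative")
        if self.rod_bond_length <= 0 or self.coil_bond_length <= 0:
            raise ValueError("bond rest lengths must be positive")

    @property
    def n_beads(self) -> int:
        return self.n_rod_beads + self.n_coil_beads

    @property
    def is_homopolymer(self) -> bool:
        return self.n_coil_beads == 0

    @property
    def contour_length(self) -> float:
        """End-to-end length of the fully straight chain."""
        rod = (self.n_rod_beads - 1) * self.rod_bond_length
        coil = self.n_coil_beads * self.coil_bond_length
        return rod + coil


@dataclass
class ForceField:
    """All interaction parameters of the bead-spring model.

    The amphiphilicity is encoded purely in the pair cutoffs: C-C and R-C
    pairs are truncated at the LJ minimum 2^(1/6) sigma and shifted to zero
    there (WCA, purely repulsive), while R-R pairs keep the attractive tail
    out to 2.5 sigma, unshifted, so the well depth equals eps_rr exactly.
    eps_rr is the control variable of the model (the experimental proxy for
    inverse temperature); eps_rc = eps_cc = 1 unless overridden.
    """

    eps_rr: float = 2.1
    eps_rc: float = 1.0
    eps_cc: float = 1.0
    k_bond: float = 10000.0
    k_angle: float = 10000.0
    theta0_deg: float = 0.1
    sigma: float = 1.0
    cutoff_rr: float = 2.5
    cutoff_rc: float = 2.0 ** (1.0 / 6.0)
    cutoff_cc: float = 2.0 ** (1.0 / 6.0)
    # Harmonic 1/2 prefactors for bond and angle springs; at k = 10^4 the
    # observables are insensitive to the factor-of-two convention.
    bond_prefactor: float = 0.5
    angle_prefactor: float = 0.5

    def __post_init__(self) -> None:
        wca = 2.0 ** (1.0 / 6.0) * self.sigma
        for name in ("cutoff_rr", "cutoff_rc", "cutoff_cc"):
            if getattr(self, name) < wca - 1e-9:
                raise ValueError(f"{name} must be at least 2^(1/6) sigma")
        for name in ("eps_rr", "eps_rc", "eps_cc", "k_bond", "k_angle", "sigma"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def theta0(self) -> float:
        """Equilibrium bond angle in radians."""
        return math.radians(self.theta0_deg)

    @property
    def max_cutoff(self) -> float:
        return max(self.cutoff_rr, self.cutoff_rc, self.cutoff_cc)

    def pair_tables(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(eps, cutoff^2, energy shift) as 3x3 species-indexed tables.

        The shift makes the repulsive (WCA) pairs continuous at their cutoff;
        attractive R-R pairs are plainly truncated (shift 0).
        """
        eps = np.empty((3, 3))
        rc = np.empty((3, 3))
        shift = np.zeros((3, 3))
        for si in range(3):
            for sj in range(3):
                ci = si == SPECIES_COIL
                cj = sj == SPECIES_COIL
                if ci and cj:
                    eps[si, sj], rc[si, sj] = self.eps_cc, self.cutoff_cc
                elif ci or cj:
                    eps[si, sj], rc[si, sj] = self.eps_rc, self.cutoff_rc
                else:
                    eps[si, sj], rc[si, sj] = self.eps_rr, self.cutoff_rr
                if ci or cj:  # repulsive pair classes: shift so U(rc) = 0
                    s6 = (self.sigma / rc[si, sj]) ** 6
                    shift[si, sj] = -4.0 * eps[si, sj] * (s6 * s6 - s6)
        return eps, rc**2, shift


@dataclass
class MixtureComposition:
    """Chain counts and chain types of one mixture system."""

    n_copolymers: int
    copolymer: ChainSpec
    homopolymer: ChainSpec = field(default_factory=lambda: ChainSpec(150))
    n_homopolymers: int = 4

    def __post_init__(self) -> None:
        if self.n_copolymers < 0 or self.n_homopolymers < 0:
            raise ValueError("chain counts must be non-negative")
        if not self.homopolymer.is_homopolymer:
            raise ValueError("homopolymer spec must have n_coil_beads == 0")

    @property
    def mixture_ratio(self) -> float:
        """phi: chain-number ratio of copolymers to homopolymers."""
        if self.n_homopolymers == 0:
            raise ValueError("mixture ratio undefined without homopolymers")
        return self.n_copolymers / self.n_homopolymers

    def chains(self) -> list[ChainSpec]:
        """Per-chain specs; homopolymers (the bundle template) come first."""
        return [self.homopolymer] * self.n_homopolymers + [
            self.copolymer
        ] * self.n_copolymers


@dataclass
class Topology:
    """Bonded structure of a system: bonds, rod angles, 1-2 exclusions."""

    bonds: np.ndarray        # (n_bonds, 2) int64
    bond_r0: np.ndarray      # (n_bonds,) float64
    angles: np.ndarray       # (n_angles, 3) int64, consecutive R-R-R triples
    exclusions: np.ndarray   # (n_beads, 2) int64, -1 padded; bonded partners

    @property
    def n_bonds(self) -> int:
        return len(self.bonds)


def build_topology(chains: list[ChainSpec]) -> tuple[np.ndarray, np.ndarray, Topology]:
    """Species, chain-id and bonded topology for a list of chains.

    Within a copolymer the rod block comes first.  Angle springs act on every
    consecutive R-R-R triple (rigidity of rod blocks and homopolymers); no
    angle spans the rod-coil junction and coils carry no angle potential.
    The junction bond uses the coil rest length (1.0 sigma).
    """
    n_beads = sum(c.n_beads for c in chains)
    species = np.empty(n_beads, dtype=np.int64)
    chain_id = np.empty(n_beads, dtype=np.int64)
    bonds, bond_r0, angles = [], [], []
    offset = 0
    for cid, chain in enumerate(chains):
        m, n = chain.n_rod_beads, chain.n_coil_beads
        rod_code = SPECIES_HOMO if chain.is_homopolymer else SPECIES_ROD
        species[offset : offset + m] = rod_code
        species[offset + m : offset + m + n] = SPECIES_COIL
        chain_id[offset : offset + m + n] = cid
        for k in range(m + n - 1):
            i = offset + k
            bonds.append((i, i + 1))
            bond_r0.append(chain.rod_bond_length if k < m - 1 else chain.coil_bond_length)
        for k in range(m - 2):
            i = offset + k
            angles.append((i, i + 1, i + 2))
        offset += m + n
    bonds_arr = (
        np.array(bonds, dtype=np.int64) if bonds else np.empty((0, 2), dtype=np.int64)
    )
    angles_arr = (
        np.array(angles, dtype=np.int64) if angles else np.empty((0, 3), dtype=np.int64)
    )
    excl = np.full((n_beads, 2), -1, dtype=np.int64)
    for i, j in bonds_arr:
        for a, b in ((i, j), (j, i)):
            excl[a, 0 if excl[a, 0] < 0 else 1] = b
    topo = Topology(bonds_arr, np.asarray(bond_r0, dtype=np.float64), angles_arr, excl)
    return species, chain_id, topo


@dataclass
class SystemState:
    """Bead positions/velocities plus topology in a periodic cubic box."""

    positions: np.ndarray    # (N, 3) float64, wrapped into [0, box_length)
    velocities: np.ndarray   # (N, 3) float64
    species: np.ndarray      # (N,) int64
    chain_id: np.ndarray     # (N,) int64
    box_length: float
    topology: Topology
    masses: np.ndarray | None = None  # (N,), default all 1

    def __post_init__(self) -> None:
        if self.masses is None:
            self.masses = np.ones(len(self.positions))

    @property
    def n_beads(self) -> int:
        return len(self.positions)

    @property
    def n_chains(self) -> int:
        return int(self.chain_id.max()) + 1 if self.n_beads else 0

    def copy(self) -> "SystemState":
        return SystemState(
            self.positions.copy(),
            self.velocities.copy(),
            self.species.copy(),
            self.chain_id.copy(),
            self.box_length,
            self.topology,
            self.masses.copy(),
        )

    def wrap(self) -> None:
        np.mod(self.positions, self.box_length, out=self.positions)


def count_beads(comp: MixtureComposition) -> int:
    """Total bead number: n_cop * (m + n) + n_homo * x."""
    return (
        comp.n_copolymers * comp.copolymer.n_beads
        + comp.n_homopolymers * comp.homopolymer.n_beads
    )


def number_density(comp: MixtureComposition, box_length: float) -> float:
    """Bead number density in sigma^-3."""
    if box_length <= 0:
        raise ValueError("box_length must be positive")
    return count_beads(comp) / box_length**3


def _lattice_sites(spacing: float, r_min: float, n_needed: int, r_max: float) -> np.ndarray:
    """Square-lattice xy sites sorted by radius, in the annulus [r_min, r_max]."""
    k_max = int(r_max / spacing) + 1
    ks = np.arange(-k_max, k_max + 1)
    gx, gy = np.meshgrid(ks * spacing, ks * spacing, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    r = np.hypot(pts[:, 0], pts[:, 1])
    keep = (r >= r_min) & (r <= r_max)
    pts, r = pts[keep], r[keep]
    order = np.lexsort((np.arctan2(pts[:, 1], pts[:, 0]), r))
    pts = pts[order]
    if len(pts) < n_needed:
        raise PackingError(
            f"only {len(pts)} lattice sites available for {n_needed} chains "
            f"in annulus [{r_min:.2f}, {r_max:.2f}]"
        )
    return pts[:n_needed]


def build_mixture(
    comp: MixtureComposition,
    ff: ForceField,
    box_length: float = 150.0,
    seed: int = 0,
    temperature: float = 3.0,
    jitter: float = 0.05,
    max_retries: int = 5,
) -> SystemState:
    """Deterministic initial configuration of a mixture in a cubic box.

    Homopolymers are placed as parallel straight rods through the box center
    (the bundle template, on a 1-sigma square lattice in xy); copolymers are
    straight chains parallel to the bundle, on concentric 2-sigma square
    lattice shells around it, stacked in z layers.  Small seeded jitter breaks
    lattice degeneracy; velocities are Maxwell-Boltzmann at ``temperature``.
    """
    chains = comp.chains()
    if not chains:
        raise ValueError("composition contains no chains")
    homo_extent = (comp.homopolymer.n_beads - 1) * comp.homopolymer.rod_bond_length
    if comp.n_homopolymers and homo_extent >= box_length:
        raise PackingError(
            f"homopolymer extent {homo_extent:.1f} does not fit in box {box_length}"
        )
    species, chain_id, topo = build_topology(chains)
    n_beads = len(species)
    rng = np.random.default_rng(seed)
    center = box_length / 2.0

    for attempt in range(max_retries):
        positions = np.empty((n_beads, 3))
        offset = 0
        # --- homopolymer bundle: straight rods along z about the center
        r_bundle = 0.0
        if comp.n_homopolymers:
            sites = _lattice_sites(1.0, 0.0, comp.n_homopolymers, box_length / 4)
            r_bundle = float(np.hypot(sites[:, 0], sites[:, 1]).max())
            for h in range(comp.n_homopolymers):
                x = comp.homopolymer.n_beads
                z0 = center - homo_extent / 2.0
                zs = z0 + np.arange(x) * comp.homopolymer.rod_bond_length
                positions[offset : offset + x, 0] = center + sites[h, 0]
                positions[offset : offset + x, 1] = center + sites[h, 1]
                positions[offset : offset + x, 2] = zs
                offset += x
        # --- copolymers: straight chains along +z on lattice shells
        if comp.n_copolymers:
            cp = comp.copolymer
            extent = cp.contour_length
            layer_dz = extent + 1.5
            n_layers = max(1, int((box_length - 1.0) // layer_dz))
            per_layer = -(-comp.n_copolymers // n_layers)  # ceil
            r_min = r_bundle + 1.5
            sites = _lattice_sites(2.0, r_min, per_layer, box_length / 2 - extent / 2 - 1.0)
            bead_z = np.empty(cp.n_beads)
            for k in range(cp.n_rod_beads):
                bead_z[k] = k * cp.rod_bond_length
            for k in range(cp.n_coil_beads):
                bead_z[cp.n_rod_beads + k] = (
                    (cp.n_rod_beads - 1) * cp.rod_bond_length + (k + 1) * cp.coil_bond_length
                )
            for c in range(comp.n_copolymers):
                layer, slot = divmod(c, per_layer)
                z0 = (
                    center
                    + (layer - (n_layers - 1) / 2.0) * layer_dz
                    - extent / 2.0
                )
                jit = rng.uniform(-jitter, jitter, size=3)
                nb = cp.n_beads
                positions[offset : offset + nb, 0] = center + sites[slot, 0] + jit[0]
                positions[offset : offset + nb, 1] = center + sites[slot, 1] + jit[1]
                positions[offset : offset + nb, 2] = z0 + bead_z + jit[2]
                offset += nb
        positions = np.mod(positions, box_length)
        if _min_pair_distance(positions, box_length) >= 0.75 - 1e-9:
            break
    else:
        raise PackingError(
            "could not place chains without overlap after "
            f"{max_retries} retries (number density {n_beads / box_length**3:.4g})"
        )

    velocities = rng.normal(0.0, math.sqrt(temperature), size=(n_beads, 3))
    return SystemState(positions, velocities, species, chain_id, box_length, topo)


def _min_pair_distance(positions: np.ndarray, box_length: float) -> float:
    from scipy.spatial import cKDTree

    if len(positions) < 2:
        return np.inf
    tree = cKDTree(positions, boxsize=box_length)
    d, _ = tree.query(positions, k=2)
    return float(d[:, 1].min())


def renormalize_experiment(
    mn_rod: float,
    mn_coil: float,
    rod_rise_per_bead_set: tuple[float, float] = (3.6, 0.54),
    coil_length_per_bead: float = 0.35,
    rod_reference: float = 7.0,
) -> tuple[float, float]:
    """Map experimental block molar masses to model bead counts.

    Two-step renormalization: bead numbers are first taken proportional to
    block molar mass (equal bulk density), then scaled by the physical length
    one bead represents in each block -- ``rod_rise_per_bead_set = (beads,
    length_nm)`` for the helical rod (e.g. 3.6 beads per 0.54 nm helical
    turn) and ``coil_length_per_bead`` in nm for the coil.  The result is
    normalized so the rod block has ``rod_reference`` beads.
    """
    beads_per_rise, rise_nm = rod_rise_per_bead_set
    if min(mn_rod, mn_coil, beads_per_rise, rise_nm, coil_length_per_bead) <= 0:
        raise ValueError("all renormalization inputs must be positive")
    rod_score = mn_rod * rise_nm / beads_per_rise
    coil_score = mn_coil * coil_length_per_bead
    return rod_reference, rod_reference * coil_score / rod_score


def mn_chain_ratios(
    mn_homopolymer: float, mn_copolymer: float, mn_rod_block: float
) -> tuple[float, float]:
    """Molar-mass ratios homopolymer:copolymer and homopolymer:rod-block.

    These set the model's homopolymer-to-copolymer bead ratio (150:10) and
    homopolymer-to-rod-block bead ratio (150:7).
    """
    if min(mn_homopolymer, mn_copolymer, mn_rod_block) <= 0:
        raise ValueError("molar masses must be positive")
    return mn_homopolymer / mn_copolymer, mn_homopolymer / mn_rod_block


def reference_composition() -> MixtureComposition:
    """The reference mixture: 660 R7C3 copolymers + 4 R150 homopolymers."""
    return MixtureComposition(
        n_copolymers=660,
        copolymer=ChainSpec(7, 3),
        homopolymer=ChainSpec(150),
        n_homopolymers=4,
    )


__all__ = [
    "SPECIES_ROD",
    "SPECIES_COIL",
    "SPECIES_HOMO",
    "SPECIES_LABELS",
    "LABEL_SPECIES",
    "ChainSpec",
    "ForceField",
    "MixtureComposition",
    "Topology",
    "SystemState",
    "PackingError",
    "build_topology",
    "build_mixture",
    "count_beads",
    "number_density",
    "renormalize_experiment",
    "mn_chain_ratios",
    "reference_composition",
]
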