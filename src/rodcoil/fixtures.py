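"""Analytic configurations with known ground truth.

These generators build idealized helix / abacus / isotropic geometries as
ordinary :class:`~rodcoil.model.SystemState` frames, so every analysis
operator can be exercised in milliseconds without running any dynamics.
They are geometric oracles only and make no attempt at thermodynamic
realism (no energies are ever evaluated on them).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .model import ChainSpec, SystemState, build_topology


@dataclass
class HelixSpec:
    """Geometry of an ideal helical string around a straight bundle.

    ``pitch`` is the screw pitch P1 (axial rise of one turn of the string),
    ``twist_period`` the local twisting pitch P2 (axial period of the rod
    packing direction), both in sigma.  ``noise`` is the Gaussian positional
    noise amplitude applied to every bead.
    """

    pitch: float = 17.7
    radius: float = 3.0
    axial_extent: float = 60.0
    rods_per_turn: int = 24
    twist_period: float = 17.0
    noise: float = 0.0
    seed: int = 0
    n_rod_beads: int = 7
    n_coil_beads: int = 3
    n_homopolymers: int = 4
    box_length: float = 150.0

    def __post_init__(self) -> None:
        if self.pitch <= 0 or self.twist_period <= 0:
            raise ValueError("pitch and twist_period must be positive")
        if self.radius < 0 or self.noise < 0:
            raise ValueError("radius and noise must be non-negative")


def _bundle_chains(
    n_homopolymers: int, axial_extent: float, center: np.ndarray
) -> tuple[list[ChainSpec], list[np.ndarray]]:
    """Straight homopolymer rods along z on a 1-sigma lattice around center."""
    spacing = 0.75
    n_beads = max(2, int(round(axial_extent / spacing)) + 1)
    offsets = [(0.0, 0.0), (1.0, 0.0), (0.0, 1.0), (1.0, 1.0), (-1.0, 0.0),
               (0.0, -1.0), (-1.0, 1.0), (1.0, -1.0), (-1.0, -1.0)]
    chains, coords = [], []
    z0 = center[2] - (n_beads - 1) * spacing / 2.0
    for h in range(n_homopolymers):
        ox, oy = offsets[h % len(offsets)]
        pos = np.empty((n_beads, 3))
        pos[:, 0] = center[0] + ox
        pos[:, 1] = center[1] + oy
        pos[:, 2] = z0 + np.arange(n_beads) * spacing
        chains.append(ChainSpec(n_beads))
        coords.append(pos)
    return chains, coords


def _copolymer_coords(
    center: np.ndarray, u: np.ndarray, outward: np.ndarray,
    n_rod: int, n_coil: int,
) -> np.ndarray:
    """Bead coordinates of one straight R-rod + radially extended coil."""
    pos = np.empty((n_rod + n_coil, 3))
    for k in range(n_rod):
        pos[k] = center + (k - (n_rod - 1) / 2.0) * 0.75 * u
    tail = pos[n_rod - 1]
    for k in range(n_coil):
        pos[n_rod + k] = tail + (k + 1) * 1.0 * outward
    return pos


def make_ideal_helix(spec: HelixSpec) -> SystemState:
    """Ideal double-twisted helix: a straight bundle plus a winding string.

    Copolymer rod centers sit on the helix (radius * cos phi, radius *
    sin phi, z) with phi = 2 pi z / pitch; rod directions rotate about the
    bundle with the local twist period, u(z) = cos(alpha) z_hat +
    sin(alpha) x_hat, alpha = 2 pi z / twist_period.  Seeded Gaussian noise
    of the stated amplitude is added to every bead position.
    """
    center = np.array([spec.box_length / 2.0] * 3)
    chains, coords = _bundle_chains(spec.n_homopolymers, spec.axial_extent, center)
    n_rods = max(2, int(round(spec.rods_per_turn * spec.axial_extent / spec.pitch)))
    zs = np.linspace(
        center[2] - spec.axial_extent / 2.0,
        center[2] + spec.axial_extent / 2.0,
        n_rods,
    )
    for z in zs:
        phi = 2.0 * math.pi * (z - center[2]) / spec.pitch
        alpha = 2.0 * math.pi * (z - center[2]) / spec.twist_period
        c = center + np.array(
            [spec.radius * math.cos(phi), spec.radius * math.sin(phi),
             z - center[2]]
        )
        u = np.array([math.sin(alpha), 0.0, math.cos(alpha)])
        outward = np.array([math.cos(phi), math.sin(phi), 0.0])
        chains.append(ChainSpec(spec.n_rod_beads, spec.n_coil_beads))
        coords.append(
            _copolymer_coords(c, u, outward, spec.n_rod_beads, spec.n_coil_beads)
        )
    return _assemble(chains, coords, spec.box_length, spec.noise, spec.seed)


def make_ideal_abacus(
    n_disks: int = 5,
    disk_spacing: float = 6.0,
    rods_per_disk: int = 30,
    seed: int = 0,
    ring_radius: float = 1.8,
    angular_noise: float = 0.1,
    positional_noise: float = 0.1,
    n_rod_beads: int = 7,
    n_coil_beads: int = 3,
    n_homopolymers: int = 4,
    box_length: float = 150.0,
) -> SystemState:
    """Ideal abacus: discrete copolymer disks with empty axial gaps.

    Rods within a disk are near-parallel to the bundle axis (seeded angular
    noise of ``angular_noise`` radians tilts them slightly), arranged on a
    ring around the homopolymer bundle; disks are separated by empty gaps of
    ``disk_spacing`` so the axial density is strongly periodic.
    """
    if n_disks < 2:
        raise ValueError("an abacus needs at least 2 disks")
    rng = np.random.default_rng(seed)
    extent = (n_disks - 1) * disk_spacing + 4.0
    center = np.array([box_length / 2.0] * 3)
    chains, coords = _bundle_chains(n_homopolymers, extent, center)
    z_disks = center[2] + (np.arange(n_disks) - (n_disks - 1) / 2.0) * disk_spacing
    for z in z_disks:
        for j in range(rods_per_disk):
            phi = 2.0 * math.pi * j / rods_per_disk
            c = center + np.array(
                [ring_radius * math.cos(phi), ring_radius * math.sin(phi),
                 z - center[2]]
            )
            tilt = rng.normal(0.0, angular_noise, size=2)
            u = np.array([tilt[0], tilt[1], 1.0])
            u /= np.linalg.norm(u)
            outward = np.array([math.cos(phi), math.sin(phi), 0.0])
            chains.append(ChainSpec(n_rod_beads, n_coil_beads))
            coords.append(_copolymer_coords(c, u, outward, n_rod_beads, n_coil_beads))
    return _assemble(chains, coords, box_length, positional_noise, seed + 1)


def make_dispersed_unimers(
    n_copolymers: int = 40,
    spacing: float = 12.0,
    seed: int = 0,
    n_rod_beads: int = 7,
    n_coil_beads: int = 3,
    box_length: float = 150.0,
    n_homopolymers: int = 4,
) -> SystemState:
    """Copolymers dispersed far apart (all unimers) plus a small bundle."""
    center = np.array([box_length / 2.0] * 3)
    chains, coords = _bundle_chains(n_homopolymers, 20.0, center)
    rng = np.random.default_rng(seed)
    side = max(2, int(math.ceil(n_copolymers ** (1.0 / 3.0))))
    placed = 0
    for ix in range(side):
        for iy in range(side):
            for iz in range(side):
                if placed >= n_copolymers:
                    break
                c = np.array([
                    (ix + 0.5 - side / 2.0) * spacing + 25.0,
                    (iy + 0.5 - side / 2.0) * spacing + 25.0,
                    (iz + 0.5 - side / 2.0) * spacing,
                ]) + center
                u = rng.standard_normal(3)
                u /= np.linalg.norm(u)
                outward = rng.standard_normal(3)
                outward -= (outward @ u) * u
                outward /= np.linalg.norm(outward)
                chains.append(ChainSpec(n_rod_beads, n_coil_beads))
                coords.append(
                    _copolymer_coords(c, u, outward, n_rod_beads, n_coil_beads)
                )
                placed += 1
    return _assemble(chains, coords, box_length, 0.0, seed)


def make_isotropic_rods(n: int, seed: int = 0):
    """Rod-vector set with directions uniform on the sphere.

    Directions are normalized 3D Gaussians (exactly uniform on S^2); centers
    are spread on a loose grid so the set can also serve as input to
    geometric routines that want distinct centers.
    """
    from .analysis import RodVectorSet

    if n < 1:
        raise ValueError("need at least one rod")
    rng = np.random.default_rng(seed)
    v = rng.standard_normal((n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    centers = rng.uniform(0.0, 50.0, size=(n, 3))
    return RodVectorSet(v, centers, np.arange(n, dtype=np.int64))


def _assemble(
    chains: list[ChainSpec],
    coords: list[np.ndarray],
    box_length: float,
    noise: float,
    seed: int,
) -> SystemState:
    species, chain_id, topo = build_topology(chains)
    positions = np.concatenate(coords)
    if noise > 0:
        rng = np.random.default_rng(seed)
        positions = positions + rng.normal(0.0, noise, size=positions.shape)
    positions = np.mod(positions, box_length)
    return SystemState(
        positions,
        np.zeros_like(positions),
        species,
        chain_id,
        box_length,
        topo,
    )


__all__ = [
    "HelixSpec",
    "make_ideal_helix",
    "make_ideal_abacus",
    "make_dispersed_unimers",
    "make_isotropic_rods",
]
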