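"""Shared fixtures and independent reference implementations.

The force reference here is a deliberately naive O(N^2) numpy implementation
written from the potential definitions, kept independent of the package's
cell-list/numba path so it can serve as an oracle.
"""

from __future__ import annotations

import numpy as np
import pytest

from rodcoil.model import (
    SPECIES_COIL,
    ChainSpec,
    ForceField,
    MixtureComposition,
    SystemState,
    Topology,
    build_mixture,
)


@pytest.fixture
def small_mixture() -> tuple[MixtureComposition, ForceField, SystemState]:
    comp = MixtureComposition(
        n_copolymers=6,
        copolymer=ChainSpec(7, 3),
        homopolymer=ChainSpec(10),
        n_homopolymers=2,
    )
    ff = ForceField(eps_rr=2.1)
    state = build_mixture(comp, ff, box_length=24.0, seed=42)
    return comp, ff, state


def free_bead_state(
    n: int, box: float, seed: int = 0, temperature: float = 3.0
) -> SystemState:
    """Non-interacting beads (no bonds, spread far apart) in a large box."""
    rng = np.random.default_rng(seed)
    side = int(np.ceil(n ** (1 / 3)))
    spacing = box / (side + 1)
    assert spacing > 10.0, "beads must be dilute enough to never interact"
    grid = np.stack(
        np.meshgrid(*[np.arange(side)] * 3, indexing="ij"), axis=-1
    ).reshape(-1, 3)[:n]
    positions = (grid + 1.0) * spacing
    velocities = rng.normal(0.0, np.sqrt(temperature), size=(n, 3))
    topo = Topology(
        bonds=np.empty((0, 2), dtype=np.int64),
        bond_r0=np.empty(0),
        angles=np.empty((0, 3), dtype=np.int64),
        exclusions=np.full((n, 2), -1, dtype=np.int64),
    )
    return SystemState(
        positions,
        velocities,
        np.full(n, SPECIES_COIL, dtype=np.int64),
        np.arange(n, dtype=np.int64),
        box,
        topo,
    )


def brute_force_reference(state: SystemState, ff: ForceField):
    """O(N^2) all-pairs + bonded forces/energy, straight from the formulas."""
    pos = state.positions
    box = state.box_length
    n = len(pos)
    forces = np.zeros_like(pos)
    energy = 0.0

    def mi(d):
        return d - box * np.round(d / box)

    # bonds
    for (i, j), r0 in zip(state.topology.bonds, state.topology.bond_r0):
        d = mi(pos[j] - pos[i])
        r = np.linalg.norm(d)
        energy += ff.bond_prefactor * ff.k_bond * (r - r0) ** 2
        f = -2.0 * ff.bond_prefactor * ff.k_bond * (r - r0) * d / r
        forces[j] += f
        forces[i] -= f
    # angles (between consecutive bond vectors)
    cos0 = np.cos(np.radians(ff.theta0_deg))
    for i, j, k in state.topology.angles:
        a = mi(pos[j] - pos[i])
        b = mi(pos[k] - pos[j])
        ra, rb = np.linalg.norm(a), np.linalg.norm(b)
        c = float(np.clip(a @ b / (ra * rb), -1, 1))
        d = c - cos0
        energy += ff.angle_prefactor * ff.k_angle * d * d
        coeff = 2.0 * ff.angle_prefactor * ff.k_angle * d
        dc_da = b / (ra * rb) - c * a / ra**2
        dc_db = a / (ra * rb) - c * b / rb**2
        fi = coeff * dc_da
        fk = -coeff * dc_db
        forces[i] += fi
        forces[k] += fk
        forces[j] -= fi + fk
    # nonbonded LJ with pair-class cutoffs and WCA shifts
    eps_t, rc2_t, shift_t = ff.pair_tables()
    excl = {tuple(sorted(b)) for b in state.topology.bonds.tolist()}
    for i in range(n):
        for j in range(i + 1, n):
            if (i, j) in excl:
                continue
            d = mi(pos[j] - pos[i])
            r2 = float(d @ d)
            si, sj = state.species[i], state.species[j]
            if r2 >= rc2_t[si, sj]:
                continue
            s6 = (ff.sigma**2 / r2) ** 3
            s12 = s6 * s6
            energy += 4 * eps_t[si, sj] * (s12 - s6) + shift_t[si, sj]
            fr = 24 * eps_t[si, sj] * (2 * s12 - s6) / r2
            forces[j] += fr * d
            forces[i] -= fr * d
    return forces, energy


def make_bare_state(
    positions: np.ndarray,
    species: np.ndarray,
    box: float,
    chain_id: np.ndarray | None = None,
) -> SystemState:
    """SystemState with no bonded topology (isolated beads)."""
    positions = np.asarray(positions, dtype=float)
    n = len(positions)
    topo = Topology(
        bonds=np.empty((0, 2), dtype=np.int64),
        bond_r0=np.empty(0),
        angles=np.empty((0, 3), dtype=np.int64),
        exclusions=np.full((n, 2), -1, dtype=np.int64),
    )
    return SystemState(
        positions,
        np.zeros_like(positions),
        np.asarray(species, dtype=np.int64),
        np.arange(n, dtype=np.int64) if chain_id is None else np.asarray(chain_id),
        box,
        topo,
    )
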