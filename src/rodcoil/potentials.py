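"""Bonded and nonbonded energies/forces of the bead-spring force field.

Three terms only:

* harmonic bond stretching  U_b(r) = (1/2) k_b (r - r0)^2
* cosine-harmonic angle bending on rigid triples
  U_a(theta) = (1/2) k_a (cos theta - cos theta0)^2
* 12:6 Lennard-Jones between all nonbonded pairs, with pair-class cutoffs:
  repulsive (WCA, shifted) for C-C and R-C at 2^(1/6) sigma, attractive
  (plainly truncated) for R-R at 2.5 sigma.

Scalar reference implementations live at module level; the system-level
``total_forces`` runs numba kernels over a Verlet pair list built from a
cell decomposition, under the minimum-image convention.  Directly bonded
(1-2) pairs are excluded from the nonbonded sum; 1-3 pairs interact.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

from .model import ForceField, SystemState

# ---------------------------------------------------------------------------
# scalar reference forms


def bond_energy_force(r: float, k_b: float, r0: float, prefactor: float = 0.5):
    """Energy and scalar force of one harmonic bond.

    The returned force is f = -dU/dr: positive when the bond is compressed
    (pushing the beads apart), negative when stretched.
    """
    if r <= 0:
        raise ValueError("bonded beads are coincident (r = 0)")
    dr = r - r0
    energy = prefactor * k_b * dr * dr
    force = -2.0 * prefactor * k_b * dr
    return energy, force


def angle_energy(theta: float, k_a: float, theta0: float, prefactor: float = 0.5):
    """Cosine-harmonic bending energy at bond angle ``theta`` (radians)."""
    d = math.cos(theta) - math.cos(theta0)
    return prefactor * k_a * d * d


def angle_energy_force(
    p_i: np.ndarray,
    p_j: np.ndarray,
    p_k: np.ndarray,
    k_a: float,
    theta0: float,
    prefactor: float = 0.5,
):
    """Energy and forces on the three beads of an angle (j is the vertex).

    theta is the angle between the two consecutive bond vectors
    a = p_j - p_i and b = p_k - p_j (zero for a straight chain, so the
    near-zero equilibrium theta0 keeps rods straight).  Forces are the
    exact negative gradient of U = prefactor * k_a * (cos theta - cos
    theta0)^2.
    """
    a = np.asarray(p_j, dtype=float) - np.asarray(p_i, dtype=float)
    b = np.asarray(p_k, dtype=float) - np.asarray(p_j, dtype=float)
    ra = np.linalg.norm(a)
    rb = np.linalg.norm(b)
    if ra == 0.0 or rb == 0.0:
        raise ValueError("degenerate angle: zero-length bond vector")
    c = float(np.dot(a, b) / (ra * rb))
    c = min(1.0, max(-1.0, c))
    d = c - math.cos(theta0)
    energy = prefactor * k_a * d * d
    coeff = 2.0 * prefactor * k_a * d  # = dU/dc
    dc_da = b / (ra * rb) - c * a / (ra * ra)
    dc_db = a / (ra * rb) - c * b / (rb * rb)
    f_i = coeff * dc_da       # a = p_j - p_i, so dU/dp_i = -coeff * dc_da
    f_k = -coeff * dc_db
    f_j = -(f_i + f_k)
    return energy, (f_i, f_j, f_k)


def lj_energy_force(r: float, pair: str, ff: ForceField):
    """LJ 12:6 energy and scalar force (-dU/dr) for one pair at distance r.

    ``pair`` is one of "RR", "RC", "CC".  Repulsive classes (RC, CC) are
    truncated and shifted at their cutoff (WCA form); the attractive RR
    class is plainly truncated at 2.5 sigma so its well depth is exactly
    eps_rr.
    """
    if r <= 0:
        raise ValueError("beads are coincident (r = 0)")
    key = "".join(sorted(pair.upper()))
    if key == "RR":
        eps, rc, shift = ff.eps_rr, ff.cutoff_rr, 0.0
    elif key == "CR":
        eps, rc = ff.eps_rc, ff.cutoff_rc
        s6 = (ff.sigma / rc) ** 6
        shift = -4.0 * eps * (s6 * s6 - s6)
    elif key == "CC":
        eps, rc = ff.eps_cc, ff.cutoff_cc
        s6 = (ff.sigma / rc) ** 6
        shift = -4.0 * eps * (s6 * s6 - s6)
    else:
        raise ValueError(f"unknown pair class {pair!r}")
    if r >= rc:
        return 0.0, 0.0
    s6 = (ff.sigma / r) ** 6
    s12 = s6 * s6
    energy = 4.0 * eps * (s12 - s6) + shift
    force = 24.0 * eps * (2.0 * s12 - s6) / r
    return energy, force


# ---------------------------------------------------------------------------
# numba kernels


@njit(cache=True, inline="always")
def _min_image(d: float, box: float) -> float:
    # branch form beats round(): inputs are wrapped, so |d| < box always
    if d > 0.5 * box:
        return d - box
    if d < -0.5 * box:
        return d + box
    return d


@njit(cache=True)
def _bonded_kernel(
    pos, box, bonds, bond_r0, kb2, angles, ka2, cos0, forces
):
    """Accumulate bond + angle forces; returns bonded potential energy.

    kb2 / ka2 are the full quadratic coefficients 2 * prefactor * k.
    """
    energy = 0.0
    for b in range(bonds.shape[0]):
        i = bonds[b, 0]
        j = bonds[b, 1]
        dx = _min_image(pos[j, 0] - pos[i, 0], box)
        dy = _min_image(pos[j, 1] - pos[i, 1], box)
        dz = _min_image(pos[j, 2] - pos[i, 2], box)
        r = math.sqrt(dx * dx + dy * dy + dz * dz)
        dr = r - bond_r0[b]
        energy += 0.5 * kb2 * dr * dr
        fmag = -kb2 * dr / r  # force on j along (r_j - r_i)
        forces[j, 0] += fmag * dx
        forces[j, 1] += fmag * dy
        forces[j, 2] += fmag * dz
        forces[i, 0] -= fmag * dx
        forces[i, 1] -= fmag * dy
        forces[i, 2] -= fmag * dz
    for t in range(angles.shape[0]):
        i = angles[t, 0]
        j = angles[t, 1]
        k = angles[t, 2]
        # theta is between consecutive bond vectors a = r_j - r_i, b = r_k - r_j
        ax = _min_image(pos[j, 0] - pos[i, 0], box)
        ay = _min_image(pos[j, 1] - pos[i, 1], box)
        az = _min_image(pos[j, 2] - pos[i, 2], box)
        bx = _min_image(pos[k, 0] - pos[j, 0], box)
        by = _min_image(pos[k, 1] - pos[j, 1], box)
        bz = _min_image(pos[k, 2] - pos[j, 2], box)
        ra2 = ax * ax + ay * ay + az * az
        rb2 = bx * bx + by * by + bz * bz
        ra = math.sqrt(ra2)
        rb = math.sqrt(rb2)
        inv_ab = 1.0 / (ra * rb)
        c = (ax * bx + ay * by + az * bz) * inv_ab
        if c > 1.0:
            c = 1.0
        elif c < -1.0:
            c = -1.0
        d = c - cos0
        energy += 0.5 * ka2 * d * d
        coeff = ka2 * d  # dU/dc
        # f_i = +coeff * dc/da (a = r_j - r_i), f_k = -coeff * dc/db
        gix = coeff * (bx * inv_ab - c * ax / ra2)
        giy = coeff * (by * inv_ab - c * ay / ra2)
        giz = coeff * (bz * inv_ab - c * az / ra2)
        gkx = -coeff * (ax * inv_ab - c * bx / rb2)
        gky = -coeff * (ay * inv_ab - c * by / rb2)
        gkz = -coeff * (az * inv_ab - c * bz / rb2)
        forces[i, 0] += gix
        forces[i, 1] += giy
        forces[i, 2] += giz
        forces[k, 0] += gkx
        forces[k, 1] += gky
        forces[k, 2] += gkz
        forces[j, 0] -= gix + gkx
        forces[j, 1] -= giy + gky
        forces[j, 2] -= giz + gkz
    return energy


@njit(cache=True, fastmath=True)
def _pair_kernel(pos, box, pi, pj, pair_eps, pair_rc2, pair_shift, sigma2, forces):
    """Accumulate nonbonded LJ forces over the pair list; returns energy.

    Pair parameters are pre-gathered per pair at list-build time, keeping
    the inner loop free of table lookups.
    """
    energy = 0.0
    for n in range(pi.shape[0]):
        i = pi[n]
        j = pj[n]
        dx = _min_image(pos[j, 0] - pos[i, 0], box)
        dy = _min_image(pos[j, 1] - pos[i, 1], box)
        dz = _min_image(pos[j, 2] - pos[i, 2], box)
        r2 = dx * dx + dy * dy + dz * dz
        if r2 < pair_rc2[n]:
            eps = pair_eps[n]
            s2 = sigma2 / r2
            s6 = s2 * s2 * s2
            s12 = s6 * s6
            energy += 4.0 * eps * (s12 - s6) + pair_shift[n]
            fr = 24.0 * eps * (2.0 * s12 - s6) / r2  # f_j = fr * (r_j - r_i)
            forces[j, 0] += fr * dx
            forces[j, 1] += fr * dy
            forces[j, 2] += fr * dz
            forces[i, 0] -= fr * dx
            forces[i, 1] -= fr * dy
            forces[i, 2] -= fr * dz
    return energy


@njit(cache=True)
def _is_excluded(excl, i, j):
    return excl[i, 0] == j or excl[i, 1] == j


@njit(cache=True)
def _build_pairs_bruteforce(pos, box, rlist2, excl):
    n = pos.shape[0]
    count = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx = _min_image(pos[j, 0] - pos[i, 0], box)
            dy = _min_image(pos[j, 1] - pos[i, 1], box)
            dz = _min_image(pos[j, 2] - pos[i, 2], box)
            if dx * dx + dy * dy + dz * dz < rlist2 and not _is_excluded(excl, i, j):
                count += 1
    pi = np.empty(count, dtype=np.int64)
    pj = np.empty(count, dtype=np.int64)
    k = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx = _min_image(pos[j, 0] - pos[i, 0], box)
            dy = _min_image(pos[j, 1] - pos[i, 1], box)
            dz = _min_image(pos[j, 2] - pos[i, 2], box)
            if dx * dx + dy * dy + dz * dz < rlist2 and not _is_excluded(excl, i, j):
                pi[k] = i
                pj[k] = j
                k += 1
    return pi, pj


@njit(cache=True)
def _build_pairs_cells(pos, box, rlist, excl, cap, nc):
    """Half pair list from a linked-cell decomposition (needs >= 3 cells/side).

    Bead-centric sweep over the 14-cell half stencil; returns (pi, pj, count)
    where count may exceed len(pi) when the capacity ``cap`` was too small
    (the caller then retries with a larger one).  ``nc`` cells per side must
    satisfy box / nc >= rlist (cells may be larger than rlist; that only
    adds candidates, never misses a pair).
    """
    n = pos.shape[0]
    rlist2 = rlist * rlist
    head = np.full(nc * nc * nc, -1, dtype=np.int64)
    nxt = np.full(n, -1, dtype=np.int64)
    cellxyz = np.empty((n, 3), dtype=np.int64)
    for i in range(n):
        cx = int(pos[i, 0] / box * nc)
        cy = int(pos[i, 1] / box * nc)
        cz = int(pos[i, 2] / box * nc)
        if cx >= nc:
            cx = nc - 1
        if cy >= nc:
            cy = nc - 1
        if cz >= nc:
            cz = nc - 1
        cellxyz[i, 0] = cx
        cellxyz[i, 1] = cy
        cellxyz[i, 2] = cz
        c = (cx * nc + cy) * nc + cz
        nxt[i] = head[c]
        head[c] = i
    # half stencil: the same cell plus 13 of the 26 neighbors
    offs = np.empty((14, 3), dtype=np.int64)
    idx = 0
    for ox in range(-1, 2):
        for oy in range(-1, 2):
            for oz in range(-1, 2):
                key = (ox * 9) + (oy * 3) + oz
                if key > 0 or (ox == 0 and oy == 0 and oz == 0):
                    offs[idx, 0] = ox
                    offs[idx, 1] = oy
                    offs[idx, 2] = oz
                    idx += 1
    pi = np.empty(cap, dtype=np.int64)
    pj = np.empty(cap, dtype=np.int64)
    count = 0
    for i in range(n):
        cx = cellxyz[i, 0]
        cy = cellxyz[i, 1]
        cz = cellxyz[i, 2]
        for s in range(14):
            ox = (cx + offs[s, 0]) % nc
            oy = (cy + offs[s, 1]) % nc
            oz = (cz + offs[s, 2]) % nc
            c2 = (ox * nc + oy) * nc + oz
            # within the home cell, start after i in the linked list (half list)
            if offs[s, 0] == 0 and offs[s, 1] == 0 and offs[s, 2] == 0:
                j = nxt[i]
            else:
                j = head[c2]
            while j >= 0:
                dx = _min_image(pos[j, 0] - pos[i, 0], box)
                dy = _min_image(pos[j, 1] - pos[i, 1], box)
                dz = _min_image(pos[j, 2] - pos[i, 2], box)
                if (
                    dx * dx + dy * dy + dz * dz < rlist2
                    and not _is_excluded(excl, i, j)
                ):
                    if count < cap:
                        pi[count] = i
                        pj[count] = j
                    count += 1
                j = nxt[j]
    return pi, pj, count


@njit(cache=True)
def _max_displacement2(pos, ref, box):
    m = 0.0
    for i in range(pos.shape[0]):
        d2 = 0.0
        for k in range(3):
            d = _min_image(pos[i, k] - ref[i, k], box)
            d2 += d * d
        if d2 > m:
            m = d2
    return m


class NeighborList:
    """Verlet pair list with a skin margin, rebuilt from a cell decomposition.

    The list is valid while no bead has moved farther than skin/2 since the
    last build; ``total_forces`` checks this and rebuilds automatically.
    """

    def __init__(self, ff: ForceField, skin: float = 0.4):
        if skin <= 0:
            raise ValueError("skin must be positive")
        self.skin = skin
        self.rlist = ff.max_cutoff + skin
        self._eps_t, self._rc2_t, self._shift_t = ff.pair_tables()
        self.pair_eps = np.empty(0)
        self.pair_rc2 = np.empty(0)
        self.pair_shift = np.empty(0)
        self.pi = np.empty(0, dtype=np.int64)
        self.pj = np.empty(0, dtype=np.int64)
        self.ref_positions: np.ndarray | None = None
        self.n_builds = 0
        self._cap = 0

    def build(self, state: SystemState) -> None:
        pos = state.positions
        box = state.box_length
        excl = state.topology.exclusions
        # cap the grid so the cell array never dwarfs the bead count
        # (relevant for dilute systems in very large boxes)
        nc = min(int(box / self.rlist), max(3, int(len(pos) ** (1 / 3)) + 1))
        if nc >= 3 and len(pos) > 32:
            if self._cap == 0:
                self._cap = max(1024, 64 * len(pos))
            while True:
                pi, pj, count = _build_pairs_cells(
                    pos, box, self.rlist, excl, self._cap, nc
                )
                if count <= self._cap:
                    break
                self._cap = int(1.5 * count) + 64
            self.pi, self.pj = pi[:count], pj[:count]
        else:
            self.pi, self.pj = _build_pairs_bruteforce(
                pos, box, self.rlist * self.rlist, excl
            )
        si = state.species[self.pi]
        sj = state.species[self.pj]
        self.pair_eps = self._eps_t[si, sj]
        self.pair_rc2 = self._rc2_t[si, sj]
        self.pair_shift = self._shift_t[si, sj]
        self.ref_positions = pos.copy()
        self.n_builds += 1

    def is_stale(self, state: SystemState) -> bool:
        if self.ref_positions is None or len(self.ref_positions) != len(state.positions):
            return True
        half = 0.5 * self.skin
        return (
            _max_displacement2(state.positions, self.ref_positions, state.box_length)
            > half * half
        )


def total_forces(
    state: SystemState, ff: ForceField, neighbors: NeighborList | None = None
):
    """Per-bead forces and total potential energy of one configuration.

    Sums bonded (bond + angle) and nonbonded LJ contributions under the
    minimum-image convention, excluding directly bonded pairs from the
    nonbonded sum.  A stale or absent neighbor list is (re)built.
    """
    if neighbors is None:
        neighbors = NeighborList(ff)
    if neighbors.is_stale(state):
        neighbors.build(state)
    forces = np.zeros_like(state.positions)
    energy = _bonded_kernel(
        state.positions,
        state.box_length,
        state.topology.bonds,
        state.topology.bond_r0,
        2.0 * ff.bond_prefactor * ff.k_bond,
        state.topology.angles,
        2.0 * ff.angle_prefactor * ff.k_angle,
        math.cos(ff.theta0),
        forces,
    )
    energy += _pair_kernel(
        state.positions,
        state.box_length,
        neighbors.pi,
        neighbors.pj,
        neighbors.pair_eps,
        neighbors.pair_rc2,
        neighbors.pair_shift,
        ff.sigma**2,
        forces,
    )
    return forces, energy


__all__ = [
    "bond_energy_force",
    "angle_energy",
    "angle_energy_force",
    "lj_energy_force",
    "NeighborList",
    "total_forces",
]
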