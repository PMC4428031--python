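"""Structural descriptors of rod-coil copolymer / homopolymer aggregates.

From a single trajectory frame this module computes everything needed to
place a configuration in the morphology diagram:

* chain clusters and the unimer fraction (free copolymer chains),
* the bundle (major) axis from the homopolymer beads, optionally split
  into 2-3 subaxes for slightly flexible fibers,
* the nematic order parameter S of the rod blocks and the orientation
  director u_d, via the Q-tensor eigen-decomposition,
* the cos(theta) twist profile of rod orientation along the axis and the
  local twisting pitch P2 (axial period of one full rotation of the rod
  packing direction),
* the screw pitch P1 of the helical copolymer string (axial length of one
  turn of the string around the bundle), and
* a morphology label in {abacus, helix, plain_fiber, unimers}.

S is defined as the maximum over directors d of <(3 (u_i . d)^2 - 1)/2>;
the maximizing d is the leading eigenvector of the nematic Q-tensor
Q = (3/2) <u u> - (1/2) I, so the "iterative maximization" definition is
evaluated exactly by eigen-decomposition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, sparse
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .model import SPECIES_COIL, SPECIES_HOMO, SPECIES_ROD, SystemState


# ---------------------------------------------------------------------------
# chain geometry helpers


def _unwrap_chain(pos: np.ndarray, box: float) -> np.ndarray:
    """Undo periodic wrapping along one chain (sequentially bonded beads)."""
    out = pos.copy()
    d = np.diff(pos, axis=0)
    d -= box * np.round(d / box)
    out[1:] = pos[0] + np.cumsum(d, axis=0)
    return out


def _chain_slices(chain_id: np.ndarray) -> list[slice]:
    """Per-chain contiguous index ranges (beads of a chain are contiguous)."""
    boundaries = np.flatnonzero(np.diff(chain_id)) + 1
    edges = np.concatenate(([0], boundaries, [len(chain_id)]))
    return [slice(a, b) for a, b in zip(edges[:-1], edges[1:])]


def chain_is_copolymer(frame: SystemState) -> np.ndarray:
    """Boolean mask over chains: True where the chain has coil (C) beads."""
    slices = _chain_slices(frame.chain_id)
    return np.array(
        [bool(np.any(frame.species[s] == SPECIES_COIL)) for s in slices]
    )


@dataclass
class RodVectorSet:
    """Normalized rod-block direction vectors and their centers of mass.

    Directions run from the first to the last bead of each rod block and are
    unit-norm; centers are unwrapped coordinates.
    """

    vectors: np.ndarray    # (n, 3) unit vectors
    centers: np.ndarray    # (n, 3)
    chain_ids: np.ndarray  # (n,) source chain of each rod block

    def __len__(self) -> int:
        return len(self.vectors)


def rod_vectors(
    frame: SystemState, chain_subset: np.ndarray | None = None
) -> RodVectorSet:
    """Rod-block vectors of the copolymer chains (optionally a chain subset)."""
    box = frame.box_length
    vectors, centers, cids = [], [], []
    subset = None if chain_subset is None else set(int(c) for c in chain_subset)
    for s in _chain_slices(frame.chain_id):
        cid = int(frame.chain_id[s.start])
        if subset is not None and cid not in subset:
            continue
        rod_mask = frame.species[s] == SPECIES_ROD
        if not rod_mask.any():
            continue
        chain_pos = _unwrap_chain(frame.positions[s], box)
        rod_pos = chain_pos[rod_mask]
        if len(rod_pos) < 2:
            continue
        u = rod_pos[-1] - rod_pos[0]
        norm = np.linalg.norm(u)
        if norm == 0:
            raise ValueError(f"zero-length rod block on chain {cid}")
        vectors.append(u / norm)
        centers.append(rod_pos.mean(axis=0))
        cids.append(cid)
    if not vectors:
        return RodVectorSet(
            np.empty((0, 3)), np.empty((0, 3)), np.empty(0, dtype=np.int64)
        )
    return RodVectorSet(
        np.array(vectors), np.array(centers), np.array(cids, dtype=np.int64)
    )


# ---------------------------------------------------------------------------
# clustering


def find_clusters(frame: SystemState, cutoff: float = 1.5) -> np.ndarray:
    """Single-linkage chain clusters via hydrophobic (R) bead contacts.

    Two chains belong to one cluster when any of their R beads (copolymer
    rod or homopolymer) approach within ``cutoff`` under the minimum image.
    Coil beads are solvated coronas and are ignored.  Returns one integer
    label per chain.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    n_chains = frame.n_chains
    hydrophobic = frame.species != SPECIES_COIL
    idx = np.flatnonzero(hydrophobic)
    if len(idx) == 0:
        return np.arange(n_chains)
    pos = np.mod(frame.positions[idx], frame.box_length)
    tree = cKDTree(pos, boxsize=frame.box_length)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    ci = frame.chain_id[idx[pairs[:, 0]]] if len(pairs) else np.empty(0, dtype=np.int64)
    cj = frame.chain_id[idx[pairs[:, 1]]] if len(pairs) else np.empty(0, dtype=np.int64)
    keep = ci != cj
    adj = sparse.coo_matrix(
        (np.ones(keep.sum()), (ci[keep], cj[keep])), shape=(n_chains, n_chains)
    )
    _, labels = connected_components(adj, directed=False)
    return labels


def unimer_fraction(labels: np.ndarray, is_copolymer: np.ndarray) -> float:
    """Fraction of copolymer chains that sit alone in a singleton cluster.

    Homopolymers are excluded from both numerator and denominator.
    """
    labels = np.asarray(labels)
    is_copolymer = np.asarray(is_copolymer, dtype=bool)
    n_cop = int(is_copolymer.sum())
    if n_cop == 0:
        return 0.0
    sizes = np.bincount(labels)
    singleton = sizes[labels] == 1
    return float(np.sum(singleton & is_copolymer)) / n_cop


# ---------------------------------------------------------------------------
# bundle axis


@dataclass
class AxisModel:
    """Piecewise-linear major axis: a polyline of 1-3 straight subaxes."""

    nodes: np.ndarray  # (n_segments + 1, 3)

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=float)
        if self.nodes.ndim != 2 or len(self.nodes) < 2:
            raise ValueError("axis needs at least two nodes")

    @property
    def n_segments(self) -> int:
        return len(self.nodes) - 1

    @property
    def segment_directions(self) -> np.ndarray:
        d = np.diff(self.nodes, axis=0)
        return d / np.linalg.norm(d, axis=1, keepdims=True)

    @property
    def segment_lengths(self) -> np.ndarray:
        return np.linalg.norm(np.diff(self.nodes, axis=0), axis=1)

    @property
    def direction(self) -> np.ndarray:
        """Overall unit direction from first to last node."""
        d = self.nodes[-1] - self.nodes[0]
        return d / np.linalg.norm(d)

    def axial_coordinate(self, points: np.ndarray) -> np.ndarray:
        """Arc-length coordinate of the projection of each point."""
        s, _ = self._project(np.atleast_2d(points))
        return s

    def local_direction(self, points: np.ndarray) -> np.ndarray:
        """Unit direction of the subaxis nearest to each point."""
        _, seg = self._project(np.atleast_2d(points))
        return self.segment_directions[seg]

    def _project(self, pts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        dirs = self.segment_directions
        lens = self.segment_lengths
        cum = np.concatenate(([0.0], np.cumsum(lens)))
        # t[p, s]: projection of point p onto segment s, from segment start
        t = np.einsum("psk,sk->ps", pts[:, None, :] - self.nodes[None, :-1, :], dirs)
        t_clip = np.clip(t, 0.0, lens[None, :])
        foot = self.nodes[None, :-1, :] + t_clip[:, :, None] * dirs[None, :, :]
        d2 = np.sum((pts[:, None, :] - foot) ** 2, axis=2)
        seg = np.argmin(d2, axis=1)
        rows = np.arange(len(pts))
        t_sel = t_clip[rows, seg]
        # allow extrapolation beyond the first/last segment ends
        first = seg == 0
        t_sel = np.where(first & (t[rows, seg] < 0), t[rows, seg], t_sel)
        last = seg == self.n_segments - 1
        t_sel = np.where(last & (t[rows, seg] > lens[seg]), t[rows, seg], t_sel)
        return cum[seg] + t_sel, seg


def _principal_direction(points: np.ndarray) -> np.ndarray:
    c = points - points.mean(axis=0)
    _, _, vt = np.linalg.svd(c, full_matrices=False)
    d = vt[0]
    # deterministic sign: largest-magnitude component positive
    k = int(np.argmax(np.abs(d)))
    return d if d[k] >= 0 else -d


def bundle_axis(frame: SystemState, n_subaxes: int = 1) -> AxisModel:
    """Major axis of the homopolymer bundle (principal direction fit).

    With ``n_subaxes`` in {2, 3} the axis is a polyline of that many
    straight pieces fitted over contiguous axial intervals, for slightly
    flexible fibers.
    """
    if n_subaxes not in (1, 2, 3):
        raise ValueError("n_subaxes must be 1, 2 or 3")
    box = frame.box_length
    chunks = []
    ref_centroid = None
    for s in _chain_slices(frame.chain_id):
        if not np.all(frame.species[s] == SPECIES_HOMO):
            continue
        p = _unwrap_chain(frame.positions[s], box)
        c = p.mean(axis=0)
        if ref_centroid is None:
            ref_centroid = c
        else:
            shift = box * np.round((c - ref_centroid) / box)
            p -= shift
        chunks.append(p)
    if not chunks:
        raise ValueError("no homopolymer chains in frame")
    pts = np.concatenate(chunks)
    if len(pts) < 2:
        raise ValueError("need at least 2 homopolymer beads to fit an axis")
    major = _principal_direction(pts)
    centroid = pts.mean(axis=0)
    t = (pts - centroid) @ major
    if n_subaxes == 1:
        nodes = np.array([centroid + t.min() * major, centroid + t.max() * major])
        return AxisModel(nodes)
    edges = np.linspace(t.min(), t.max(), n_subaxes + 1)
    seg_ends = []
    for a, b in zip(edges[:-1], edges[1:]):
        mask = (t >= a) & (t <= b)
        if mask.sum() < 2:
            raise ValueError("too few homopolymer beads in a subaxis interval")
        seg_pts = pts[mask]
        d = _principal_direction(seg_pts)
        if d @ major < 0:
            d = -d
        c = seg_pts.mean(axis=0)
        u = (seg_pts - c) @ d
        seg_ends.append((c + u.min() * d, c + u.max() * d))
    nodes = [seg_ends[0][0]]
    for (_, end_prev), (start_next, _) in zip(seg_ends[:-1], seg_ends[1:]):
        nodes.append(0.5 * (end_prev + start_next))
    nodes.append(seg_ends[-1][1])
    return AxisModel(np.array(nodes))


# ---------------------------------------------------------------------------
# order parameter


def order_parameter(vectors: RodVectorSet | np.ndarray) -> tuple[float, np.ndarray]:
    """Nematic order parameter S and director u_d of a rod-vector set.

    S is the largest eigenvalue of Q = (3/2) <u u> - (1/2) I and u_d the
    corresponding eigenvector, which is exactly the direction maximizing
    <(3 cos^2 theta - 1)/2>.  S = 1 for perfectly parallel rods, ~0 for an
    isotropic set, -1/2 for rods all perpendicular to the director.
    """
    u = vectors.vectors if isinstance(vectors, RodVectorSet) else np.asarray(vectors)
    if u.ndim != 2 or u.shape[1] != 3 or len(u) == 0:
        raise ValueError("need a non-empty (n, 3) array of rod vectors")
    norms = np.linalg.norm(u, axis=1)
    if np.any(norms == 0):
        raise ValueError("rod vectors must be nonzero")
    u = u / norms[:, None]
    q = 1.5 * (u.T @ u) / len(u) - 0.5 * np.eye(3)
    w, v = np.linalg.eigh(q)
    s = float(w[-1])
    director = v[:, -1]
    k = int(np.argmax(np.abs(director)))
    if director[k] < 0:
        director = -director
    return s, director


# ---------------------------------------------------------------------------
# twist profile and pitches


def _centers_near_axis(
    centers: np.ndarray, axis: AxisModel, frame: SystemState | None
) -> np.ndarray:
    """Re-image rod centers into the periodic image nearest the axis.

    Chains are unwrapped individually, so two chains of one aggregate can
    land in different periodic images; anchoring on the axis midpoint makes
    axial/azimuthal coordinates image-independent.
    """
    if frame is None:
        return centers
    anchor = 0.5 * (axis.nodes[0] + axis.nodes[-1])
    rel = centers - anchor
    rel -= frame.box_length * np.round(rel / frame.box_length)
    return anchor + rel


@dataclass
class CosThetaProfile:
    """cos(theta_i) of each rod block versus its axial position, sorted."""

    position: np.ndarray
    cos_theta: np.ndarray
    chain_ids: np.ndarray


def cos_theta_profile(
    frame: SystemState,
    axis: AxisModel,
    u_d: np.ndarray,
    rods: RodVectorSet | None = None,
) -> CosThetaProfile:
    """Twist descriptor cos(theta_i) = u_i . u_d along the major axis.

    The axial position of a rod block is the projection of its center of
    mass onto the axis.
    """
    if rods is None:
        rods = rod_vectors(frame)
    if len(rods) == 0:
        raise ValueError("no rod blocks in frame")
    centers = _centers_near_axis(rods.centers, axis, frame)
    pos = axis.axial_coordinate(centers)
    cos = rods.vectors @ np.asarray(u_d, dtype=float)
    order = np.argsort(pos)
    return CosThetaProfile(pos[order], cos[order], rods.chain_ids[order])


@dataclass
class PitchEstimate:
    """A pitch measurement: value +/- error with a fit-quality score.

    ``ok`` is False for indeterminate results (no resolvable period or a
    degenerate geometry); then ``value`` is None and ``note`` says why.
    """

    value: float | None
    error: float | None = None
    quality: float = 0.0
    ok: bool = True
    note: str = ""

    def __bool__(self) -> bool:
        return self.ok


def _indeterminate(note: str) -> PitchEstimate:
    return PitchEstimate(value=None, error=None, quality=0.0, ok=False, note=note)


def twisting_pitch_P2(
    profile: CosThetaProfile,
    bin_width: float = 1.0,
    min_amplitude: float = 0.2,
    min_r2: float = 0.4,
) -> PitchEstimate:
    """Local twisting pitch P2: axial period of the cos(theta) oscillation.

    The profile is binned at bead resolution (1 sigma), a sinusoid
    A cos(2 pi z / P + phi) + c is fitted with a period scan plus local
    refinement, and the period is reported.  Indeterminate when the profile
    spans less than one period or carries no oscillation (flat profile).
    """
    z_raw = np.asarray(profile.position, dtype=float)
    c_raw = np.asarray(profile.cos_theta, dtype=float)
    if len(z_raw) < 6:
        return _indeterminate("too few rod blocks for a period estimate")
    edges = np.arange(z_raw.min(), z_raw.max() + bin_width, bin_width)
    if len(edges) < 6:
        return _indeterminate("profile spans too few bins")
    which = np.clip(np.digitize(z_raw, edges) - 1, 0, len(edges) - 2)
    counts = np.bincount(which, minlength=len(edges) - 1)
    sums = np.bincount(which, weights=c_raw, minlength=len(edges) - 1)
    occupied = counts > 0
    z = (edges[:-1] + 0.5 * bin_width)[occupied]
    c = sums[occupied] / counts[occupied]
    span = z[-1] - z[0]
    if np.std(c) < 1e-12:
        return _indeterminate("constant profile (untwisted)")

    def residual_stats(k: float) -> tuple[float, np.ndarray]:
        basis = np.column_stack([np.cos(k * z), np.sin(k * z), np.ones_like(z)])
        coef, *_ = np.linalg.lstsq(basis, c, rcond=None)
        res = c - basis @ coef
        return float(np.sum(res**2)), coef

    k_lo = 2.0 * math.pi / (2.0 * span)  # period at most twice the span
    k_hi = 2.0 * math.pi / max(3.0 * bin_width, 2.0)
    if k_hi <= k_lo:
        return _indeterminate("profile spans less than one resolvable period")
    grid = np.linspace(k_lo, k_hi, 800)
    sse = np.array([residual_stats(k)[0] for k in grid])
    k0 = grid[int(np.argmin(sse))]
    dk = grid[1] - grid[0]
    ref = optimize.minimize_scalar(
        lambda k: residual_stats(k)[0],
        bounds=(max(k_lo, k0 - 2 * dk), min(k_hi, k0 + 2 * dk)),
        method="bounded",
    )
    k_best = float(ref.x)
    sse_best, coef = residual_stats(k_best)
    sst = float(np.sum((c - c.mean()) ** 2))
    r2 = 1.0 - sse_best / sst if sst > 0 else 0.0
    amplitude = math.hypot(coef[0], coef[1])
    period = 2.0 * math.pi / k_best
    if amplitude < min_amplitude:
        return _indeterminate("oscillation amplitude below threshold")
    if r2 < min_r2:
        return _indeterminate("sinusoid fit quality below threshold")
    if period > span:
        return _indeterminate("profile spans less than one full period")
    # parameter error from a final nonlinear fit around the scan optimum
    err = None
    try:
        import warnings

        phi0 = math.atan2(-coef[1], coef[0])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, pcov = optimize.curve_fit(
            lambda zz, a, p, phi, off: a * np.cos(2 * np.pi * zz / p + phi) + off,
                z, c, p0=[amplitude, period, phi0, float(coef[2])], maxfev=5000,
            )
        if np.all(np.isfinite(pcov)):
            err = float(np.sqrt(pcov[1, 1]))
            period = float(abs(popt[1]))
    except Exception:
        pass
    return PitchEstimate(value=float(period), error=err, quality=float(r2), ok=True)


def _orthonormal_basis(d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    d = d / np.linalg.norm(d)
    helper = np.array([1.0, 0.0, 0.0])
    if abs(d[0]) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(d, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(d, e1)
    return e1, e2


def screw_pitch_P1(
    frame: SystemState,
    axis: AxisModel,
    rods: RodVectorSet | None = None,
    min_quality: float = 0.5,
    min_radius: float = 0.75,
    min_span: float = 4.0,
) -> PitchEstimate:
    """Screw pitch P1 of the helical copolymer string around the bundle.

    The azimuthal angle phi of each copolymer rod-block center about the
    axis is treated as a helical phase phi = k z + phi0; the winding number
    k is found by maximizing the helical order function
    H(k) = |< exp(i (phi_j - k z_j)) >| over both handednesses, and
    P1 = 2 pi / |k|.  H in [0, 1] doubles as the fit quality: an axially
    uniform ring coverage (no winding) has no sharp H peak and the result
    is indeterminate.  Only |P1| is reported (achiral model: both
    handednesses occur).
    """
    if rods is None:
        rods = rod_vectors(frame)
    if len(rods) < 6:
        return _indeterminate("too few rod blocks for a pitch estimate")
    centers = _centers_near_axis(rods.centers, axis, frame)
    z = axis.axial_coordinate(centers)
    # radial vectors about the overall axis direction
    d = axis.direction
    origin = axis.nodes[0]
    rel = centers - origin
    rad = rel - np.outer(rel @ d, d)
    radii = np.linalg.norm(rad, axis=1)
    if np.median(radii) < min_radius:
        return _indeterminate("rod centers lie on the axis (no radial offset)")
    span = z.max() - z.min()
    if span < min_span:
        return _indeterminate("axial span too short for a pitch estimate")
    e1, e2 = _orthonormal_basis(d)
    phi = np.arctan2(rad @ e2, rad @ e1)
    phase = np.exp(1j * phi)

    def h_of(k: float) -> float:
        return abs(np.mean(phase * np.exp(-1j * k * z)))

    k_max = 2.0 * math.pi / 2.0          # minimum pitch 2 sigma
    k_min = 2.0 * math.pi / (2.0 * span)  # at least half a turn over the span
    grid = np.concatenate([-np.linspace(k_min, k_max, 2048),
                           np.linspace(k_min, k_max, 2048)])
    h = np.array([h_of(k) for k in grid])
    k0 = grid[int(np.argmax(h))]
    dk = math.pi * 2.0 / (2.0 * span) / 8.0
    ref = optimize.minimize_scalar(
        lambda k: -h_of(k), bounds=(k0 - 2 * dk, k0 + 2 * dk), method="bounded"
    )
    k_best = float(ref.x)
    quality = h_of(k_best)
    if quality < min_quality:
        return _indeterminate("no coherent winding (helical order below threshold)")
    pitch = 2.0 * math.pi / abs(k_best)
    # error from the half-width of the H peak
    target = quality * 0.9
    k_step = dk / 4.0
    width = k_step
    while width < 20 * dk and min(h_of(k_best - width), h_of(k_best + width)) > target:
        width += k_step
    err = 2.0 * math.pi * width / k_best**2
    return PitchEstimate(
        value=float(pitch), error=float(abs(err)), quality=float(quality), ok=True
    )


# ---------------------------------------------------------------------------
# morphology classification


@dataclass
class ClassifierConfig:
    """Thresholds of the morphology rules (declared, tunable heuristics)."""

    cluster_cutoff: float = 1.5
    unimer_threshold: float = 0.9
    bin_width: float = 1.0
    abacus_min_disks: int = 3
    abacus_min_rods_per_disk: float = 4.0
    abacus_min_gap_bins: int = 2
    abacus_gap_occupancy: float = 0.10
    abacus_max_unimer_fraction: float = 0.3
    helix_min_quality: float = 0.5
    helix_max_unimer_fraction: float = 0.3
    n_subaxes: int = 1


@dataclass
class MorphologyReport:
    """Morphology label plus every structural descriptor of one frame."""

    label: str
    order_parameter: float
    director: np.ndarray
    unimer_fraction: float
    n_clusters: int
    p1: PitchEstimate | None = None
    p2: PitchEstimate | None = None

    @property
    def p1_value(self) -> float:
        return self.p1.value if (self.p1 and self.p1.ok) else math.nan

    @property
    def p2_value(self) -> float:
        return self.p2.value if (self.p2 and self.p2.ok) else math.nan


def _abacus_like(z: np.ndarray, cfg: ClassifierConfig) -> bool:
    """Discrete-disk test on the axial density of rod-block centers.

    The histogram (1-sigma bins) is segmented into contiguous occupied
    blobs; empty runs shorter than ``abacus_min_gap_bins`` are bridged (a
    disk several bins wide may contain incidental holes).  A blob counts
    as a disk when it holds at least ``abacus_min_rods_per_disk`` rods —
    a sparsely sampled helical string leaves only single-rod blobs and
    never qualifies.  The configuration is an abacus when there are at
    least ``abacus_min_disks`` disks and the mean density in the gaps
    between them is below ``abacus_gap_occupancy`` of the mean in-disk
    density.
    """
    edges = np.arange(z.min() - cfg.bin_width, z.max() + 2 * cfg.bin_width,
                      cfg.bin_width)
    hist, _ = np.histogram(z, bins=edges)
    if hist.max() == 0:
        return False
    occupied = hist > 0
    # bridge empty runs shorter than the minimum gap
    blobs: list[tuple[int, int]] = []  # [start, end) bin ranges
    i = 0
    n = len(hist)
    while i < n:
        if not occupied[i]:
            i += 1
            continue
        j = i
        while j < n:
            if occupied[j]:
                j += 1
                continue
            k = j
            while k < n and not occupied[k]:
                k += 1
            if k - j < cfg.abacus_min_gap_bins and k < n:
                j = k  # short hole inside a disk: bridge it
            else:
                break
        blobs.append((i, j))
        i = j
    disks = [
        (a, b) for a, b in blobs if hist[a:b].sum() >= cfg.abacus_min_rods_per_disk
    ]
    if len(disks) < cfg.abacus_min_disks:
        return False
    disk_density = np.mean([hist[a:b].mean() for a, b in disks])
    gap_bins = np.concatenate(
        [hist[b:a2] for (_, b), (a2, _) in zip(disks[:-1], disks[1:])]
    )
    if len(gap_bins) == 0:
        return False
    return float(gap_bins.mean()) < cfg.abacus_gap_occupancy * disk_density


def classify_morphology(
    frame: SystemState, config: ClassifierConfig | None = None
) -> MorphologyReport:
    """Assign a morphology label by ordered rules and report all descriptors.

    (i) ``unimers`` when more than ``unimer_threshold`` of the copolymers are
    free; (ii) ``abacus`` when the axial density of aggregated copolymer rod
    centers along the bundle axis shows discrete disks with near-empty gaps
    and nearly all copolymers are incorporated (disks absorb the chains);
    (iii) ``helix`` when the screw pitch is determinate with sufficient
    helical order and most copolymers are incorporated in the aggregate (a
    sparsely coated fiber shedding many free chains is a plain fiber even
    when its sparse coating admits a winding fit); (iv) ``plain_fiber``
    otherwise.
    """
    cfg = config or ClassifierConfig()
    labels = find_clusters(frame, cutoff=cfg.cluster_cutoff)
    is_cop = chain_is_copolymer(frame)
    uf = unimer_fraction(labels, is_cop)
    n_clusters = len(np.unique(labels))

    sizes = np.bincount(labels)
    aggregated = sizes[labels] > 1  # per chain
    agg_cop_chains = np.flatnonzero(aggregated & is_cop)
    all_rods = rod_vectors(frame)
    rods_for_s = (
        rod_vectors(frame, chain_subset=agg_cop_chains)
        if len(agg_cop_chains)
        else all_rods
    )
    s_val, director = (
        order_parameter(rods_for_s) if len(rods_for_s) else (math.nan, np.zeros(3))
    )

    if uf > cfg.unimer_threshold or len(agg_cop_chains) == 0:
        return MorphologyReport(
            label="unimers",
            order_parameter=s_val,
            director=director,
            unimer_fraction=uf,
            n_clusters=n_clusters,
        )

    # restrict pitch analysis to copolymers aggregated with the bundle
    homo_chains = np.flatnonzero(~is_cop)
    if len(homo_chains):
        bundle_labels = set(labels[homo_chains].tolist())
        fiber_chains = np.array(
            [c for c in agg_cop_chains if labels[c] in bundle_labels], dtype=np.int64
        )
        if len(fiber_chains) == 0:
            fiber_chains = agg_cop_chains
    else:
        fiber_chains = agg_cop_chains
    rods = rod_vectors(frame, chain_subset=fiber_chains)

    axis = bundle_axis(frame, n_subaxes=cfg.n_subaxes)
    z = axis.axial_coordinate(_centers_near_axis(rods.centers, axis, frame))
    p1 = screw_pitch_P1(frame, axis, rods=rods, min_quality=cfg.helix_min_quality)
    try:
        profile = cos_theta_profile(frame, axis, director, rods=rods)
        p2 = twisting_pitch_P2(profile, bin_width=cfg.bin_width)
    except ValueError:
        p2 = _indeterminate("no rod blocks for a twist profile")

    if _abacus_like(z, cfg) and uf <= cfg.abacus_max_unimer_fraction:
        label = "abacus"
    elif p1.ok and uf <= cfg.helix_max_unimer_fraction:
        label = "helix"
    else:
        label = "plain_fiber"
    return MorphologyReport(
        label=label,
        order_parameter=s_val,
        director=director,
        unimer_fraction=uf,
        n_clusters=n_clusters,
        p1=p1,
        p2=p2,
    )


def analyze_trajectory(traj, config: ClassifierConfig | None = None, frames=None):
    """Per-frame morphology records of a trajectory as a pandas DataFrame."""
    import pandas as pd

    rows = []
    indices = range(traj.n_frames) if frames is None else frames
    for i in indices:
        frame = traj.frame(i)
        rep = classify_morphology(frame, config)
        rows.append(
            {
                "step": traj.steps[i],
                "label": rep.label,
                "S": rep.order_parameter,
                "P1": rep.p1_value,
                "P2": rep.p2_value,
                "unimer_fraction": rep.unimer_fraction,
                "n_clusters": rep.n_clusters,
            }
        )
    return pd.DataFrame(rows)


__all__ = [
    "RodVectorSet",
    "AxisModel",
    "CosThetaProfile",
    "PitchEstimate",
    "ClassifierConfig",
    "MorphologyReport",
    "chain_is_copolymer",
    "rod_vectors",
    "find_clusters",
    "unimer_fraction",
    "bundle_axis",
    "order_parameter",
    "cos_theta_profile",
    "twisting_pitch_P2",
    "screw_pitch_P1",
    "classify_morphology",
    "analyze_trajectory",
]
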