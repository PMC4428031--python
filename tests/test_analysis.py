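"""Structure descriptors: clusters, axis, order parameter, pitches, labels."""

import math

import numpy as np
import pytest

from conftest import make_bare_state
from rodcoil.analysis import (
    AxisModel,
    ClassifierConfig,
    CosThetaProfile,
    RodVectorSet,
    bundle_axis,
    chain_is_copolymer,
    classify_morphology,
    cos_theta_profile,
    find_clusters,
    order_parameter,
    rod_vectors,
    screw_pitch_P1,
    twisting_pitch_P2,
    unimer_fraction,
)
from rodcoil.fixtures import (
    HelixSpec,
    make_dispersed_unimers,
    make_ideal_abacus,
    make_ideal_helix,
    make_isotropic_rods,
)
from rodcoil.model import SPECIES_HOMO, SPECIES_ROD


# ---------------------------------------------------------------------------
# clustering


class TestClusters:
    def test_two_close_rods_form_one_cluster(self):
        state = make_bare_state(
            [[5, 5, 5], [5, 5, 6]], [SPECIES_ROD, SPECIES_ROD], box=20.0,
            chain_id=[0, 1],
        )
        labels = find_clusters(state, cutoff=1.5)
        assert labels[0] == labels[1]

    def test_distant_chains_stay_separate(self):
        state = make_bare_state(
            [[2, 2, 2], [12, 12, 12]], [SPECIES_ROD, SPECIES_ROD], box=30.0,
            chain_id=[0, 1],
        )
        labels = find_clusters(state, cutoff=1.5)
        assert labels[0] != labels[1]

    def test_nonpositive_cutoff_rejected(self):
        state = make_bare_state([[1, 1, 1]], [SPECIES_ROD], box=10.0)
        with pytest.raises(ValueError):
            find_clusters(state, cutoff=0.0)

    def test_matches_brute_force_union_find(self):
        rng = np.random.default_rng(3)
        for trial in range(10):
            n_chains, box, cutoff = 20, 18.0, 1.5
            pos = np.repeat(rng.uniform(0, box, (n_chains, 3)), 2, axis=0)
            pos[1::2] += rng.normal(0, 0.3, (n_chains, 3))
            chain_id = np.repeat(np.arange(n_chains), 2)
            state = make_bare_state(
                np.mod(pos, box), [SPECIES_ROD] * 2 * n_chains, box, chain_id
            )
            labels = find_clusters(state, cutoff)
            # brute-force union-find over minimum-image bead distances
            parent = list(range(n_chains))

            def find(a):
                while parent[a] != a:
                    parent[a] = parent[parent[a]]
                    a = parent[a]
                return a

            for i in range(2 * n_chains):
                for j in range(i + 1, 2 * n_chains):
                    if chain_id[i] == chain_id[j]:
                        continue
                    d = state.positions[i] - state.positions[j]
                    d -= box * np.round(d / box)
                    if np.linalg.norm(d) <= cutoff:
                        parent[find(chain_id[i])] = find(chain_id[j])
            ref = np.array([find(c) for c in range(n_chains)])
            # same partition up to relabeling
            for a in range(n_chains):
                for b in range(n_chains):
                    assert (labels[a] == labels[b]) == (ref[a] == ref[b])


class TestUnimerFraction:
    def test_all_singletons(self):
        labels = np.arange(10)
        assert unimer_fraction(labels, np.ones(10, bool)) == 1.0

    def test_single_cluster(self):
        labels = np.zeros(10, dtype=int)
        assert unimer_fraction(labels, np.ones(10, bool)) == 0.0

    def test_partial_count_excludes_homopolymers(self):
        # chains 0..3 homopolymers in one cluster; 12 copolymers, 3 free
        labels = np.array([0, 0, 0, 0] + [0] * 9 + [1, 2, 3])
        is_cop = np.array([False] * 4 + [True] * 12)
        assert unimer_fraction(labels, is_cop) == pytest.approx(0.25)


# ---------------------------------------------------------------------------
# axis


class TestBundleAxis:
    def test_straight_line_recovers_z(self):
        z = np.linspace(0, 30, 41)
        pos = np.column_stack([np.full_like(z, 5.0), np.full_like(z, 5.0), z + 10])
        state = make_bare_state(pos, [SPECIES_HOMO] * len(z), box=100.0,
                                chain_id=np.zeros(len(z), dtype=int))
        axis = bundle_axis(state)
        assert abs(axis.direction @ [0, 0, 1]) == pytest.approx(1.0, abs=1e-9)

    def test_equivariance_under_rotation(self):
        rng = np.random.default_rng(0)
        z = np.linspace(0, 30, 41)
        base = np.column_stack([np.zeros_like(z), np.zeros_like(z), z])
        a = 0.7
        rot = np.array([[np.cos(a), 0, np.sin(a)], [0, 1, 0], [-np.sin(a), 0, np.cos(a)]])
        pos = base @ rot.T + 40.0
        state = make_bare_state(pos, [SPECIES_HOMO] * len(z), box=100.0,
                                chain_id=np.zeros(len(z), dtype=int))
        axis = bundle_axis(state)
        expected = rot @ np.array([0, 0, 1.0])
        assert abs(axis.direction @ expected) == pytest.approx(1.0, abs=1e-6)

    def test_two_subaxes_fit_a_gently_bent_fiber(self):
        """Two straight halves meeting at 170 degrees are recovered within 1 deg."""
        bend = math.radians(5.0)  # each half tilts 5 deg from z: 170 deg joint
        t = np.linspace(0, 20, 80)
        d1 = np.array([math.sin(-bend), 0, math.cos(bend)])
        d2 = np.array([math.sin(bend), 0, math.cos(bend)])
        half1 = 50.0 + (t[:, None] - 20) * d1
        half2 = 50.0 + t[:, None] * d2
        pos = np.vstack([half1, half2])
        state = make_bare_state(pos, [SPECIES_HOMO] * len(pos), box=150.0,
                                chain_id=np.zeros(len(pos), dtype=int))
        axis = bundle_axis(state, n_subaxes=2)
        assert axis.n_segments == 2
        for seg_dir, gen_dir in zip(axis.segment_directions, (d1, d2)):
            angle = math.degrees(math.acos(np.clip(abs(seg_dir @ gen_dir), 0, 1)))
            assert angle < 1.0

    def test_requires_homopolymer_beads(self):
        state = make_bare_state([[1, 1, 1], [2, 2, 2]], [SPECIES_ROD] * 2, box=10.0)
        with pytest.raises(ValueError):
            bundle_axis(state)


# ---------------------------------------------------------------------------
# order parameter


class TestOrderParameter:
    def test_parallel_rods(self):
        u = np.tile([0.0, 0.0, 1.0], (50, 1))
        s, d = order_parameter(u)
        assert s == pytest.approx(1.0)
        assert abs(d @ [0, 0, 1]) == pytest.approx(1.0)

    def test_two_orthogonal_vectors(self):
        s, _ = order_parameter(np.array([[1.0, 0, 0], [0, 1.0, 0]]))
        assert s == pytest.approx(0.25)

    def test_single_vector_is_its_own_director(self):
        s, _ = order_parameter(make_isotropic_rods(1, seed=0))
        assert s == pytest.approx(1.0)

    def test_isotropic_set_is_disordered(self):
        s, _ = order_parameter(make_isotropic_rods(10_000, seed=1))
        assert s < 0.05

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            order_parameter(np.zeros((3, 3)))

    def test_eigen_decomposition_matches_sphere_grid_maximization(self):
        """The Q-tensor route equals brute-force director search on a grid."""
        # Fibonacci sphere with ~2e4 directions: ~1.5e-3 resolution in S
        m = 20_000
        golden = (1 + 5**0.5) / 2
        k = np.arange(m)
        zs = 1 - 2 * (k + 0.5) / m
        theta = 2 * np.pi * k / golden
        r = np.sqrt(1 - zs**2)
        dirs = np.column_stack([r * np.cos(theta), r * np.sin(theta), zs])
        rng = np.random.default_rng(11)
        for _ in range(40):
            u = rng.standard_normal((20, 3))
            u /= np.linalg.norm(u, axis=1, keepdims=True)
            s_eig, _ = order_parameter(u)
            proj = (u @ dirs.T) ** 2
            s_grid = (1.5 * proj.mean(axis=0) - 0.5).max()
            assert s_eig == pytest.approx(s_grid, abs=2e-3)
            assert s_eig >= s_grid - 1e-12  # eigenvalue is the true maximum

    def test_s_decreases_monotonically_with_angular_noise(self):
        rng = np.random.default_rng(5)
        widths = [0.0, 0.1, 0.25, 0.5, 1.0]
        values = []
        for w in widths:
            u = np.tile([0.0, 0.0, 1.0], (4000, 1)) + rng.normal(0, w, (4000, 3))
            u /= np.linalg.norm(u, axis=1, keepdims=True)
            values.append(order_parameter(u)[0])
        assert all(a > b for a, b in zip(values[:-1], values[1:]))


# ---------------------------------------------------------------------------
# twist profile and pitches


def staircase_rods(period: float, extent: float = 80.0, n: int = 160) -> RodVectorSet:
    """Rods rotating in the x-z plane with the stated axial period."""
    z = np.linspace(0.0, extent, n)
    alpha = 2 * np.pi * z / period
    u = np.column_stack([np.sin(alpha), np.zeros_like(z), np.cos(alpha)])
    centers = np.column_stack([np.zeros_like(z), np.zeros_like(z), z])
    return RodVectorSet(u, centers, np.arange(n, dtype=np.int64))


def straight_axis(extent: float = 80.0) -> AxisModel:
    return AxisModel(np.array([[0.0, 0.0, 0.0], [0.0, 0.0, extent]]))


class TestCosThetaProfile:
    def test_parallel_rods_give_unity(self):
        rods = RodVectorSet(
            np.tile([0.0, 0, 1.0], (10, 1)),
            np.column_stack([np.zeros(10), np.zeros(10), np.arange(10.0)]),
            np.arange(10, dtype=np.int64),
        )
        prof = cos_theta_profile(None, straight_axis(), np.array([0, 0, 1.0]), rods=rods)
        assert np.allclose(prof.cos_theta, 1.0)

    def test_perpendicular_rods_give_zero(self):
        rods = RodVectorSet(
            np.tile([1.0, 0, 0.0], (10, 1)),
            np.column_stack([np.zeros(10), np.zeros(10), np.arange(10.0)]),
            np.arange(10, dtype=np.int64),
        )
        prof = cos_theta_profile(None, straight_axis(), np.array([0, 0, 1.0]), rods=rods)
        assert np.allclose(prof.cos_theta, 0.0)

    def test_twisted_staircase_reproduces_generator_sinusoid(self):
        period = 17.0
        rods = staircase_rods(period)
        s, u_d = order_parameter(rods)
        prof = cos_theta_profile(None, straight_axis(), u_d, rods=rods)
        # the director is degenerate in the rotation plane, so compare
        # against the generator sinusoid with a fitted phase
        z, c = prof.position, prof.cos_theta
        basis = np.column_stack([np.cos(2 * np.pi * z / period),
                                 np.sin(2 * np.pi * z / period)])
        coef, *_ = np.linalg.lstsq(basis, c, rcond=None)
        assert np.hypot(*coef) == pytest.approx(1.0, abs=1e-9)
        assert np.abs(c - basis @ coef).max() < 1e-6

    def test_positions_are_sorted_axial_projections(self):
        rods = staircase_rods(20.0)
        prof = cos_theta_profile(None, straight_axis(), np.array([0, 0, 1.0]), rods=rods)
        assert np.all(np.diff(prof.position) >= 0)


class TestTwistingPitch:
    @pytest.mark.parametrize("period", [13.4, 17.0, 25.6])
    def test_recovers_generator_period(self, period):
        rods = staircase_rods(period)
        _, u_d = order_parameter(rods)
        prof = cos_theta_profile(None, straight_axis(), u_d, rods=rods)
        est = twisting_pitch_P2(prof)
        assert est.ok
        assert est.value == pytest.approx(period, abs=0.5)

    def test_constant_profile_is_indeterminate(self):
        z = np.linspace(0, 40, 80)
        prof = CosThetaProfile(z, np.ones_like(z), np.arange(80, dtype=np.int64))
        est = twisting_pitch_P2(prof)
        assert not est.ok and est.value is None

    def test_less_than_one_period_is_indeterminate(self):
        rods = staircase_rods(200.0, extent=40.0)
        _, u_d = order_parameter(rods)
        prof = cos_theta_profile(None, straight_axis(40.0), u_d, rods=rods)
        assert not twisting_pitch_P2(prof).ok


class TestScrewPitch:
    @pytest.mark.parametrize("pitch,tol", [(17.7, 0.5), (41.2, 1.0)])
    def test_recovers_ideal_helix_pitch(self, pitch, tol):
        state = make_ideal_helix(HelixSpec(pitch=pitch, axial_extent=80.0))
        est = screw_pitch_P1(state, bundle_axis(state))
        assert est.ok
        assert est.value == pytest.approx(pitch, abs=tol)

    @pytest.mark.parametrize("pitch", [10.0, 17.7, 25.0, 41.2])
    def test_unbiased_under_positional_noise(self, pitch):
        """5% positional noise leaves the estimate within 3%."""
        state = make_ideal_helix(
            HelixSpec(pitch=pitch, axial_extent=80.0, noise=0.15, seed=8)
        )
        est = screw_pitch_P1(state, bundle_axis(state))
        assert est.ok
        assert abs(est.value - pitch) / pitch < 0.03

    def test_uniform_ring_coverage_is_indeterminate(self):
        rng = np.random.default_rng(2)
        n = 200
        z = rng.uniform(0, 60, n)
        phi = rng.uniform(0, 2 * np.pi, n)
        centers = np.column_stack([3 * np.cos(phi), 3 * np.sin(phi), z])
        rods = RodVectorSet(
            np.tile([0.0, 0, 1.0], (n, 1)), centers, np.arange(n, dtype=np.int64)
        )
        est = screw_pitch_P1(None, straight_axis(60.0), rods=rods)
        assert not est.ok

    def test_zero_radius_is_degenerate(self):
        state = make_ideal_helix(HelixSpec(pitch=17.7, radius=0.0, axial_extent=60.0))
        est = screw_pitch_P1(state, bundle_axis(state))
        assert not est.ok and "axis" in est.note


# ---------------------------------------------------------------------------
# classification and invariance


class TestClassifier:
    def test_ideal_abacus(self):
        rep = classify_morphology(make_ideal_abacus())
        assert rep.label == "abacus"
        assert rep.order_parameter > 0.7

    def test_ideal_helix(self):
        rep = classify_morphology(make_ideal_helix(HelixSpec()))
        assert rep.label == "helix"
        assert rep.p1.ok and rep.p1.value == pytest.approx(17.7, rel=0.05)

    def test_dispersed_unimers(self):
        rep = classify_morphology(make_dispersed_unimers())
        assert rep.label == "unimers"
        assert rep.unimer_fraction == pytest.approx(1.0)
        assert rep.p1 is None and rep.p2 is None

    def test_two_disk_precondition(self):
        with pytest.raises(ValueError):
            make_ideal_abacus(n_disks=1)

    def test_metrics_invariant_under_rigid_motion_and_wrap(self):
        spec = HelixSpec(pitch=17.7, twist_period=17.0, axial_extent=60.0)
        state = make_ideal_helix(spec)
        rep0 = classify_morphology(state)

        a = 1.1
        rot = np.array([[np.cos(a), -np.sin(a), 0],
                        [np.sin(a), np.cos(a), 0],
                        [0, 0, 1.0]]) @ np.array([[1, 0, 0],
                                                  [0, np.cos(0.6), -np.sin(0.6)],
                                                  [0, np.sin(0.6), np.cos(0.6)]])
        moved = state.copy()
        center = np.full(3, state.box_length / 2)
        moved.positions = (state.positions - center) @ rot.T + center + [40.0, -35.0, 80.0]
        moved.wrap()
        rep1 = classify_morphology(moved)
        assert rep1.label == rep0.label == "helix"
        assert rep1.order_parameter == pytest.approx(rep0.order_parameter, abs=1e-6)
        assert rep1.p1.value == pytest.approx(rep0.p1.value, rel=0.01)
        assert rep1.p2.value == pytest.approx(rep0.p2.value, rel=0.01)


class TestRodVectors:
    def test_unit_norm_and_chain_bookkeeping(self):
        state = make_ideal_helix(HelixSpec(axial_extent=40.0))
        rods = rod_vectors(state)
        assert np.allclose(np.linalg.norm(rods.vectors, axis=1), 1.0, atol=1e-9)
        is_cop = chain_is_copolymer(state)
        assert len(rods) == int(is_cop.sum())
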