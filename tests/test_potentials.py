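"""Potential energy terms, gradient consistency, cell-list correctness."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import brute_force_reference, make_bare_state
from rodcoil.model import (
    SPECIES_COIL,
    SPECIES_ROD,
    ChainSpec,
    ForceField,
    MixtureComposition,
    build_mixture,
)
from rodcoil.potentials import (
    NeighborList,
    angle_energy,
    angle_energy_force,
    bond_energy_force,
    lj_energy_force,
    total_forces,
)


class TestBond:
    def test_minimum(self):
        assert bond_energy_force(0.75, 10000.0, 0.75) == (0.0, 0.0)

    def test_quadratic_closed_form(self):
        e, f = bond_energy_force(0.76, 10000.0, 0.75)
        assert e == pytest.approx(0.5, rel=1e-9)
        assert f == pytest.approx(-100.0, rel=1e-9)

    def test_coincident_beads_rejected(self):
        with pytest.raises(ValueError):
            bond_energy_force(0.0, 10000.0, 0.75)

    @given(r=st.floats(0.3, 2.0))
    @settings(max_examples=30, derandomize=True)
    def test_force_is_negative_gradient(self, r):
        h = 1e-6
        _, f = bond_energy_force(r, 123.0, 0.75)
        ep, _ = bond_energy_force(r + h, 123.0, 0.75)
        em, _ = bond_energy_force(r - h, 123.0, 0.75)
        assert f == pytest.approx(-(ep - em) / (2 * h), abs=1e-4)


class TestAngle:
    def test_minimum_at_theta0(self):
        theta0 = math.radians(0.1)
        assert angle_energy(theta0, 10000.0, theta0) == 0.0

    def test_right_angle_closed_form(self):
        # cos(90 deg) = 0, cos(theta0 ~ 0) ~ 1 -> U ~ k_a / 2
        u = angle_energy(math.pi / 2, 10000.0, math.radians(0.1))
        assert u == pytest.approx(5000.0, abs=0.1)

    def test_degenerate_bond_rejected(self):
        p = np.zeros(3)
        with pytest.raises(ValueError):
            angle_energy_force(p, p, np.array([1.0, 0, 0]), 100.0, 0.0)

    def test_straight_chain_is_near_minimum(self):
        p = [np.array([0.0, 0, 0]), np.array([0.75, 0, 0]), np.array([1.5, 0, 0])]
        e, _ = angle_energy_force(*p, 10000.0, math.radians(0.1))
        assert e < 1e-4

    @settings(max_examples=25, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_forces_match_finite_difference(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.normal(0, 1.5, (3, 3))
        if min(np.linalg.norm(p[1] - p[0]), np.linalg.norm(p[2] - p[1])) < 0.2:
            return
        _, fs = angle_energy_force(p[0], p[1], p[2], 250.0, 0.3)
        h = 1e-6
        for bead in range(3):
            for k in range(3):
                pp, pm = p.copy(), p.copy()
                pp[bead, k] += h
                pm[bead, k] -= h
                ep, _ = angle_energy_force(*pp, 250.0, 0.3)
                em, _ = angle_energy_force(*pm, 250.0, 0.3)
                fd = -(ep - em) / (2 * h)
                assert fs[bead][k] == pytest.approx(fd, rel=1e-5, abs=1e-5)


class TestLennardJones:
    def test_zero_at_sigma_unshifted(self):
        e, _ = lj_energy_force(1.0, "RR", ForceField(eps_rr=2.0))
        assert e == pytest.approx(0.0, abs=1e-12)

    def test_rr_minimum_depth_equals_eps(self):
        ff = ForceField(eps_rr=2.1)
        e, f = lj_energy_force(2 ** (1 / 6), "RR", ff)
        assert e == pytest.approx(-2.1, rel=1e-12)
        assert f == pytest.approx(0.0, abs=1e-9)

    def test_beyond_rr_cutoff(self):
        assert lj_energy_force(2.6, "RR", ForceField()) == (0.0, 0.0)

    def test_wca_pairs_vanish_continuously_at_cutoff(self):
        ff = ForceField()
        for pair in ("RC", "CC"):
            e_in, _ = lj_energy_force(2 ** (1 / 6) - 1e-9, pair, ff)
            e_out, _ = lj_energy_force(2 ** (1 / 6) + 1e-9, pair, ff)
            assert abs(e_in) < 1e-6 and e_out == 0.0

    def test_coincident_beads_rejected(self):
        with pytest.raises(ValueError):
            lj_energy_force(0.0, "RR", ForceField())


class TestTotalForces:
    def test_isolated_rr_pair_at_minimum_has_zero_force(self):
        state = make_bare_state(
            [[5.0, 5.0, 5.0], [5.0 + 2 ** (1 / 6), 5.0, 5.0]],
            [SPECIES_ROD, SPECIES_ROD],
            box=20.0,
        )
        ff = ForceField(eps_rr=2.0)
        f, e = total_forces(state, ff)
        assert np.allclose(f, 0.0, atol=1e-9)
        assert e == pytest.approx(-2.0)

    def test_newtons_third_law(self, small_mixture):
        _, ff, state = small_mixture
        f, _ = total_forces(state, ff)
        assert np.abs(f.sum(axis=0)).max() < 1e-8

    def test_matches_brute_force_on_random_mixture_states(self):
        comp = MixtureComposition(3, ChainSpec(5, 2), ChainSpec(5), 1)
        ff = ForceField(eps_rr=2.2)
        rng = np.random.default_rng(0)
        for trial in range(6):
            state = build_mixture(comp, ff, box_length=12.0, seed=trial)
            # random perturbation makes every term (bond, angle, LJ) active
            state.positions += rng.normal(0, 0.08, state.positions.shape)
            state.wrap()
            f, e = total_forces(state, ff)
            f_ref, e_ref = brute_force_reference(state, ff)
            assert e == pytest.approx(e_ref, rel=1e-9)
            np.testing.assert_allclose(f, f_ref, rtol=1e-9, atol=1e-7)

    def test_cell_list_path_matches_brute_force(self):
        """Dense 100-bead states force the cell-list path; compare bead-by-bead."""
        ff = ForceField(eps_rr=1.8)
        rng = np.random.default_rng(7)
        for trial in range(12):
            n = 100
            pos = rng.uniform(0, 12.0, (n, 3))
            species = rng.integers(0, 3, n)
            state = make_bare_state(pos, species, box=12.0)
            nl = NeighborList(ff)
            nl.build(state)
            assert int(12.0 / nl.rlist) >= 3  # genuinely the cell path
            f, e = total_forces(state, ff, neighbors=nl)
            f_ref, e_ref = brute_force_reference(state, ff)
            assert e == pytest.approx(e_ref, rel=1e-9, abs=1e-9)
            np.testing.assert_allclose(f, f_ref, rtol=1e-9, atol=1e-6)

    def test_stale_list_is_rebuilt_automatically(self):
        ff = ForceField()
        state = make_bare_state(
            [[5.0, 5.0, 5.0], [7.0, 5.0, 5.0]], [SPECIES_ROD, SPECIES_ROD], box=20.0
        )
        nl = NeighborList(ff)
        nl.build(state)
        state.positions[1, 0] = 5.0 + 2 ** (1 / 6)  # moved farther than skin/2
        assert nl.is_stale(state)
        _, e = total_forces(state, ff, neighbors=nl)
        assert e == pytest.approx(-ff.eps_rr)

    def test_energy_invariant_under_rigid_motions(self):
        """Translation + rotation of an isolated cluster leave energy fixed."""
        comp = MixtureComposition(4, ChainSpec(5, 2), ChainSpec(6), 1)
        ff = ForceField(eps_rr=2.0)
        state = build_mixture(comp, ff, box_length=400.0, seed=3)
        _, e0 = total_forces(state, ff)
        center = state.positions.mean(axis=0)
        rng = np.random.default_rng(1)
        a, b, c = rng.uniform(0, 2 * np.pi, 3)
        rz = np.array([[np.cos(a), -np.sin(a), 0], [np.sin(a), np.cos(a), 0], [0, 0, 1]])
        ry = np.array([[np.cos(b), 0, np.sin(b)], [0, 1, 0], [-np.sin(b), 0, np.cos(b)]])
        rot = rz @ ry
        moved = state.copy()
        moved.positions = (state.positions - center) @ rot.T + center + [17.3, -4.2, 60.0]
        moved.wrap()
        _, e1 = total_forces(moved, ff)
        assert e1 == pytest.approx(e0, rel=1e-9)
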