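"""Relaxation dynamics: stiffness decay, spring forces, boundary update."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from turbisim import (
    BackboneTree,
    BoundaryState,
    SimParams,
    boundary_displacement,
    exclusion_radius,
    neighbor_displacement,
    nonneighbor_displacement,
    relax_step,
    stiffness,
    total_displacement,
    update_boundary,
)
from turbisim.relax import all_exclusion_radii

from conftest import random_tree


class TestStiffness:
    @pytest.mark.parametrize(
        "age_factor,expected_factor",
        [(0.0, 1.0), (1.0, math.exp(-1)), (10.0, math.exp(-10))],
    )
    def test_exponential_decay(self, age_factor, expected_factor):
        p = SimParams(K=0.3, tau=500.0)
        k = stiffness(t_now=age_factor * p.tau, t_birth=0.0, params=p)
        assert k == pytest.approx(p.K * expected_factor, rel=1e-12)

    def test_monotone_in_age(self):
        p = SimParams()
        ages = np.linspace(0, 5 * p.tau, 30)
        ks = [stiffness(a, 0.0, p) for a in ages]
        assert all(a > b for a, b in zip(ks, ks[1:]))
        assert all(k > 0 for k in ks)

    def test_negative_age_rejected(self):
        with pytest.raises(ValueError):
            stiffness(t_now=5.0, t_birth=10.0, params=SimParams())


class TestPairDisplacements:
    def test_neighbor_at_rest_length_is_zero(self):
        d = neighbor_displacement((0.0, 0.0), (1.0, 0.0), r0=1.0)
        assert np.allclose(d, 0.0)

    def test_neighbor_attracts_when_stretched(self):
        d = neighbor_displacement((0.0, 0.0), (2.0, 0.0), r0=1.0)
        assert np.allclose(d, (1.0, 0.0))

    def test_neighbor_repels_when_compressed(self):
        d = neighbor_displacement((0.0, 0.0), (0.5, 0.0), r0=1.0)
        assert np.allclose(d, (-0.5, 0.0))

    def test_coincident_neighbors_zero_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            d = neighbor_displacement((1.0, 1.0), (1.0, 1.0), r0=1.0)
        assert np.allclose(d, 0.0)
        assert any("coincident" in r.message for r in caplog.records)

    def test_nonneighbor_zero_at_and_beyond_cutoff(self):
        assert np.allclose(
            nonneighbor_displacement((0, 0), (2.0, 0.0), m_j=2.0), 0.0
        )
        assert np.allclose(
            nonneighbor_displacement((0, 0), (6.0, 0.0), m_j=2.0), 0.0
        )

    def test_nonneighbor_pushes_away_inside_range(self):
        d = nonneighbor_displacement((0.0, 0.0), (1.0, 0.0), m_j=2.0)
        assert np.allclose(d, (-1.0, 0.0))

    def test_coincident_nonneighbors_deterministic_kick(self):
        d1 = nonneighbor_displacement((0, 0), (0, 0), m_j=2.0, pair_ids=(3, 9))
        d2 = nonneighbor_displacement((0, 0), (0, 0), m_j=2.0, pair_ids=(3, 9))
        assert np.allclose(d1, d2)
        assert math.hypot(*d1) == pytest.approx(2.0)


class TestExclusionRadius:
    def test_floor_is_two_r0(self, chain_tree):
        # interior node with both neighbours at distance 1
        assert exclusion_radius(chain_tree, 2, r0=1.0) == pytest.approx(2.0)

    def test_stretched_edge_extends_radius(self):
        pos = np.array([[0.0, 0.0], [3.0, 0.0], [4.0, 0.0]])
        tree = BackboneTree(pos, [-1, 0, 1], [0, 0, 0])
        assert exclusion_radius(tree, 1, r0=1.0) == pytest.approx(3.0)
        assert exclusion_radius(tree, 2, r0=1.0) == pytest.approx(2.0)

    def test_leaf_with_close_neighbor(self, chain_tree):
        assert exclusion_radius(chain_tree, 4, r0=1.0) == pytest.approx(2.0)

    def test_vectorized_matches_scalar(self):
        rng = np.random.default_rng(0)
        tree = random_tree(rng, 40)
        m = all_exclusion_radii(tree, r0=1.0)
        for i in range(tree.n):
            assert m[i] == pytest.approx(exclusion_radius(tree, i, 1.0))


class TestBoundaryDisplacement:
    def test_zero_in_interior(self):
        b = BoundaryState(b=10.0, b_max=20.0)
        assert np.allclose(boundary_displacement((1.0, 2.0), b, r0=1.0), 0.0)

    def test_inward_spring_at_wall(self):
        b = BoundaryState(b=10.0, b_max=20.0)
        d = boundary_displacement((10.0, 0.0), b, r0=1.0)
        assert np.allclose(d, (-1.0, 0.0))

    def test_magnitude_ramps_linearly(self):
        b = BoundaryState(b=10.0, b_max=20.0)
        d = boundary_displacement((9.5, 0.0), b, r0=1.0)
        assert np.allclose(d, (-0.5, 0.0))


class TestTotalDisplacement:
    def test_equilibrium_pair_far_from_wall(self, far_boundary):
        pos = np.array([[0.0, 0.0], [1.0, 0.0]])
        tree = BackboneTree(pos, [-1, 0], [0, 0])
        s = total_displacement(tree, 1, far_boundary, SimParams())
        assert np.allclose(s, 0.0, atol=1e-12)

    def test_root_has_no_displacement(self, chain_tree, far_boundary):
        with pytest.raises(ValueError):
            total_displacement(chain_tree, 0, far_boundary, SimParams())

    def test_collinear_cancellation(self, far_boundary):
        # node 1 with a neighbour stretched to 2 r0 on one side and a
        # non-neighbour at r0 on the other: the two pulls cancel exactly
        pos = np.array([[0.0, 0.0], [2.0, 0.0], [1.0, 0.0]])
        #  root --(edge len 2)-- node1 ; node2 child of root at (1,0)
        tree = BackboneTree(pos, [-1, 0, 0], [0, 0, 0])
        p = SimParams()
        s = total_displacement(tree, 1, far_boundary, p)
        # neighbour (root) pulls by (2-1) toward root = (-1, 0);
        # non-neighbour node2 at distance 1 < m=2 pushes by (2-1) = (+1, 0)
        assert np.allclose(s, 0.0, atol=1e-12)


class TestRelaxStep:
    def test_chain_at_rest_is_fixed_point(self, chain_tree, far_boundary):
        p = SimParams()
        new = relax_step(chain_tree, far_boundary, t_now=1, params=p)
        assert np.allclose(new.positions, chain_tree.positions, atol=1e-12)

    def test_stretched_link_relaxes_monotonically(self, far_boundary):
        pos = np.array([[0.0, 0.0], [1.8, 0.0]])
        tree = BackboneTree(pos, [-1, 0], [0, 0])
        p = SimParams(K=0.1)
        lengths = [tree.edge_lengths()[0]]
        for t in range(1, 120):
            tree = relax_step(tree, far_boundary, t, p)
            lengths.append(tree.edge_lengths()[0])
        assert all(a >= b - 1e-12 for a, b in zip(lengths, lengths[1:]))
        assert lengths[-1] == pytest.approx(1.0, abs=1e-3)

    def test_old_nodes_barely_move(self, far_boundary):
        pos = np.array([[0.0, 0.0], [1.9, 0.0]])
        p = SimParams(K=0.1, tau=100.0)
        tree = BackboneTree(pos, [-1, 0], [0, 10])
        age = 1000 - 10
        new = relax_step(tree, far_boundary, t_now=1000, params=p)
        moved = np.hypot(*(new.positions[1] - tree.positions[1]))
        assert moved <= p.K * math.exp(-age / p.tau) * 0.9 + 1e-15

    def test_topology_and_root_preserved(self, small_run):
        # after a full (small) simulation the root never moved off the wall
        tree = small_run.tree
        b = small_run.boundary.b
        assert np.allclose(tree.positions[0], (-b, 0.0))


class TestBoundaryUpdate:
    def test_identity_at_target_porosity(self):
        p = SimParams(phi_target=0.75)
        bnd = BoundaryState(b=10.0, b_max=100.0)
        A_b = (1 - 0.75) * math.pi * 10.0**2
        assert update_boundary(bnd, A_b, p) == pytest.approx(10.0)

    def test_half_porosity_expands_by_sqrt2(self):
        p = SimParams(phi_target=0.75)
        bnd = BoundaryState(b=10.0, b_max=100.0)
        A_b = 0.5 * math.pi * 10.0**2  # phi = 0.5
        assert update_boundary(bnd, A_b, p) == pytest.approx(10.0 * math.sqrt(2))

    def test_capped_at_maximum_radius(self):
        p = SimParams(phi_target=0.75)
        bnd = BoundaryState(b=10.0, b_max=12.0)
        A_b = 0.5 * math.pi * 10.0**2
        assert update_boundary(bnd, A_b, p) == pytest.approx(12.0)

    def test_no_bone_area_rejected(self):
        with pytest.raises(ValueError):
            update_boundary(BoundaryState(b=5.0, b_max=10.0), 0.0, SimParams())

    @settings(deadline=None, max_examples=60)
    @given(
        b=st.floats(1.0, 50.0),
        phi=st.floats(0.01, 0.98),
        phi_target=st.floats(0.05, 0.95),
    )
    def test_unclamped_update_solves_target_exactly(self, b, phi, phi_target):
        """Plugging b' back into the porosity formula recovers the target."""
        p = SimParams(phi_target=phi_target)
        A_b = (1 - phi) * math.pi * b**2
        bnd = BoundaryState(b=b, b_max=1e9)
        b_new = update_boundary(bnd, A_b, p)
        if b_new > b:  # unclamped branch
            phi_new = 1 - A_b / (math.pi * b_new**2)
            assert phi_new == pytest.approx(phi_target, abs=1e-9)
        else:
            # clamped from below: porosity would have had to shrink the disc
            assert phi >= phi_target - 1e-12
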