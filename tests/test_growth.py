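"""Growth step and simulation-loop contracts."""

import numpy as np
import pytest

from turbisim import (
    SimParams,
    grow,
    local_density,
    seed_tree,
    select_growth_site,
    simulate,
)

from conftest import small_params


class TestSeedTree:
    def test_shape_and_root_placement(self):
        p = SimParams()
        tree, bnd = seed_tree(p)
        assert tree.n == 4
        assert tree.leaf_count() == 1
        assert np.allclose(tree.positions[0], (-bnd.b, 0.0))
        assert tree.degrees[0] == 1
        assert np.all(tree.birth_times == 0)

    def test_initial_porosity_matches_target(self):
        p = SimParams()
        tree, bnd = seed_tree(p)
        A_b = tree.total_length() * p.w
        phi0 = 1 - A_b / (np.pi * bnd.b**2)
        assert phi0 == pytest.approx(p.phi_target, abs=1e-9)


class TestLocalDensity:
    def test_isolated_node_sees_nothing(self):
        p = SimParams()
        tree, _ = seed_tree(p)
        # chain spacing is r0: the interior node sees both neighbours
        assert local_density(tree, 1, p.r0) == 2
        # tip sees only its parent
        assert local_density(tree, 3, p.r0) == 1

    def test_counts_exclude_self(self):
        p = SimParams()
        tree, _ = seed_tree(p)
        n = tree.n
        for i in range(n):
            assert 0 <= local_density(tree, i, p.r0) < n


class TestSiteSelection:
    def test_single_tip_always_chosen(self):
        p = SimParams()
        tree, _ = seed_tree(p)
        rng = np.random.default_rng(0)
        for _ in range(10):
            assert select_growth_site(tree, p, rng) == 3

    def test_inverse_density_weighting(self):
        # two long chains from the root; tip B has two bystander nodes
        # inside its counting ball, so its weight is 1/5 against tip A's
        # 1/3 and A should be picked 5/3 as often as B
        pos = [[0.0, 0.0]]
        parents = [-1]
        for k in range(1, 8):  # chain A along +x, tip A = node 7
            pos.append([float(k), 0.0])
            parents.append(k - 1)
        for k in range(1, 8):  # chain B along -x, tip B = node 14
            pos.append([-float(k), 0.0])
            parents.append(0 if k == 1 else 7 + k - 1)
        pos += [[-6.0, 1.0], [-6.0, 2.0]]  # bystander stub near tip B
        parents += [13, 15]
        from turbisim import BackboneTree

        tree = BackboneTree(np.array(pos), np.array(parents),
                            np.zeros(len(pos), dtype=np.int64))
        p = SimParams()
        assert set(tree.tips()) == {7, 14, 16}
        rng = np.random.default_rng(1)
        picks = [select_growth_site(tree, p, rng) for _ in range(5000)]
        frac_a = np.mean([s == 7 for s in picks])
        frac_b = np.mean([s == 14 for s in picks])
        assert frac_a / frac_b == pytest.approx(5.0 / 3.0, rel=0.15)

    def test_uniform_when_density_weighting_off(self):
        p = SimParams(density_weighting=False)
        res = simulate(small_params(density_weighting=False, t_max=60, t_B=41))
        assert res.tree.n > 10  # smoke: ablation variant runs


class TestGrow:
    def test_elongate_adds_one_keeps_leafcount(self):
        p = SimParams()
        tree, _ = seed_tree(p)
        rng = np.random.default_rng(0)
        leaves_before = tree.leaf_count()
        ev = grow(tree, 3, "elongate", t_now=1, params=p, rng=rng)
        assert tree.n == 5
        assert tree.leaf_count() == leaves_before
        assert ev.mode == "elongate"

    def test_fork_adds_two_and_a_leaf(self):
        p = SimParams()
        tree, _ = seed_tree(p)
        rng = np.random.default_rng(0)
        grow(tree, 3, "fork", t_now=1, params=p, rng=rng)
        assert tree.n == 6
        assert tree.leaf_count() == 2

    def test_child_placed_on_small_circle(self):
        p = SimParams()
        tree, _ = seed_tree(p)
        rng = np.random.default_rng(0)
        ev = grow(tree, 3, "elongate", t_now=2, params=p, rng=rng)
        child = ev.child_ids[0]
        d = np.hypot(*(tree.positions[child] - tree.positions[3]))
        assert d == pytest.approx(p.r0 / 10.0)
        assert tree.birth_times[child] == 2

    def test_fork_after_birth_rejected(self):
        p = SimParams(t_B=100, t_max=200)
        tree, _ = seed_tree(p)
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError):
            grow(tree, 3, "fork", t_now=150, params=p, rng=rng)

    def test_non_tip_site_rejected(self):
        p = SimParams()
        tree, _ = seed_tree(p)
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError):
            grow(tree, 1, "elongate", t_now=1, params=p, rng=rng)


class TestSimulate:
    def test_tree_remains_single_component(self, small_run):
        import networkx as nx

        g = small_run.tree.to_networkx()
        assert nx.is_tree(g)

    def test_leafcount_monotone_then_frozen(self, small_run):
        lt = small_run.leaf_trace
        t_B = small_run.params.t_B
        before = lt[:t_B]
        assert np.all(np.diff(before) >= 0)
        assert np.all(lt[t_B:] == lt[t_B])

    def test_same_seed_bitwise_identical(self, small_run_pair):
        a, b = small_run_pair
        assert np.array_equal(a.tree.positions, b.tree.positions)
        assert np.array_equal(a.tree.parents, b.tree.parents)
        assert a.boundary.b == b.boundary.b
        assert np.array_equal(a.phi_trace, b.phi_trace)

    def test_different_seeds_differ(self):
        a = simulate(small_params(seed=1, t_max=80, t_B=54))
        b = simulate(small_params(seed=2, t_max=80, t_B=54))
        assert not np.array_equal(a.tree.positions, b.tree.positions)

    def test_boundary_never_shrinks(self, small_run):
        assert np.all(np.diff(small_run.b_trace) >= -1e-12)

    def test_porosity_tracks_target(self, small_run):
        phi = small_run.phi_trace
        target = small_run.params.phi_target
        # after the brief seed transient the analytic porosity is pinned
        assert abs(phi[20:].mean() - target) < 0.01

    def test_snapshots_taken_at_requested_times(self):
        res = simulate(small_params(t_max=100, t_B=68), snapshot_times=(0.5, 1.0))
        assert set(res.snapshots) == {0.5, 1.0}
        assert res.snapshots[0.5].t == 50
        assert res.snapshots[0.5].tree.n <= res.tree.n

    def test_no_crossings_with_avoidance(self, small_run):
        assert small_run.collisions == 0

    def test_crossings_without_avoidance(self):
        res = simulate(small_params(avoidance=False, seed=3))
        assert res.collisions > 0

    def test_events_recorded_in_order(self):
        res = simulate(small_params(t_max=60, t_B=41), record_events=True)
        ts = [ev.t for ev in res.events]
        assert ts == sorted(ts)
        assert all(ev.mode in ("elongate", "fork") for ev in res.events)
        assert all(
            ev.mode == "elongate" for ev in res.events if ev.t >= res.params.t_B
        )


class TestAblationContrast:
    def test_density_rule_steers_growth_to_open_tips(self, small_run):
        """With the inverse-density rule, selected growth sites sit in
        measurably emptier neighbourhoods than the average tip; with the
        rule ablated the selection is uniform over tips."""
        from turbisim.growth import DENSITY_RADIUS_FACTOR
        from turbisim._kernels import count_within_radius

        tree = small_run.tree
        p_on = small_run.params
        p_off = p_on.replace(density_weighting=False)
        tips = tree.tips()
        dens = count_within_radius(
            tree.positions, tips, DENSITY_RADIUS_FACTOR * p_on.r0
        )
        dens_of = dict(zip(tips.tolist(), dens.tolist()))
        rng = np.random.default_rng(0)
        picked_on = [
            dens_of[select_growth_site(tree, p_on, rng)] for _ in range(2000)
        ]
        picked_off = [
            dens_of[select_growth_site(tree, p_off, rng)] for _ in range(2000)
        ]
        assert np.mean(picked_on) < np.mean(picked_off) - 0.2
        assert np.mean(picked_off) == pytest.approx(dens.mean(), rel=0.05)
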