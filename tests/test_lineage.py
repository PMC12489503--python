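"""Lineage tree analyses and the constraint-respecting mutation kernel."""

import numpy as np
import pytest

from protocrm.core import SimulationConfig, validate_metabolism
from protocrm.lineage import (LineageTree, count_evolvable_parameters,
                              lineage_enzyme_series, mutate_type,
                              quasi_species_count, significant_variants,
                              trunk, variants_per_period)
from protocrm.core import StructuralError
from protocrm.trajectory import Trajectory

from conftest import make_type


def chain_tree(n_variants, interval, extra_terminal_at=None):
    """Root plus a straight chain of variants born every ``interval``."""
    tree = LineageTree()
    tree.add(0, None, 0.0)
    prev = 0
    for k in range(1, n_variants + 1):
        tree.add(k, prev, k * interval)
        tree.close(prev, k * interval + interval / 2)
        prev = k
    if extra_terminal_at is not None:
        tree.add(prev + 1, prev, extra_terminal_at)
        tree.close(prev, extra_terminal_at + 1)
    return tree


def flat_trajectory(times, pops, b0=1.0, d=2):
    """Build a trajectory with given per-type population dicts and flat enzymes."""
    times = np.asarray(times, float)
    chem = np.zeros((times.size, 1))
    enz = {tid: np.tile(np.arange(1.0, d + 1) * (tid + 1), (times.size, 1))
           for tid in pops}
    dense = {tid: np.asarray(v, float) for tid, v in pops.items()}
    return Trajectory.from_dense(times, chem, dense, enz, b0=b0)


class TestTrunk:
    def test_single_root_is_its_own_trunk(self):
        tree = LineageTree()
        tree.add(0, None, 0.0)
        assert trunk(tree) == [0]
        assert significant_variants(tree) == set()

    def test_chain_in_birth_order(self):
        tree = chain_tree(2, 10.0)
        assert trunk(tree) == [0, 1, 2]
        assert significant_variants(tree) == {1}

    def test_longer_chain_excludes_terminal(self):
        tree = chain_tree(3, 10.0)
        assert significant_variants(tree) == {1, 2}

    def test_dominant_branch_selected_by_biomass(self):
        tree = LineageTree()
        tree.add(0, None, 0.0)
        tree.add(1, 0, 10.0)
        tree.add(2, 0, 20.0)
        times = np.linspace(0, 100, 11)
        traj = flat_trajectory(times, {
            0: np.full(11, 1.0),
            1: np.full(11, 50.0),   # dominant
            2: np.full(11, 5.0),
        })
        assert trunk(tree, traj) == [0, 1]

    def test_all_extinct_ends_at_last_survivor(self):
        tree = LineageTree()
        tree.add(0, None, 0.0)
        tree.add(1, 0, 5.0)
        tree.close(0, 30.0)
        tree.close(1, 20.0)
        assert trunk(tree) == [0]


class TestVariantsPerPeriod:
    @pytest.mark.parametrize("interval, period, expected", [
        (25_000.0, 2.5e5, 10.0),
        (5_000.0, 2.5e5, 50.0),
        (5_000.0, 2.5e4, 5.0),
    ])
    def test_mean_counts(self, interval, period, expected):
        """Regular significant-variant production binned by forcing period."""
        tau_end = 2 * 2.5e5
        n = int(tau_end / interval)
        tree = LineageTree()
        tree.add(0, None, 0.0)
        prev = 0
        # births at half-interval offsets so windows tile evenly
        for k in range(n):
            b = (k + 0.5) * interval
            tree.add(k + 1, prev, b)
            tree.close(prev, b + 1)
            prev = k + 1
        # extra terminal beyond the binned range so all others are significant
        tree.add(n + 1, prev, tau_end + 1.0)
        tree.close(prev, tau_end + 2.0)
        mean, counts = variants_per_period(tree, period, tau_end=tau_end)
        assert mean == expected
        assert np.all(counts == expected)

    def test_no_variants_gives_zero(self):
        tree = LineageTree()
        tree.add(0, None, 0.0)
        mean, counts = variants_per_period(tree, 10.0, tau_end=100.0)
        assert mean == 0.0

    def test_run_shorter_than_period_errors(self):
        tree = LineageTree()
        tree.add(0, None, 0.0)
        with pytest.raises(StructuralError):
            variants_per_period(tree, 1000.0, tau_end=10.0)


class TestQuasiSpecies:
    def test_single_type_constant_one(self):
        times = np.linspace(0, 10, 6)
        traj = flat_trajectory(times, {0: np.full(6, 40.0)})
        counts, mean = quasi_species_count(traj)
        assert mean == 1.0 and np.all(counts == 1)

    def test_two_founders_constant_two(self):
        times = np.linspace(0, 10, 6)
        traj = flat_trajectory(times, {0: np.full(6, 40.0),
                                       1: np.full(6, 10.0)})
        _, mean = quasi_species_count(traj)
        assert mean == 2.0

    def test_known_occupancy_counts(self):
        times = np.linspace(0, 10, 6)
        traj = flat_trajectory(times, {
            0: np.array([5, 5, 5, 0, 0, 0.0]),
            1: np.array([0, 3, 3, 3, 3, 3.0]),
        })
        counts, mean = quasi_species_count(traj, burn_in=0.0)
        np.testing.assert_array_equal(counts, [1, 2, 2, 1, 1, 1])
        assert mean == pytest.approx(8 / 6)


class TestLineageEnzymeSeries:
    def test_single_type_reports_its_own_series(self):
        times = np.linspace(0, 10, 6)
        traj = flat_trajectory(times, {0: np.full(6, 10.0)})
        tree = LineageTree()
        tree.add(0, None, 0.0)
        t, E, src, valid = lineage_enzyme_series(traj, tree)
        assert np.all(valid)
        np.testing.assert_allclose(E[:, 0], 1.0)
        assert np.all(src == 0)

    def test_series_switches_at_child_birth(self):
        times = np.arange(0.0, 10.0)
        traj = flat_trajectory(times, {
            0: np.array([10, 10, 10, 10, 5, 0, 0, 0, 0, 0.0]),
            1: np.array([0, 0, 0, 1, 5, 10, 10, 10, 10, 10.0]),
        })
        tree = LineageTree()
        tree.add(0, None, 0.0)
        tree.add(1, 0, 3.0)
        tree.close(0, 5.0)
        t, E, src, valid = lineage_enzyme_series(traj, tree)
        # child reported from its birth time onward, parent before
        assert list(src[:3]) == [0, 0, 0]
        assert list(src[3:]) == [1] * 7
        np.testing.assert_allclose(E[:3, 0], 1.0)
        np.testing.assert_allclose(E[3:, 0], 2.0)


class TestMutation:
    def _parent(self, chem4, reg=False):
        from protocrm.regulation import RegulatoryNetwork
        t = make_type(regulation=RegulatoryNetwork.disabled(2) if reg else None,
                      reg_enabled=reg)
        t.bind_chemistry(chem4)
        return t

    def test_null_kernel_copies_parent(self, chem4):
        cfg = SimulationConfig(sigma_m=0.0, sigma_nn=0.0, sigma_e=0.0)
        parent = self._parent(chem4)
        child = mutate_type(parent, cfg, np.random.default_rng(0), 7, 5.0)
        assert child.type_id == 7 and child.parent_id == 0
        assert child.birth_time == 5.0
        np.testing.assert_array_equal(child.enzymes, parent.enzymes)
        np.testing.assert_array_equal(child.metabolism.weights,
                                      parent.metabolism.weights)

    def test_diet_inherited_exactly(self, chem4):
        cfg = SimulationConfig()
        parent = self._parent(chem4)
        child = mutate_type(parent, cfg, np.random.default_rng(1), 7, 5.0)
        assert child.metabolism.nutrient_set == parent.metabolism.nutrient_set
        assert child.metabolism.byproduct_set == parent.metabolism.byproduct_set

    def test_noreg_never_touches_network(self, chem4):
        from protocrm.regulation import RegulatoryNetwork
        net = RegulatoryNetwork.disabled(2)
        t = make_type(regulation=net, reg_enabled=False)
        t.bind_chemistry(chem4)
        cfg = SimulationConfig()
        rng = np.random.default_rng(2)
        for k in range(20):
            child = mutate_type(t, cfg, rng, 10 + k, 5.0)
            assert not np.any(child.regulation.w_out)
            assert not np.any(child.regulation.w_in)

    def test_children_always_valid_under_adverse_draws(self, chem4):
        """Rejection sampling keeps every child thermodynamically valid and
        budget-feasible, even for a parent at the constraint boundary."""
        boundary = make_type(weights=((1.95, 0.0), (0.0, 1.95)),
                             enzymes=(60.0, 0.0))
        boundary.bind_chemistry(chem4)
        cfg = SimulationConfig(sigma_m=0.3, p_mut=1.0, sigma_e=5.0)
        rng = np.random.default_rng(3)
        for k in range(2000):
            child = mutate_type(boundary, cfg, rng, k + 1, 1.0)
            report = validate_metabolism(child.metabolism, chem4)
            assert report, report.describe()
            assert float(child.budget_weights @ child.enzymes) \
                <= child.e_budget * (1 + 1e-9)
            assert np.all(child.enzymes >= 0)

    def test_reg_mutation_perturbs_network(self, chem4):
        parent = self._parent(chem4, reg=True)
        cfg = SimulationConfig(p_mut=1.0)
        child = mutate_type(parent, cfg, np.random.default_rng(4), 7, 5.0)
        assert np.any(child.regulation.w_out != 0)
        assert np.all(child.regulation.decay >= 0)

    def test_evolvable_parameter_count(self, chem4):
        assert count_evolvable_parameters(self._parent(chem4)) == 6
        assert count_evolvable_parameters(self._parent(chem4, reg=True)) == 45


class TestExports:
    def test_newick_roundtrip_topology(self, tmp_path):
        import dendropy
        from protocrm.lineage import export_newick
        tree = chain_tree(3, 10.0)
        path = tmp_path / "lineage.nwk"
        export_newick(tree, path, significant={1, 2})
        loaded = dendropy.TreeList.get(path=str(path), schema="newick")
        assert len(loaded) == 1
        labels = {leaf.taxon.label for leaf in loaded[0].leaf_node_iter()
                  if leaf.taxon is not None}
        assert "t3" in labels

    def test_table_roundtrip(self, tmp_path):
        from protocrm.lineage import export_table, tree_from_table
        tree = chain_tree(3, 10.0)
        path = tmp_path / "lineage.tsv"
        export_table(tree, path, trunk_path=trunk(tree),
                     significant=significant_variants(tree))
        back = tree_from_table(path)
        assert set(back.nodes) == set(tree.nodes)
        for tid in tree.nodes:
            assert back.nodes[tid].parent_id == tree.nodes[tid].parent_id
            assert back.nodes[tid].birth_time == tree.nodes[tid].birth_time
            assert back.nodes[tid].extinction_time == \
                tree.nodes[tid].extinction_time
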