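"""Exact reconciliation against exhaustive enumeration, plus constraints."""
import numpy as np
import pytest

import cophylo as cp
from cophylo.errors import InfeasibleReconciliationError, ValidationError
from cophylo.reconcile import CostRegime, SolverConfig, TimeZones

from _oracles import brute_min_cost, random_instance


class TestSolveBasics:
    def test_identical_trees_give_pure_cospeciation(self):
        host = cp.read_newick("((A:1,B:1):1,C:1);")
        symb = cp.read_newick("((a:1,b:1):1,c:1);")
        links = cp.AssociationMap([("A", "a"), ("B", "b"), ("C", "c")])
        rec = cp.solve_reconciliation(host, symb, links)
        assert rec.total_cost == 0.0
        assert rec.event_counts() == (2, 0, 0, 0)

    def test_single_leaf_symbiont_costs_nothing(self):
        host = cp.read_newick("((A:1,B:1):1,C:1);")
        symb = cp.PhyloTree.from_newick("s1;")
        rec = cp.solve_reconciliation(host, symb, cp.AssociationMap([("B", "s1")]))
        assert rec.total_cost == 0.0
        assert rec.event_counts() == (0, 0, 0, 0)

    def test_three_leaf_swap_matches_enumeration(self, incongruent_triple):
        host, symb, links = incongruent_triple
        oracle_cost, oracle_counts = brute_min_cost(host, symb, links)
        rec = cp.solve_reconciliation(host, symb, links)
        assert rec.total_cost == oracle_cost == 2.0
        assert rec.event_counts() == oracle_counts == (1, 0, 1, 0)

    def test_unlinked_symbiont_leaf_rejected(self, incongruent_triple):
        host, symb, _ = incongruent_triple
        with pytest.raises(ValidationError, match="no host link"):
            cp.solve_reconciliation(
                host, symb, cp.AssociationMap([("A", "a"), ("B", "b")])
            )

    def test_nonbinary_tree_rejected(self):
        host = cp.read_newick("((A:1,B:1,C:1):1,D:1);")
        symb = cp.read_newick("(a:1,b:1);")
        links = cp.AssociationMap([("A", "a"), ("D", "b")])
        with pytest.raises(ValidationError, match="binary"):
            cp.solve_reconciliation(host, symb, links)

    def test_deterministic_reconciliation(self):
        rng = np.random.default_rng(5)
        host, symb, links = random_instance(rng)
        a = cp.solve_reconciliation(host, symb, links)
        b = cp.solve_reconciliation(host, symb, links)
        assert a.mapping == b.mapping and a.events == b.events
        assert a.total_cost == b.total_cost


class TestAgainstBruteForce:
    @pytest.mark.parametrize("seed", range(60))
    def test_dp_cost_equals_exhaustive_minimum(self, seed):
        rng = np.random.default_rng(seed)
        host, symb, links = random_instance(rng)
        oracle_cost, _ = brute_min_cost(host, symb, links)
        rec = cp.solve_reconciliation(host, symb, links)
        assert rec.total_cost == pytest.approx(oracle_cost)
        assert rec.cost_from_counts() == pytest.approx(rec.total_cost)

    @pytest.mark.parametrize("seed", range(20))
    def test_dp_matches_oracle_under_random_regimes(self, seed):
        rng = np.random.default_rng(1000 + seed)
        host, symb, links = random_instance(rng, max_leaves=5)
        regime = CostRegime(
            cospeciation=float(rng.integers(0, 2)),
            duplication=float(rng.integers(1, 4)),
            loss=float(rng.integers(1, 3)),
            switch=float(rng.integers(1, 5)),
        )
        oracle_cost, _ = brute_min_cost(host, symb, links, regime)
        rec = cp.solve_reconciliation(host, symb, links, regime)
        assert rec.total_cost == pytest.approx(oracle_cost)

    @pytest.mark.parametrize("seed", range(15))
    def test_cost_monotone_in_event_costs(self, seed):
        rng = np.random.default_rng(2000 + seed)
        host, symb, links = random_instance(rng)
        base = cp.solve_reconciliation(host, symb, links).total_cost
        for bump in (
            CostRegime(duplication=2.0),
            CostRegime(loss=2.0),
            CostRegime(switch=4.0),
            CostRegime(cospeciation=0.5),
        ):
            assert cp.solve_reconciliation(host, symb, links, bump).total_cost >= base - 1e-9


class TestCountEvents:
    @pytest.mark.parametrize("n", [3, 5, 8, 12])
    def test_perfect_cospeciation_counts(self, n):
        host = cp.simulate_host_tree(n, seed=n)
        sim = cp.simulate_cophylogeny(
            host,
            cp.SimulationParams(
                p_cospeciation=1.0, p_loss=0.0, p_duplication=0.0, p_switch=0.0, seed=n
            ),
        )
        rec = cp.solve_reconciliation(host, sim.symbiont, sim.links)
        assert cp.count_events(rec) == (n - 1, 0, 0, 0)

    @pytest.mark.parametrize("seed", range(10))
    def test_counts_reproduce_total_cost(self, seed):
        rng = np.random.default_rng(3000 + seed)
        host, symb, links = random_instance(rng)
        regime = CostRegime(0.0, 1.5, 1.0, 2.5)
        rec = cp.solve_reconciliation(host, symb, links, regime)
        c, d, s, l = cp.count_events(rec)
        assert c * 0.0 + d * 1.5 + s * 2.5 + l * 1.0 == pytest.approx(rec.total_cost)


class TestTimeZones:
    def _zoned_instance(self):
        host = cp.read_newick("(((A:1,B:1)N3:1,C:1)N2:1,(D:1,E:1)N4:1)N1;")
        symb = cp.read_newick("((a:1,b:1):1,(c:1,d:1):1);")
        links = cp.AssociationMap([("A", "a"), ("B", "b"), ("C", "c"), ("D", "d")])
        return host, symb, links

    def test_single_zone_equals_unconstrained(self):
        host, symb, links = self._zoned_instance()
        zones = TimeZones({"N1": 1}, min_divergence_zone=1)
        free = cp.solve_reconciliation(host, symb, links)
        tied = cp.solve_reconciliation(host, symb, links, zones=zones)
        assert tied.total_cost == pytest.approx(free.total_cost)

    def test_zones_never_decrease_cost(self):
        host, symb, links = self._zoned_instance()
        free = cp.solve_reconciliation(host, symb, links).total_cost
        zones = TimeZones({"N1": 1, "N2": 2, "N4": 2}, min_divergence_zone=2)
        constrained = cp.solve_reconciliation(host, symb, links, zones=zones).total_cost
        assert constrained >= free - 1e-9

    @pytest.mark.parametrize("seed", range(12))
    def test_constrained_dp_matches_constrained_oracle(self, seed):
        rng = np.random.default_rng(4000 + seed)
        host, symb, links = random_instance(rng, max_leaves=5)
        # zone 2 = everything below the root's first child; zone 1 elsewhere
        first = host.root.children[0]
        zone_of = {}
        in_two = {id(n) for n in _descendants(first)}
        for node in host.preorder():
            label = node.label if node.label else None
            zone_of[_name(host, node)] = 2 if id(node) in in_two else 1
        zones = TimeZones(
            {lbl: z for lbl, z in zone_of.items() if lbl}, min_divergence_zone=1
        )
        oracle_cost, _ = brute_min_cost(
            host, symb, links, zone_of_label=zone_of, min_zone=1
        )
        try:
            rec = cp.solve_reconciliation(host, symb, links, zones=zones)
            assert rec.total_cost == pytest.approx(oracle_cost)
        except InfeasibleReconciliationError:
            assert not np.isfinite(oracle_cost)

    def test_infeasible_zones_raise(self):
        host, symb, links = self._zoned_instance()
        zones = TimeZones({"N1": 1}, min_divergence_zone=5)  # no admissible node
        with pytest.raises(InfeasibleReconciliationError):
            cp.solve_reconciliation(host, symb, links, zones=zones)

    def test_non_monotone_zone_assignment_rejected(self):
        host, symb, links = self._zoned_instance()
        zones = TimeZones({"N1": 2, "N2": 1})
        with pytest.raises(ValidationError, match="ancestry"):
            cp.solve_reconciliation(host, symb, links, zones=zones)


def _descendants(node):
    stack = [node]
    while stack:
        n = stack.pop()
        yield n
        stack.extend(n.children)


def _name(tree, node):
    """Mirror the solver's naming of unlabelled host nodes (postorder id)."""
    if node.label:
        return node.label
    for i, n in enumerate(tree.postorder()):
        if n is node:
            return f"host{i}"
    raise AssertionError


class TestGeneticMode:
    @pytest.mark.parametrize("seed", range(8))
    def test_never_beats_exact_and_ties_small_instances(self, seed):
        rng = np.random.default_rng(5000 + seed)
        host, symb, links = random_instance(rng, max_leaves=4)
        exact = cp.solve_reconciliation(host, symb, links).total_cost
        ga = cp.solve_reconciliation(
            host,
            symb,
            links,
            config=SolverConfig(mode="genetic", generations=80, population_size=30, seed=seed),
        )
        assert not ga.exact
        assert ga.total_cost >= exact - 1e-9
        assert ga.total_cost == pytest.approx(exact)  # small enough to verify

    def test_genetic_mode_deterministic_under_seed(self):
        rng = np.random.default_rng(77)
        host, symb, links = random_instance(rng, max_leaves=5)
        cfg = SolverConfig(mode="genetic", generations=40, population_size=20, seed=3)
        a = cp.solve_reconciliation(host, symb, links, config=cfg)
        b = cp.solve_reconciliation(host, symb, links, config=cfg)
        assert a.total_cost == b.total_cost and a.mapping == b.mapping


class TestCompositeHostTree:
    def test_graft_counts_and_clades(self):
        nem = cp.read_newick("((A:1,B:1):1,C:1);")
        art = cp.read_newick("(X:1,Y:1);")
        combo = cp.build_composite_host_tree(nem, art, attachment="C")
        assert combo.n_leaves == 5
        clades = {combo.bipartition_of(n) for n in combo.preorder() if n.children}
        assert frozenset({"X", "Y"}) in clades
        assert frozenset({"A", "B"}) in clades

    def test_label_collision_rejected(self):
        nem = cp.read_newick("((A:1,B:1):1,C:1);")
        art = cp.read_newick("(C:1,Y:1);")
        with pytest.raises(ValidationError, match="collision"):
            cp.build_composite_host_tree(nem, art, attachment="A")

    def test_prohibitive_switch_cost_reduces_to_nematode_only(self):
        rng = np.random.default_rng(9)
        host = cp.simulate_host_tree(5, seed=21)
        symb = cp.simulate_host_tree(5, seed=22)
        for leaf in symb.leaves():
            leaf.label = leaf.label.replace("H", "s")
        links = cp.AssociationMap(
            [(host.leaf_labels[int(rng.integers(5))], s) for s in symb.leaf_labels]
        )
        art = cp.read_newick("(X1:1,X2:1);")
        combo = cp.build_composite_host_tree(host, art, attachment="N1")
        # with switches priced out, adding an uninfested arthropod clade at
        # the root cannot change the optimum (all links stay on nematodes)
        regime = CostRegime(switch=10_000.0)
        alone = cp.solve_reconciliation(host, symb, links, regime).total_cost
        grafted = cp.solve_reconciliation(combo, symb, links, regime).total_cost
        assert grafted == pytest.approx(alone)
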