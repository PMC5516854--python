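import math

import pytest

from pathlinker.evaluation import (
    EvalConfig,
    UNRANKED,
    aggregate_pr,
    edge_distance_from_pathway,
    exclude_adjacent_negatives,
    node_sets_from_edges,
    perturb_roles,
    precision_recall,
    recovery_ranks,
    rwr_baseline,
    rwr_stationary,
    subsample_negatives,
)
from pathlinker.graph_io import Interactome, PathwayTruth, RoleSet

from conftest import random_instance, rwr_linear_solve


class TestSubsampleNegatives:
    def test_size_contract(self):
        universe = {f"e{i}" for i in range(10_000)}
        positives = {f"e{i}" for i in range(10)}
        neg = subsample_negatives(universe, positives, EvalConfig(neg_ratio=5, seed=1))
        assert len(neg) == 50
        assert not neg & positives

    def test_same_seed_same_sample(self):
        universe = {f"e{i}" for i in range(200)}
        positives = {"e0", "e1"}
        cfg = EvalConfig(neg_ratio=10, seed=7)
        assert subsample_negatives(universe, positives, cfg) == subsample_negatives(
            universe, positives, cfg
        )

    def test_pool_exhaustion_clamps(self):
        universe = {f"e{i}" for i in range(20)}
        positives = {"e0", "e1"}
        neg = subsample_negatives(
            universe, positives, EvalConfig(neg_ratio=1000, seed=0)
        )
        assert neg == universe - positives

    def test_errors(self):
        with pytest.raises(ValueError):
            subsample_negatives({"a"}, {"a"}, EvalConfig(seed=0))
        with pytest.raises(ValueError):
            subsample_negatives({"a"}, {"b"}, EvalConfig(seed=0))


class TestPrecisionRecall:
    def test_hand_computed_points(self):
        ranked = [("p1", 1), ("n1", 2), ("p2", 3)]
        curve = precision_recall(ranked, {"p1", "p2"}, {"n1"})
        assert curve.recall_precision() == [(0.5, 1.0), (0.5, 0.5), (1.0, 2 / 3)]
        assert curve.positives_total == 2

    def test_all_positive_precision_constant_one(self):
        ranked = [(f"p{i}", i) for i in range(1, 6)]
        curve = precision_recall(ranked, {r[0] for r in ranked}, set())
        assert all(p.precision == 1.0 for p in curve.points)

    def test_block_tie_enters_together(self):
        curve = precision_recall([("p1", 1), ("n1", 1)], {"p1", "p2"}, {"n1"})
        assert curve.recall_precision() == [(0.5, 0.5)]

    def test_unlabeled_items_ignored(self):
        curve = precision_recall(
            [("x", 1), ("p1", 2), ("y", 3)], {"p1"}, {"n1"}
        )
        assert curve.recall_precision() == [(1.0, 1.0)]

    def test_errors(self):
        with pytest.raises(ValueError):
            precision_recall([], set(), {"n"})
        with pytest.raises(ValueError):
            precision_recall([], {"a"}, {"a"})

    def test_recall_nondecreasing_invariant(self):
        inst = random_instance(3, n=20, p=0.2, n_receptors=2, n_trs=2)
        assert inst is not None
        g, _roles, _cg = inst
        edges = sorted(g.edge_set())
        pos = set(edges[::3])
        neg = set(edges) - pos
        ranked = [(e, i + 1) for i, e in enumerate(edges)]
        curve = precision_recall(ranked, pos, neg)
        recalls = [p.recall for p in curve.points]
        assert recalls == sorted(recalls)
        assert all(0 <= p.precision <= 1 and 0 <= p.recall <= 1 for p in curve.points)


class TestEdgeDistance:
    # Chain: pathway edge (A,B); C,D,E hang off B in a line; F isolated.
    def _fixture(self):
        g = Interactome.from_edges(
            [("A", "B", 0.5), ("B", "C", 0.5), ("C", "D", 0.5), ("D", "E", 0.5),
             ("F", "G", 0.5)]
        )
        truth = PathwayTruth(frozenset({("A", "B")}))
        return g, truth

    def test_positive_edge_distance_zero(self):
        g, truth = self._fixture()
        assert edge_distance_from_pathway(("A", "B"), truth, g) == 0.0

    def test_pathway_adjacent_distance_one(self):
        g, truth = self._fixture()
        assert edge_distance_from_pathway(("B", "C"), truth, g) == 1.0

    def test_two_hop_endpoints_distance_three(self):
        g, truth = self._fixture()
        # D and E are 2 and 3 undirected hops from pathway node B.
        assert edge_distance_from_pathway(("D", "E"), truth, g) == 3.0

    def test_unreachable_is_infinite(self):
        g, truth = self._fixture()
        assert edge_distance_from_pathway(("F", "G"), truth, g) == math.inf

    def test_direction_ignored(self):
        g = Interactome.from_edges([("A", "B", 0.5), ("C", "A", 0.5), ("D", "C", 0.5)])
        truth = PathwayTruth(frozenset({("A", "B")}))
        # C -> A points *into* the pathway; undirected adjacency still applies.
        assert edge_distance_from_pathway(("C", "A"), truth, g) == 1.0
        assert edge_distance_from_pathway(("D", "C"), truth, g) == 2.0


class TestExcludeAdjacent:
    def test_adjacent_removed_distant_retained(self):
        g = Interactome.from_edges(
            [("A", "B", 0.5), ("B", "C", 0.5), ("C", "D", 0.5), ("D", "E", 0.5)]
        )
        truth = PathwayTruth(frozenset({("A", "B")}))
        negatives = {("B", "C"), ("C", "D"), ("D", "E")}
        kept = exclude_adjacent_negatives(negatives, truth, g)
        assert kept == {("C", "D"), ("D", "E")}

    def test_never_returns_positives(self):
        g = Interactome.from_edges([("A", "B", 0.5), ("C", "D", 0.5)])
        truth = PathwayTruth(frozenset({("A", "B")}))
        kept = exclude_adjacent_negatives({("C", "D")}, truth, g)
        assert kept & truth.positive_edges == set()


class TestRecoveryRanks:
    def test_earliest_incident_edge(self):
        ranked = [(("A", "B"), 2), (("R1", "A"), 4), (("R1", "B"), 9)]
        assert recovery_ranks(ranked, {"R1"}) == {"R1": 4}

    def test_uncovered_node_unranked(self):
        assert recovery_ranks([(("A", "B"), 1)], {"Z"}) == {"Z": UNRANKED}

    def test_head_and_tail_both_count(self):
        ranked = [(("A", "R1"), 3), (("R1", "B"), 5)]
        assert recovery_ranks(ranked, {"R1", "A", "B"}) == {"R1": 3, "A": 3, "B": 5}


class TestPerturbRoles:
    def _roles(self):
        return RoleSet(
            frozenset(f"R{i}" for i in range(10)),
            frozenset(f"T{i}" for i in range(10)),
        )

    def test_remove_thirty_percent(self):
        out = perturb_roles(self._roles(), 0.3, "remove", seed=1)
        assert len(out.receptors) == 7 and len(out.trs) == 7
        assert out.receptors <= self._roles().receptors

    def test_add_thirty_percent(self):
        pool = {f"X{i}" for i in range(20)}
        out = perturb_roles(self._roles(), 0.3, "add", candidate_pool=pool, seed=1)
        assert len(out.receptors) == 13 and len(out.trs) == 13
        assert out.receptors - self._roles().receptors <= pool

    def test_fraction_zero_is_identity(self):
        roles = self._roles()
        assert perturb_roles(roles, 0.0, "remove", seed=0) == roles

    def test_seed_determinism(self):
        a = perturb_roles(self._roles(), 0.5, "remove", seed=9)
        b = perturb_roles(self._roles(), 0.5, "remove", seed=9)
        assert a == b

    def test_emptying_removal_is_error(self):
        roles = RoleSet(frozenset({"R"}), frozenset({"T"}))
        with pytest.raises(ValueError):
            perturb_roles(roles, 1.0, "remove", seed=0)


class TestRWR:
    def test_teleport_one_closed_form(self):
        g = Interactome.from_edges([("R", "A", 0.5), ("A", "B", 0.5)])
        roles = RoleSet(frozenset({"R"}), frozenset({"B"}))
        p = rwr_stationary(g, roles, teleport=1.0)
        assert p == {"R": 1.0, "A": 0.0, "B": 0.0}

    def test_probabilities_sum_to_one(self):
        inst = random_instance(11, n=25, p=0.15, n_receptors=3, n_trs=2)
        assert inst is not None
        g, roles, _ = inst
        p = rwr_stationary(g, roles)
        assert sum(p.values()) == pytest.approx(1.0, abs=1e-9)

    def test_six_node_fixture_matches_linear_solve(self):
        g = Interactome.from_edges(
            [("R", "A", 0.9), ("A", "B", 0.4), ("B", "C", 0.7), ("C", "A", 0.2),
             ("A", "D", 0.6), ("D", "R", 0.3)]
        )
        roles = RoleSet(frozenset({"R"}), frozenset({"C"}))
        p = rwr_stationary(g, roles, teleport=0.5)
        oracle = rwr_linear_solve(g, roles, teleport=0.5)
        for u in g.nodes:
            assert p[u] == pytest.approx(oracle[u], abs=1e-9)

    def test_edge_ranking_is_total_and_flux_ordered(self):
        inst = random_instance(4, n=20, p=0.2, n_receptors=2, n_trs=2)
        assert inst is not None
        g, roles, _ = inst
        ranked = rwr_baseline(g, roles)
        assert len(ranked) == g.n_edges
        assert [r for _e, r in ranked] == list(range(1, g.n_edges + 1))

    def test_non_convergence_reports_residual(self):
        g = Interactome.from_edges([("R", "A", 0.5), ("A", "R", 0.5)])
        roles = RoleSet(frozenset({"R"}), frozenset({"A"}))
        with pytest.raises(RuntimeError, match="residual"):
            rwr_stationary(g, roles, teleport=0.5, tol=0.0, max_iter=3)


class TestAggregatePR:
    def _pathway(self):
        ranked = [("a", 1), ("b", 2), ("c", 3)]
        return ranked, {"a", "c"}, {"b"}

    def test_single_pathway_identity(self):
        ranked, pos, neg = self._pathway()
        assert aggregate_pr([(ranked, pos, neg)]).recall_precision() == (
            precision_recall(ranked, pos, neg).recall_precision()
        )

    def test_identical_copies_equal_one_pathway(self):
        entry = self._pathway()
        assert aggregate_pr([entry, entry]).recall_precision() == (
            precision_recall(*entry).recall_precision()
        )

    def test_disjoint_pathways_sum_positives(self):
        e1 = ([("a", 1)], {"a"}, {"z"})
        e2 = ([("b", 1)], {"b"}, {"y"})
        curve = aggregate_pr([e1, e2])
        assert curve.positives_total == 2
        assert curve.points[-1].recall == 1.0

    def test_same_edge_in_two_pathways_counts_twice(self):
        e = ([("a", 1)], {"a"}, set())
        curve = aggregate_pr([e, e])
        assert curve.positives_total == 2
        assert curve.points[-1].tp == 2


class TestNodeSets:
    def test_negative_nodes_exclude_pathway_proteins(self):
        truth = PathwayTruth(frozenset({("A", "B")}))
        pos, neg = node_sets_from_edges({("B", "C"), ("C", "D")}, truth)
        assert pos == {"A", "B"}
        assert neg == {"C", "D"}
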