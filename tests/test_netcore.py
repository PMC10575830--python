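"""Structural queries: validation, counts, cycles, bridges, classes."""

import networkx as nx
import pytest

from sdcet.netcore import (
    RootedNetwork,
    SemiDirectedNetwork,
    classify,
    cut_edges,
    cycles,
    find_chain,
    max_reticulations,
    reticulation_count,
    tree_vertex_count,
    validate,
)
from sdcet import partner
from sdcet.standard import standard_form

from conftest import rooted_corpus, sd_corpus


def _level2_blob() -> RootedNetwork:
    """u -> m1, u -> m2, m1 -> m2, m1 -> v, m2 -> v: two reticulations in
    one biconnected component (not level-1)."""
    return RootedNetwork(
        {0: (0, 1), 1: (1, 2), 2: (1, 3), 3: (2, 3), 4: (2, 4),
         5: (3, 4), 6: (4, 5)},
        0, {5: "a"})


class TestValidate:
    def test_worked_examples_are_valid(self, fig_pair_rooted, fig_loop_sd,
                                       single_edge):
        assert validate(fig_pair_rooted).ok
        assert validate(fig_loop_sd).ok
        assert validate(single_edge).ok
        assert reticulation_count(single_edge) == 0

    def test_root_out_degree_two_is_reported(self):
        bad = RootedNetwork({0: (0, 1), 1: (0, 2)}, 0,
                            {1: "x1", 2: "x2"})
        rep = validate(bad)
        assert not rep.ok
        assert any("root" in v for v in rep.violations)

    def test_two_loops_rejected(self):
        bad = SemiDirectedNetwork(
            {0: (0, 0, "D"), 1: (0, 1, "U"), 2: (1, 2, "U"),
             3: (1, 3, "U"), 4: (3, 3, "D"), 5: (3, 4, "U")},
            {2: "x1", 4: "x2"})
        rep = validate(bad)
        assert not rep.ok

    def test_directed_edge_into_non_reticulation_reported(self):
        bad = SemiDirectedNetwork(
            {0: (0, 1, "D"), 1: (1, 2, "U"), 2: (1, 3, "U")},
            {0: "x1", 2: "x2", 3: "x3"})
        assert not validate(bad).ok


class TestCounts:
    def test_reticulation_counts(self, fig_loop_sd):
        assert reticulation_count(fig_loop_sd) == 1
        assert reticulation_count(standard_form(list("abcde"), 0)) == 0
        assert reticulation_count(standard_form(list("abcde"), 2)) == 2

    def test_tree_vertex_identity(self):
        assert tree_vertex_count(standard_form(["a", "b", "c"], 1)) == 3
        cherry = standard_form(["a", "b"], 0)
        assert tree_vertex_count(cherry) == 1
        assert tree_vertex_count(standard_form(list("abcde"), 2)) == 6

    def test_identity_on_corpus(self):
        for nr in rooted_corpus(25):
            k = reticulation_count(nr)
            n = len(nr.leaf_labels)
            assert tree_vertex_count(nr) == k + n - 1
            assert k <= max_reticulations(nr.labels)

    @pytest.mark.parametrize("n,expect", [(2, 1), (1, 0), (5, 4)])
    def test_max_reticulations(self, n, expect):
        assert max_reticulations([f"x{i}" for i in range(n)]) == expect


class TestCycles:
    def test_parallel_pair_is_length_two(self, fig_pair_sd):
        recs = cycles(fig_pair_sd)
        assert len(recs) == 1 and recs[0].length == 2

    def test_loop_is_length_one(self, fig_loop_sd):
        recs = cycles(fig_loop_sd)
        assert len(recs) == 1 and recs[0].length == 1

    def test_tree_has_no_cycles(self):
        assert cycles(standard_form(list("abcd"), 0)) == []

    def test_standard_form_three_cycles(self):
        recs = cycles(standard_form(list("abcd"), 3))
        assert [r.length for r in recs] == [3, 3, 3]
        assert all(r.source is not None and r.sink is not None
                   for r in recs)

    def test_agrees_with_simple_cycle_enumeration(self):
        for ns in sd_corpus(12, max_n=5):
            if len(ns.vertices) > 12:
                continue
            got = sorted(sorted(r.vertices) for r in cycles(ns)
                         if not r.composite)
            oracle = sorted(sorted(c) for c in
                            nx.simple_cycles(ns.to_nx_multigraph()))
            assert got == oracle

    def test_composite_component_flagged(self):
        # level-2 blob: u -> m1, u -> m2, m1 -> m2, m1 -> v, m2 -> v; the
        # underlying cycles share edges, so the biconnected component is
        # not a single cycle and must be flagged composite
        nr = _level2_blob()
        assert validate(nr).ok
        recs = cycles(nr)
        assert len(recs) == 1 and recs[0].composite

    def test_cycles_joined_by_a_cut_edge_are_not_composite(self):
        nr = RootedNetwork(
            {0: (0, 1), 1: (1, 2), 2: (1, 3), 3: (2, 3), 4: (3, 4),
             5: (4, 5), 6: (4, 6), 7: (5, 6), 8: (6, 7), 9: (2, 8),
             10: (5, 9)},
            0, {7: "a", 8: "b", 9: "c"})
        assert validate(nr).ok
        recs = cycles(nr)
        assert len(recs) == 2
        assert not any(r.composite for r in recs)
        assert classify(nr).is_level1


class TestCutEdges:
    def test_pair_network_cut_edges_are_leaf_edges(self, fig_pair_sd):
        bridges = cut_edges(fig_pair_sd)
        assert len(bridges) == 2
        for e in bridges:
            a, b, kind = fig_pair_sd.edges[e]
            assert kind == "U"
            assert fig_pair_sd.is_leaf(a) or fig_pair_sd.is_leaf(b)

    def test_unrooted_tree_every_edge_is_a_bridge(self):
        tree = partner.to_semidirected(standard_form(list("abcde"), 0))
        assert cut_edges(tree) == set(tree.edges)
        assert len(tree.edges) == 2 * 5 - 3

    def test_cycle_edges_never_bridges(self):
        for ns in sd_corpus(10):
            bridges = cut_edges(ns)
            for rec in cycles(ns):
                assert not (set(rec.edge_ids) & bridges)

    def test_no_directed_bridge_in_semidirected(self):
        for ns in sd_corpus(15):
            for e in cut_edges(ns):
                assert ns.edges[e][2] == "U"


class TestClassify:
    def test_loop_network_is_almost_level1_only(self, fig_loop_sd):
        rep = classify(fig_loop_sd)
        assert not rep.is_level1 and rep.is_almost_level1
        assert rep.loop_count == 1

    def test_pair_network_is_level1(self, fig_pair_sd):
        rep = classify(fig_pair_sd)
        assert rep.is_level1 and rep.parallel_pair_count == 1

    def test_vertex_sharing_cycles_are_neither(self):
        cls = classify(_level2_blob())
        assert not cls.is_level1 and not cls.is_almost_level1

    def test_rooted_parallel_pair_is_almost_only(self, fig_loop_rooted):
        rep = classify(fig_loop_rooted)
        assert not rep.is_level1 and rep.is_almost_level1
        assert rep.parallel_pair_count == 1


class TestChains:
    def test_standard_form_chain_order(self):
        nr = standard_form([f"x{i}" for i in range(1, 6)], 3)
        chain = find_chain(nr)
        assert chain is not None and len(chain) == 3
        # sinks ordered by ancestry: each sink deeper than the previous
        from sdcet.standard import _depths
        d = _depths(nr)
        sinks = [r.sink for r in chain]
        assert sinks == sorted(sinks, key=lambda v: d[v])

    def test_tree_has_empty_chain(self):
        assert find_chain(standard_form(list("abc"), 0)) == []

    def test_cycles_on_disjoint_subtrees_have_no_chain(self):
        # a tree vertex whose two subtrees each contain one 3-cycle:
        # neither sink is an ancestor of the other
        from sdcet import explore
        import random
        found = None
        for seed in range(300):
            nr = explore.random_level1([f"x{i}" for i in range(1, 7)], 2,
                                       seed=seed)
            recs = cycles(nr)
            dg = nx.DiGraph(list(nr.edges.values()))
            s0, s1 = recs[0].sink, recs[1].sink
            if s1 not in nx.descendants(dg, s0) and \
               s0 not in nx.descendants(dg, s1):
                found = nr
                break
        assert found is not None
        assert find_chain(found) is None


class TestSaturatedAllThreeCycleNetworks:
    def test_saturation_iff_max_reticulations(self):
        # among networks whose cycles all have length three, every non-leaf
        # vertex lies on a cycle exactly when k = |X| - 1
        cases = [standard_form([f"x{i}" for i in range(1, n + 1)], k)
                 for n, k in [(3, 2), (4, 3), (4, 2), (5, 3), (2, 1)]]
        for nr in rooted_corpus(30):
            if all(r.length == 3 for r in cycles(nr)):
                cases.append(nr)
        for nr in cases:
            recs = cycles(nr)
            if not all(r.length == 3 for r in recs):
                continue
            k = reticulation_count(nr)
            n = len(nr.leaf_labels)
            on_cycle = set().union(*(set(r.vertices) for r in recs)) \
                if recs else set()
            internal = {v for v in nr.vertices
                        if v != nr.root and not nr.is_leaf(v)}
            assert (internal <= on_cycle) == (k == n - 1)
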