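"""Standard form, the constructive transformations, and the connectors."""

import itertools
import random

import pytest

from sdcet.netcore import (
    ClassConstraint,
    classify,
    cut_edges,
    cycles,
    reticulation_count,
    validate,
)
from sdcet import explore, moves, partner, standard
from sdcet.moves import InvalidMove, apply_cet_sd, enumerate_cet_neighbors
from sdcet.standard import (
    ExcludedMove,
    connect_extended,
    connect_rooted,
    connect_sd,
    decompose_to_cet1,
    is_standard_form,
    is_standard_shape,
    shape_to_form,
    standard_form,
    to_standard_shape,
)

from conftest import rooted_corpus


class TestStandardForm:
    def test_two_leaves_one_reticulation_matches_pair_partner(
            self, fig_pair_rooted):
        assert partner.is_isomorphic(standard_form(["x1", "x2"], 1),
                                     fig_pair_rooted)

    def test_zero_reticulations_is_the_caterpillar(self):
        nr = standard_form(["x1", "x2", "x3"], 0)
        assert cycles(nr) == []
        assert is_standard_form(nr)

    def test_vertex_count_five_leaves_two_reticulations(self):
        # 1 root + 2 reticulations + 6 tree vertices + 5 leaves
        assert len(standard_form([f"x{i}" for i in range(1, 6)], 2)
                   .vertices) == 14

    def test_k_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            standard_form(["a", "b"], 2)
        with pytest.raises(ValueError):
            standard_form(["a"], 1)

    def test_uniqueness_across_feasible_k(self):
        labels = [f"x{i}" for i in range(1, 6)]
        for k in range(5):
            nr = standard_form(labels, k)
            assert validate(nr).ok
            assert classify(nr).is_level1
            assert reticulation_count(nr) == k
            assert is_standard_form(nr) and is_standard_shape(nr)


class TestRecognition:
    def test_caterpillar_leaf_swap_is_shape_not_form(self):
        nr = standard_form([f"x{i}" for i in range(1, 6)], 2)
        # swap two caterpillar leaves x4 and x5
        v4, v5 = nr.leaf_of("x4"), nr.leaf_of("x5")
        nr.leaf_labels[v4], nr.leaf_labels[v5] = "x5", "x4"
        assert not is_standard_form(nr)
        assert is_standard_shape(nr)

    def test_cherry_swap_is_still_standard_form(self):
        # the bottom two caterpillar leaves are interchangeable
        nr = standard_form([f"x{i}" for i in range(1, 6)], 2)
        v3, v4 = nr.leaf_of("x3"), nr.leaf_of("x4")
        nr.leaf_labels[v3], nr.leaf_labels[v4] = "x4", "x3"
        assert is_standard_form(nr)

    def test_network_with_a_four_cycle_is_neither(self):
        for seed in range(200):
            nr = explore.random_level1([f"x{i}" for i in range(1, 6)], 2,
                                       seed=seed)
            if any(r.length >= 4 for r in cycles(nr)):
                assert not is_standard_form(nr)
                assert not is_standard_shape(nr)
                return
        pytest.fail("no network with a long cycle found")


class TestToStandardShape:
    def test_standard_input_needs_no_moves(self):
        nr = standard_form([f"x{i}" for i in range(1, 6)], 3)
        assert len(to_standard_shape(nr)) == 0

    def test_corpus_reaches_shape_within_bounds(self):
        for nr in rooted_corpus(20, max_n=6):
            n = len(nr.leaf_labels)
            k = reticulation_count(nr)
            seq = to_standard_shape(nr)
            assert is_standard_shape(seq.final)
            assert len(seq) <= 2 * n + 2 * k
            assert seq.verify()

    def test_gadget_uses_at_most_three_cets_per_cycle(self):
        for nr in rooted_corpus(15, max_n=7, seed=77):
            seq = to_standard_shape(nr)
            costs = seq.meta.get("chain_gadget_moves", [])
            assert all(c <= 3 for c in costs)

    def test_intermediate_class_certificates(self):
        for nr in rooted_corpus(12, max_n=6, seed=31):
            n = len(nr.leaf_labels)
            k = reticulation_count(nr)
            seq = to_standard_shape(nr)
            for cert in seq.certificates:
                assert cert.k == k
                if k <= n - 2:
                    assert cert.is_level1
                else:
                    assert cert.is_almost_level1


class TestShapeToForm:
    @pytest.mark.parametrize("k", [0, 1, 2, 3])
    def test_exhaustive_over_leaf_permutations_n4(self, k):
        labels = ["x1", "x2", "x3", "x4"]
        base = standard_form(labels, k)
        for perm in itertools.permutations(labels):
            nr = base.copy()
            relabel = dict(zip(labels, perm))
            nr.leaf_labels = {v: relabel[lab]
                              for v, lab in nr.leaf_labels.items()}
            assert is_standard_shape(nr)
            seq = shape_to_form(nr)
            assert is_standard_form(seq.final)
            assert len(seq) <= 12
            assert seq.verify()

    def test_standard_form_input_is_a_fixed_point(self):
        nr = standard_form([f"x{i}" for i in range(1, 7)], 2)
        assert len(shape_to_form(nr)) == 0


class TestConnectRooted:
    def test_isomorphic_inputs_need_no_moves(self):
        a = explore.random_level1([f"x{i}" for i in range(1, 6)], 2,
                                  seed=41)
        b = a.copy()
        assert len(connect_rooted(a, b)) == 0

    def test_mismatched_inputs_rejected(self):
        a = standard_form(["a", "b", "c"], 1)
        with pytest.raises(InvalidMove):
            connect_rooted(a, standard_form(["a", "b", "d"], 1))
        with pytest.raises(InvalidMove):
            connect_rooted(a, standard_form(["a", "b", "c"], 2))

    def test_length_within_bound_and_reaches_target(self):
        rng = random.Random(5)
        for trial in range(8):
            n = rng.randint(2, 6)
            k = rng.randint(0, n - 1)
            labels = [f"x{i}" for i in range(1, n + 1)]
            a = explore.random_level1(labels, k, seed=trial * 11 + 1)
            b = explore.random_level1(labels, k, seed=trial * 11 + 6)
            seq = connect_rooted(a, b)
            target = seq.final if len(seq) else a
            assert partner.is_isomorphic(target, b)
            assert len(seq) <= 10 * n + 4 * k

    def test_length_at_least_bfs_distance(self):
        labels = ["x1", "x2", "x3"]
        for k in (0, 1):
            cat = explore.enumerate_networks(
                labels, k, ClassConstraint("rooted-level1", k))
            g = explore.build_move_graph(cat)
            for i, a in enumerate(cat.members):
                for j, b in enumerate(cat.members):
                    if i >= j:
                        continue
                    d = explore.bfs_distance(a, b, cat, graph=g)
                    assert d is not None
                    assert len(connect_rooted(a, b)) >= d


class TestConnectSemiDirected:
    def test_pair_network_to_its_swap_takes_two_cets(
            self, fig_pair_sd, fig_pair_sd_swapped):
        seq = connect_sd(fig_pair_sd, fig_pair_sd_swapped)
        assert len(seq) == 2
        assert partner.is_isomorphic(seq.final, fig_pair_sd_swapped)
        mid = seq.certificates[0]
        assert mid.is_almost_level1 and not mid.is_level1

    def test_exhaustive_pairs_three_leaves(self):
        labels = ["x1", "x2", "x3"]
        for k in (0, 1):
            cat = explore.enumerate_networks(labels, k,
                                             ClassConstraint("sd-level1", k))
            for a, b in itertools.combinations(cat.members, 2):
                seq = connect_sd(a, b)
                assert partner.is_isomorphic(seq.final, b)
                n = 3
                space_ok = "almost" not in seq.constraint.space \
                    if k <= n - 2 else True
                for cert in seq.certificates:
                    assert cert.k == k
                    assert cert.is_level1 if k <= n - 2 \
                        else cert.is_almost_level1

    def test_saturated_pairs_three_leaves(self):
        labels = ["x1", "x2", "x3"]
        cat = explore.enumerate_networks(labels, 2,
                                         ClassConstraint("sd-level1", 2))
        mem = cat.members
        rng = random.Random(3)
        pairs = [(mem[i], mem[j]) for i, j in
                 [(0, 1), (2, len(mem) - 1), (1, len(mem) // 2)]]
        for a, b in pairs:
            seq = connect_sd(a, b)
            assert partner.is_isomorphic(seq.final, b)
            for cert in seq.certificates:
                assert cert.is_almost_level1 and cert.k == 2


class TestConnectExtended:
    def test_tree_to_tree_is_a_pure_cet_walk(self):
        a = partner.to_semidirected(
            explore.random_level1([f"x{i}" for i in range(1, 7)], 0,
                                  seed=2))
        b = partner.to_semidirected(
            explore.random_level1([f"x{i}" for i in range(1, 7)], 0,
                                  seed=12))
        seq = connect_extended(a, b, level1_only=True)
        assert all(r.kind == "CET_sd" for r in seq.records)
        target = seq.final if len(seq) else a
        assert partner.is_isomorphic(target, b)

    def test_loop_network_to_tree_is_one_r_minus(self, fig_loop_sd,
                                                 single_edge):
        seq = connect_extended(fig_loop_sd, single_edge)
        assert len(seq) == 1 and seq.records[0].kind == "R_minus"

    def test_differing_reticulation_numbers(self):
        labels = [f"x{i}" for i in range(1, 6)]
        a = partner.to_semidirected(explore.random_level1(labels, 3,
                                                          seed=21))
        b = partner.to_semidirected(explore.random_level1(labels, 1,
                                                          seed=22))
        seq = connect_extended(a, b, level1_only=True)
        assert partner.is_isomorphic(seq.final, b)
        for cert in seq.certificates:
            assert cert.is_level1

    def test_extended_distance_is_a_metric_on_two_leaves(self):
        cat = explore.enumerate_union(["x1", "x2"], 2, "sd-all")
        g = explore.build_move_graph(cat, "extended", strict=False)
        import networkx as nx
        dist = dict(nx.all_pairs_shortest_path_length(g))
        nodes = list(g.nodes)
        for i in nodes:
            assert dist[i][i] == 0
            for j in nodes:
                if j in dist[i]:
                    assert dist[i][j] == dist[j][i]
                    assert (dist[i][j] == 0) == (i == j)
                    for l in nodes:
                        if l in dist[i] and l in dist[j]:
                            assert dist[i][l] <= dist[i][j] + dist[j][l]


class TestDecomposeToCet1:
    def _some_move(self, ns, want_cet1: bool):
        con = ClassConstraint("sd-level1", reticulation_count(ns))
        for m, rec in enumerate_cet_neighbors(ns, con):
            if moves.is_cet1(rec, ns) == want_cet1:
                return m, rec
        return None, None

    def test_cet1_move_decomposes_to_itself(self):
        ns = partner.to_semidirected(
            explore.random_level1([f"x{i}" for i in range(1, 6)], 1,
                                  seed=14))
        m, rec = self._some_move(ns, want_cet1=True)
        assert rec is not None
        seq = decompose_to_cet1(ns, rec)
        assert len(seq) == 1
        assert partner.is_isomorphic(seq.final, m)

    def test_non_local_move_walks_the_path(self):
        found = False
        for seed in (3, 9, 15, 27):
            ns = partner.to_semidirected(
                explore.random_level1([f"x{i}" for i in range(1, 7)], 2,
                                      seed=seed))
            m, rec = self._some_move(ns, want_cet1=False)
            if rec is None:
                continue
            found = True
            seq = decompose_to_cet1(ns, rec)
            assert len(seq) >= 2
            assert partner.is_isomorphic(seq.final, m)
            cur = ns
            for r, net in zip(seq.records, seq.networks):
                assert moves.is_cet1(r, cur)
                cur = net
        assert found

    def test_excluded_moves_raise(self):
        # relocating a parallel pair (see the moves tests for the instance)
        from sdcet.netcore import SemiDirectedNetwork
        ns = SemiDirectedNetwork(
            {0: (2, 3, "D"), 1: (2, 3, "D"), 2: (2, 5, "U"),
             3: (3, 6, "U"), 4: (6, 7, "D"), 5: (8, 7, "D"),
             6: (6, 8, "U"), 7: (7, 9, "U"), 8: (8, 10, "U")},
            {5: "x1", 9: "x2", 10: "x3"})
        rec = moves.MoveRecord(kind="CET_sd", cut_edge=8, suppressed_end=8,
                               recipient=0,
                               donor_edges=(5, 6))
        with pytest.raises(ExcludedMove):
            decompose_to_cet1(ns, rec)
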