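"""CET, CET_1, R+ and R-: validity, reversibility, neighbourhoods."""

import random

import pytest
from hypothesis import given, settings, strategies as st

from sdcet.netcore import (
    ClassConstraint,
    RootedNetwork,
    SemiDirectedNetwork,
    classify,
    cut_edges,
    cycles,
    reticulation_count,
    validate,
)
from sdcet import explore, moves, partner
from sdcet.moves import (
    InvalidMove,
    apply_cet_rooted,
    apply_cet_sd,
    apply_move,
    apply_r_minus,
    apply_r_plus,
    cet_valid_sd,
    enumerate_cet_neighbors,
    is_cet1,
)
from sdcet.standard import standard_form

from conftest import rooted_corpus, sd_corpus


class TestRootedCET:
    def test_caterpillar_cet_is_rooted_spr(self):
        # moving x3's pendant onto the root edge of (x1,x2,x3,x4) puts x3
        # directly below the root, next to the caterpillar (x1,x2,x4)
        cat = standard_form(["x1", "x2", "x3", "x4"], 0)
        x3 = cat.leaf_of("x3")
        pend = cat.in_edges(x3)[0]
        root_edge = cat.out_edges(cat.root)[0]
        res, rec = apply_cet_rooted(cat, pend, root_edge)
        # expect: root child has children x3 and the caterpillar (x1,x2,x4)
        expect = RootedNetwork(
            {0: (0, 1), 1: (1, 2), 2: (1, 3), 3: (3, 4), 4: (3, 5),
             5: (5, 6), 6: (5, 7)},
            0, {2: "x3", 4: "x4", 6: "x1", 7: "x2"})
        assert validate(expect).ok
        assert partner.is_isomorphic(res, expect)
        assert not rec.identity

    def test_apply_then_inverse_restores_source(self):
        rng = random.Random(7)
        for nr in rooted_corpus(10):
            nbrs = enumerate_cet_neighbors(
                nr, ClassConstraint("rooted-all", None))
            if not nbrs:
                continue
            m, rec = nbrs[rng.randrange(len(nbrs))]
            back, _ = apply_move(m, rec.inverse)
            assert partner.is_isomorphic(back, nr)

    def test_neighbor_set_matches_unpruned_bruteforce(self):
        # brute force: every (cut edge, recipient) pair filtered only by
        # the definition, deduplicated by pairwise isomorphism
        nr = standard_form(["a", "b", "c", "d"], 0)
        got = enumerate_cet_neighbors(nr, ClassConstraint("rooted-all",
                                                          None))
        brute = []
        for e in sorted(cut_edges(nr)):
            u, v = nr.edges[e]
            if u == nr.root or nr.in_degree(u) == 2:
                continue
            for f in sorted(nr.edges):
                try:
                    m, rec = apply_cet_rooted(nr, e, f)
                except InvalidMove:
                    continue
                if rec.identity:
                    continue
                if not any(partner.is_isomorphic(m, x) for x in brute):
                    brute.append(m)
        assert len(got) == len(brute)
        for m, _ in got:
            assert any(partner.is_isomorphic(m, x) for x in brute)


class TestSemiDirectedCETValidity:
    def test_loop_network_edge_is_one_directional(self, loop3_sd):
        # partner is unique (rooted at the loop); the internal bridge
        # {a, b} supports a CET only when the loop-ward endpoint stays
        ns = loop3_sd
        e = [f for f, (x, y, k) in ns.edges.items()
             if k == "U" and not ns.is_leaf(x) and not ns.is_leaf(y)
             and not ns.is_reticulation(x) and not ns.is_reticulation(y)]
        assert len(e) == 1
        a, b, _ = ns.edges[e[0]]
        # a is nearer the loop: the unique partner directs a -> b
        wit = partner.rooted_partners(ns)[0]
        if any(wit.network.edges[f] == (b, a)
               for f in wit.network.out_edges(b)):
            a, b = b, a
        ok_ab, w = cet_valid_sd(ns, e[0], a)
        ok_ba, _ = cet_valid_sd(ns, e[0], b)
        assert ok_ab and w is not None
        assert not ok_ba

    def test_every_orientation_valid_on_trees(self):
        tree = partner.to_semidirected(standard_form(list("abcd"), 0))
        for e, (x, y, kind) in tree.edges.items():
            for u in (x, y):
                if tree.degree(u) == 3:
                    ok, _ = cet_valid_sd(tree, e, u)
                    assert ok

    def test_bridge_into_reticulation_supports_no_cet(self, fig_pair_sd):
        # the undirected third edge of a reticulation is a bridge, but
        # neither endpoint choice admits a CET with the reticulation as
        # the suppressed end
        for ns in sd_corpus(6, max_n=5):
            for e in cut_edges(ns):
                x, y, _ = ns.edges[e]
                for u in (x, y):
                    if ns.is_reticulation(u):
                        ok, _ = cet_valid_sd(ns, e, u)
                        assert not ok


class TestSemiDirectedCETApplication:
    def test_results_validate_and_reverse(self):
        rng = random.Random(13)
        for ns in sd_corpus(10, max_n=6):
            nbrs = enumerate_cet_neighbors(ns, ClassConstraint("sd-all",
                                                               None))
            if not nbrs:
                continue
            m, rec = nbrs[rng.randrange(len(nbrs))]
            assert validate(m).ok
            back, _ = apply_move(m, rec.inverse)
            assert partner.is_isomorphic(back, ns)

    def test_subdividing_a_loop_makes_a_parallel_pair(self, loop3_sd):
        ns = loop3_sd
        # move a leaf pendant onto the loop
        x1 = ns.leaf_of("x2")
        pend = ns.incident(x1)[0]
        u = ns.other_end(pend, x1)
        loop = ns.loops()[0]
        res, rec = apply_cet_sd(ns, pend, u, loop)
        assert validate(res).ok
        assert not res.loops()
        assert classify(res).parallel_pair_count == 1
        back, _ = apply_move(res, rec.inverse)
        assert partner.is_isomorphic(back, ns)

    def test_pair_network_has_no_level1_neighbors(self, fig_pair_sd):
        nbrs = enumerate_cet_neighbors(fig_pair_sd,
                                       ClassConstraint("sd-level1", 1))
        assert nbrs == []


def _tree_neighbors(n: int, move_set: str):
    tree = partner.to_semidirected(
        standard_form([f"x{i}" for i in range(1, n + 1)], 0))
    return enumerate_cet_neighbors(tree, ClassConstraint("sd-level1", 0),
                                   require_cet1=(move_set == "nni"))


class TestTreeMoveEquivalence:
    @pytest.mark.parametrize("n", [4, 5, 6])
    def test_cet_neighbourhood_size_equals_spr(self, n):
        # |SPR(T)| = 2(n-3)(2n-7) distinct trees for an unrooted binary
        # caterpillar (Allen & Steel's count)
        assert len(_tree_neighbors(n, "spr")) == 2 * (n - 3) * (2 * n - 7)

    @pytest.mark.parametrize("n", [4, 5, 6])
    def test_cet1_neighbourhood_size_equals_nni(self, n):
        assert len(_tree_neighbors(n, "nni")) == 2 * (n - 3)

    def test_quartet_tree_has_the_two_other_topologies(self):
        nbrs = _tree_neighbors(4, "spr")
        assert len(nbrs) == 2
        keys = {partner.canonical_key(m) for m, _ in nbrs}
        assert len(keys) == 2

    @pytest.mark.parametrize("n", [4, 5, 6])
    def test_nni_neighbours_are_a_subset_of_spr(self, n):
        spr = {partner.canonical_key(m) for m, _ in _tree_neighbors(n,
                                                                    "spr")}
        nni = {partner.canonical_key(m) for m, _ in _tree_neighbors(n,
                                                                    "nni")}
        assert nni <= spr


class TestRMoves:
    def test_loop_removal_gives_single_edge(self, fig_loop_sd,
                                            single_edge):
        res, rec = apply_r_minus(fig_loop_sd, fig_loop_sd.loops()[0])
        assert partner.is_isomorphic(res, single_edge)
        back, _ = apply_move(res, rec.inverse)
        assert partner.is_isomorphic(back, fig_loop_sd)

    def test_loop_addition_on_tree_gives_loop_network(self, single_edge,
                                                      fig_loop_sd):
        spec = moves.RPlusSpec(variant="loop",
                               edge=sorted(single_edge.edges)[0])
        res, _ = apply_r_plus(single_edge, spec)
        assert partner.is_isomorphic(res, fig_loop_sd)

    def test_second_loop_is_rejected(self, loop3_sd):
        e = [f for f in loop3_sd.edges if not loop3_sd.is_loop(f)][0]
        with pytest.raises(InvalidMove):
            apply_r_plus(loop3_sd, moves.RPlusSpec(variant="loop", edge=e))

    def test_r_minus_r_plus_pairing_on_corpus(self):
        for ns in sd_corpus(12, max_n=6):
            k = reticulation_count(ns)
            applied = 0
            for e in sorted(ns.edges):
                if ns.edges[e][2] != "D":
                    continue
                try:
                    res, rec = apply_r_minus(ns, e)
                except InvalidMove:
                    continue
                applied += 1
                assert reticulation_count(res) == k - 1
                back, rec2 = apply_move(res, rec.inverse)
                assert reticulation_count(back) == k
                assert partner.is_isomorphic(back, ns)
            if k:
                assert applied > 0  # some reticulation is removable


class TestCet1Recognition:
    def test_donor_incident_recipient_is_cet1(self, loop3_sd):
        ns = loop3_sd
        x2 = ns.leaf_of("x2")
        pend = ns.incident(x2)[0]
        u = ns.other_end(pend, x2)
        donors = sorted(set(ns.incident(u)) - {pend})
        # recipient sharing a vertex with a donor edge
        shared = [f for f in ns.edges if f not in donors + [pend]
                  and set(ns.edges[f][:2]) &
                  set().union(*(set(ns.edges[d][:2]) for d in donors))]
        res, rec = apply_cet_sd(ns, pend, u, shared[0])
        assert is_cet1(rec, ns)
        far = ns.incident(ns.leaf_of("x1"))[0]
        donors_v = set().union(*(set(ns.edges[d][:2]) for d in donors))
        if not set(ns.edges[far][:2]) & donors_v:
            res2, rec2 = apply_cet_sd(ns, pend, u, far)
            assert not is_cet1(rec2, ns)


class TestSpecialMoves:
    def test_pair_relocation_positive_instance(self):
        # parallel pair 2=>3 plus a 3-cycle {6,7,8} (sink 7); deleting the
        # pendant cut edge of the 3-cycle vertex 8 (its donors are the two
        # 3-cycle edges) with a pair edge as recipient relocates the pair
        ns = SemiDirectedNetwork(
            {0: (2, 3, "D"), 1: (2, 3, "D"), 2: (2, 5, "U"),
             3: (3, 6, "U"), 4: (6, 7, "D"), 5: (8, 7, "D"),
             6: (6, 8, "U"), 7: (7, 9, "U"), 8: (8, 10, "U")},
            {5: "x1", 9: "x2", 10: "x3"})
        assert validate(ns).ok
        assert moves.changes_parallel_pair_location(ns, 8, 8, 0)
        # an off-cycle recipient does not relocate the pair
        assert not moves.changes_parallel_pair_location(ns, 8, 8, 2)

    def test_loop_for_pairs_exchange_donors_on_3cycle(self):
        # loop at 0; cut edge {1,3} whose suppressed end 3 has both donors
        # on the 3-cycle {3,4,5}; recipient = the loop
        ns = SemiDirectedNetwork(
            {0: (0, 0, "D"), 1: (0, 1, "U"), 2: (1, 2, "U"),
             3: (1, 3, "U"), 4: (3, 5, "D"), 5: (4, 5, "D"),
             6: (3, 4, "U"), 7: (5, 6, "U"), 8: (4, 7, "U")},
            {2: "x1", 6: "x2", 7: "x3"})
        assert validate(ns).ok
        assert moves.exchanges_loop_for_parallel_pairs(ns, 3, 3, 0)
        assert not moves.exchanges_loop_for_parallel_pairs(ns, 3, 3, 2)

    def test_loop_for_pairs_exchange_donors_form_2cycle(self):
        # two parallel pairs; the suppressed end's donors form one pair
        # and the recipient lies on the other
        ns = SemiDirectedNetwork(
            {0: (2, 3, "D"), 1: (2, 3, "D"), 2: (1, 2, "U"),
             3: (3, 7, "U"), 4: (4, 5, "D"), 5: (4, 5, "D"),
             6: (1, 4, "U"), 7: (5, 8, "U"), 8: (1, 6, "U")},
            {7: "x1", 8: "x3", 6: "x2"})
        assert validate(ns).ok
        assert moves.exchanges_loop_for_parallel_pairs(ns, 2, 2, 4)
        assert not moves.exchanges_loop_for_parallel_pairs(ns, 2, 2, 8)


@settings(max_examples=15, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_move_reversibility_property(seed):
    rng = random.Random(seed)
    n = rng.randint(3, 6)
    k = rng.randint(0, n - 1)
    ns = partner.to_semidirected(
        explore.random_level1([f"x{i}" for i in range(1, n + 1)], k,
                              seed=seed))
    nbrs = enumerate_cet_neighbors(ns, ClassConstraint("sd-all", None))
    for m, rec in nbrs[:3]:
        back, _ = apply_move(m, rec.inverse)
        assert partner.is_isomorphic(back, ns)
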