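"""Constructive connectivity algorithms for level-1 network spaces.

The central object is the *standard form*: the unique rooted level-1 network
on an ordered leaf set x_1..x_n with k reticulations that consists of a chain
of k 3-cycles hanging off the root (leaf x_i on the middle vertex of the i-th
cycle) followed by a caterpillar on x_{k+1}..x_n below the last sink.  A
network of *standard shape* differs from it only by a permutation of leaf
labels.

Every rooted level-1 network can be driven into standard shape by at most
2|X| + 2k CETs (cycle shrinking, chain assembly with a three-CET gadget,
caterpillar assembly) and from standard shape into standard form by at most
3|X| CETs (leaf-position swaps); concatenating a forward and a reversed
transformation connects any two rooted level-1 networks with the same leaf
set and reticulation number in at most 10|X| + 4k CETs.  For k <= |X| - 2
every intermediate network is level-1; for k = |X| - 1 one parallel pair may
appear, so intermediates are almost level-1.

Semi-directed spaces are handled by projection: each rooted CET projects to
at most one semi-directed CET (consecutive projections may coincide, in which
case the step is dropped).  Spaces with a varying number of reticulations are
connected by stripping reticulations with R-, walking between the resulting
trees with CETs (which on trees coincide with SPR), and rebuilding with R+.
Finally, any single CET that does not relocate a parallel pair and does not
exchange a loop for parallel pairs decomposes into a sequence of CET_1 moves
walked along a path from the suppressed endpoint to the recipient edge.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional

from . import moves as _moves
from . import partner as _partner
from .moves import InvalidMove, MoveRecord, apply_cet_rooted, apply_cet_sd, apply_move
from .netcore import (
    ClassConstraint,
    ClassReport,
    Network,
    RootedNetwork,
    SemiDirectedNetwork,
    StructuralError,
    classify,
    cycles,
    reticulation_count,
    validate,
)

__all__ = [
    "MoveSequence",
    "ExcludedMove",
    "standard_form",
    "is_standard_form",
    "is_standard_shape",
    "to_standard_shape",
    "shape_to_form",
    "connect_rooted",
    "connect_sd",
    "connect_extended",
    "decompose_to_cet1",
    "natural_leaf_order",
]


class ExcludedMove(InvalidMove):
    """The CET is one of the two special move types excluded by the
    CET_1 decomposition."""


def natural_leaf_order(labels) -> list[str]:
    """Sort labels treating trailing digit runs numerically (x2 < x10)."""
    def key(lab: str):
        parts = re.split(r"(\d+)", lab)
        return tuple(int(p) if p.isdigit() else p for p in parts if p != "")
    return sorted(set(labels), key=key)


# ---------------------------------------------------------------------------
# move sequences
# ---------------------------------------------------------------------------


@dataclass
class MoveSequence:
    """An ordered list of moves with per-step class certificates.

    ``networks[i]`` is the network after ``records[i]``; replaying the
    records from ``source`` reproduces it exactly.  ``bound`` is the declared
    upper bound on the length (None when no bound is claimed).
    """

    source: Network
    constraint: Optional[ClassConstraint] = None
    bound: Optional[int] = None
    records: list[MoveRecord] = field(default_factory=list)
    networks: list[Network] = field(default_factory=list)
    certificates: list[ClassReport] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def final(self) -> Network:
        return self.networks[-1] if self.networks else self.source

    def verify(self) -> bool:
        """Replay from source and re-check certificates and the bound."""
        cur = self.source
        for rec, net in zip(self.records, self.networks):
            cur, _ = apply_move(cur, rec, check=False)
            if not _partner.is_isomorphic(cur, net):
                return False
            cur = net
            if self.constraint is not None and not self.constraint.check(cur):
                return False
        if self.bound is not None and len(self.records) > self.bound:
            return False
        return True


class _Builder:
    """Accumulates a MoveSequence, checking the class constraint per step."""

    def __init__(self, source: Network, constraint: Optional[ClassConstraint],
                 bound: Optional[int]) -> None:
        self.seq = MoveSequence(source=source, constraint=constraint,
                                bound=bound)
        self.cur = source

    def apply(self, *args, kind: str, **kwargs) -> MoveRecord:
        if kind == "cet_rooted":
            net, rec = apply_cet_rooted(self.cur, *args, **kwargs)
        elif kind == "cet_sd":
            net, rec = apply_cet_sd(self.cur, *args, **kwargs)
        elif kind == "record":
            net, rec = apply_move(self.cur, args[0], **kwargs)
        else:  # pragma: no cover
            raise ValueError(kind)
        self.push(net, rec)
        return rec

    def push(self, net: Network, rec: MoveRecord) -> None:
        if rec.identity:
            raise StructuralError("pipeline produced an identity move")
        self.cur = net
        self.seq.records.append(rec)
        self.seq.networks.append(net)
        cert = classify(net)
        self.seq.certificates.append(cert)
        con = self.seq.constraint
        if con is not None:
            space = con.space
            if space.endswith("almost-level1"):
                ok = cert.is_almost_level1
            elif space.endswith("level1"):
                ok = cert.is_level1
            else:
                ok = True
            if con.k is not None:
                ok = ok and cert.k == con.k
            if not ok:
                raise StructuralError(
                    "intermediate network left the declared class "
                    f"({space}, k={con.k})")

    def done(self) -> MoveSequence:
        if self.seq.bound is not None and len(self.seq) > self.seq.bound:
            raise StructuralError(
                f"sequence length {len(self.seq)} exceeds declared bound "
                f"{self.seq.bound}")
        return self.seq


# ---------------------------------------------------------------------------
# standard form construction
# ---------------------------------------------------------------------------


def standard_form(labels, k: int) -> RootedNetwork:
    """The unique rooted level-1 network in standard form.

    ``labels`` is an ordered sequence x_1..x_n; k = 0 yields the caterpillar
    (x_1, ..., x_n).
    """
    order = list(labels)
    n = len(order)
    if len(set(order)) != n or n < 1:
        raise ValueError("labels must be distinct and non-empty")
    if not 0 <= k <= n - 1:
        raise ValueError(f"k={k} outside the feasible range 0..{n - 1}")

    edges: dict[int, tuple[int, int]] = {}
    leaf_labels: dict[int, str] = {}
    nid = [0]

    def newv() -> int:
        nid[0] += 1
        return nid[0]

    def add(u, v):
        edges[len(edges)] = (u, v)

    def leaf(lab: str) -> int:
        v = newv()
        leaf_labels[v] = lab
        return v

    def caterpillar(top_parent: int, labs: list[str]) -> None:
        """Attach the caterpillar (labs[0], ..., labs[-1]) below top_parent."""
        if len(labs) == 1:
            add(top_parent, leaf(labs[0]))
            return
        cur = top_parent
        for lab in reversed(labs[1:]):
            p = newv()
            add(cur, p)
            add(p, leaf(lab))
            cur = p
        # cur is the parent of labs[1]; labs[0] shares it
        add(cur, leaf(labs[0]))

    root = 0
    if k == 0:
        if n == 1:
            add(root, leaf(order[0]))
        else:
            top = newv()
            add(root, top)
            # the caterpillar hangs directly from the root child
            cur = top
            for lab in reversed(order[2:]):
                add(cur, leaf(lab))
                p = newv()
                add(cur, p)
                cur = p
            add(cur, leaf(order[0]))
            add(cur, leaf(order[1]))
    else:
        prev = root
        last_sink = None
        for i in range(k):
            u, p, v = newv(), newv(), newv()
            add(prev, u)
            add(u, p)
            add(u, v)
            add(p, v)
            add(p, leaf(order[i]))
            prev = v
            last_sink = v
        tail = order[k:]
        if len(tail) == 1:
            add(last_sink, leaf(tail[0]))
        else:
            top = newv()
            add(last_sink, top)
            cur = top
            for lab in reversed(tail[2:]):
                add(cur, leaf(lab))
                p = newv()
                add(cur, p)
                cur = p
            add(cur, leaf(tail[0]))
            add(cur, leaf(tail[1]))
    net = RootedNetwork(edges, root, leaf_labels)
    rep = validate(net)
    if not rep.ok:  # pragma: no cover - construction is fixed
        raise StructuralError("; ".join(rep.violations))
    return net


# ---------------------------------------------------------------------------
# standard shape / form recognition
# ---------------------------------------------------------------------------


def _read_caterpillar(nr: RootedNetwork, top: int) -> Optional[list[str]]:
    """Leaf labels of the caterpillar rooted at ``top``, bottom-up; None if
    the subtree is not a caterpillar.  The bottom cherry is label-sorted."""
    if nr.is_leaf(top):
        return [nr.leaf_labels[top]]
    out: list[str] = []
    cur = top
    while True:
        kids = nr.children(cur)
        if len(kids) != 2:
            return None
        leaves = [c for c in kids if nr.is_leaf(c)]
        if len(leaves) == 2:
            pair = sorted(nr.leaf_labels[c] for c in kids)
            out.extend(reversed(pair))
            break
        if len(leaves) != 1:
            return None
        out.append(nr.leaf_labels[leaves[0]])
        cur = [c for c in kids if c != leaves[0]][0]
    return list(reversed(out))


def _shape_info(nr: RootedNetwork):
    """(chain records top-down, middle leaf labels, caterpillar labels
    bottom-up) when nr is of standard shape, else None."""
    rep = classify(nr)
    if not rep.is_level1:
        return None
    recs = cycles(nr)
    k = len(recs)
    if any(r.composite or r.length != 3 for r in recs):
        return None
    by_source = {r.source: r for r in recs}
    cur = nr.children(nr.root)[0]
    chain = []
    middle_leaves = []
    for _ in range(k):
        rec = by_source.get(cur)
        if rec is None:
            return None
        mids = rec.middles
        if len(mids) != 1:
            return None
        p = mids[0]
        off = [c for c in nr.children(p) if c != rec.sink]
        if len(off) != 1 or not nr.is_leaf(off[0]):
            return None
        chain.append(rec)
        middle_leaves.append(nr.leaf_labels[off[0]])
        kids = nr.children(rec.sink)
        if len(kids) != 1:
            return None
        cur = kids[0]
    cat = _read_caterpillar(nr, cur)
    if cat is None:
        return None
    return chain, middle_leaves, cat


def is_standard_shape(nr: RootedNetwork) -> bool:
    """Standard form modulo a permutation of the leaf labels."""
    return _shape_info(nr) is not None


def is_standard_form(nr: RootedNetwork, order=None) -> bool:
    """Standard shape with the identity leaf assignment for ``order``
    (default: natural order of the labels)."""
    info = _shape_info(nr)
    if info is None:
        return False
    chain, middle_leaves, cat = info
    if order is None:
        order = natural_leaf_order(nr.labels)
    k = len(chain)
    if middle_leaves != list(order[:k]):
        return False
    tail = list(order[k:])
    if cat == tail:
        return True
    return (len(tail) >= 2 and cat[:2] == tail[:2][::-1]
            and cat[2:] == tail[2:])


# ---------------------------------------------------------------------------
# transformation: any level-1 network -> standard shape
# ---------------------------------------------------------------------------


def _depths(nr: RootedNetwork) -> dict[int, int]:
    """Longest-path depth from the root (descendants are strictly deeper)."""
    import networkx as nx
    dg = nx.DiGraph()
    dg.add_nodes_from(nr.vertices)
    dg.add_edges_from(nr.edges.values())
    depth = {nr.root: 0}
    for v in nx.topological_sort(dg):
        for c in dg.successors(v):
            depth[c] = max(depth.get(c, 0), depth[v] + 1)
    return depth


def _min_leaf_below(nr: RootedNetwork, v: int) -> str:
    import networkx as nx
    dg = nx.DiGraph()
    dg.add_nodes_from(nr.vertices)
    dg.add_edges_from(nr.edges.values())
    labs = [nr.leaf_labels[w] for w in ({v} | nx.descendants(dg, v))
            if w in nr.leaf_labels]
    return min(labs) if labs else ""


def _constraint_for(nr: RootedNetwork, k: int) -> ClassConstraint:
    n = len(nr.leaf_labels)
    space = "rooted-level1" if k <= n - 2 else "rooted-almost-level1"
    return ClassConstraint(space, k)


def to_standard_shape(nr: RootedNetwork) -> MoveSequence:
    """CET sequence of length at most 2|X| + 2k driving a rooted level-1
    network into standard shape.

    Three phases: (1) shrink every cycle to a 3-cycle by relocating pendant
    subtrees of cycle middles onto the root edge, deepest cycle first; (2)
    stack each cycle directly below the root with the chain-assembly gadget
    (at most three CETs per cycle); (3) gather the free leaves into a
    caterpillar below the bottom sink.  Intermediates are level-1 when
    k <= |X| - 2 and almost level-1 (one transient parallel pair) when
    k = |X| - 1.
    """
    rep = classify(nr)
    if not rep.is_level1:
        raise InvalidMove("input is not a rooted level-1 network")
    k = rep.k
    n = len(nr.leaf_labels)
    b = _Builder(nr, _constraint_for(nr, k), bound=2 * n + 2 * k)
    if is_standard_shape(nr):
        return b.done()

    # ---- phase 1: shrink cycles to 3-cycles -----------------------------
    while True:
        cur = b.cur
        longs = [r for r in cycles(cur) if r.length >= 4]
        if not longs:
            break
        depth = _depths(cur)
        longs.sort(key=lambda r: (-depth[r.source], r.source))
        rec = longs[0]
        mids = sorted(rec.middles,
                      key=lambda m: _min_leaf_below(
                          cur, [c for c in cur.children(m)
                                if c not in rec.vertices][0]))
        keep = mids[0]
        s = mids[1]  # relocate this middle's pendant subtree
        off = [e for e in cur.out_edges(s)
               if cur.edges[e][1] not in rec.vertices]
        root_edge = cur.out_edges(cur.root)[0]
        b.apply(off[0], root_edge, kind="cet_rooted")

    b.seq.meta["shrink_moves"] = len(b.seq.records)

    # ---- phase 2: stack every cycle at the top --------------------------
    processed: list[int] = []  # sink vertex ids, first processed = bottom
    gadget_costs: list[int] = []  # CETs spent per relocated cycle
    while True:
        cur = b.cur
        recs = [r for r in cycles(cur) if r.sink not in processed]
        if not recs:
            break
        depth = _depths(cur)
        # prefer cycles whose source parent is not a reticulation: the first
        # gadget run on such a cycle (creating the case-(b) parallel pair
        # when the network is saturated) frees a tree vertex that unblocks
        # any cycle hanging directly below a sink
        recs.sort(key=lambda r: (cur.in_degree(cur.parents(r.source)[0]) == 2,
                                 depth[r.source], r.source))
        rec = recs[0]
        uj, vj = rec.source, rec.sink
        t0 = cur.parents(uj)[0]
        if t0 == cur.root:
            processed.append(vj)  # already at the top
            gadget_costs.append(0)
            continue
        moves_before = len(b.seq.records)
        on_cycle = set().union(*(set(r.vertices) for r in cycles(cur)))
        free = sorted(v for v in cur.vertices
                      if v not in on_cycle and v != cur.root
                      and cur.in_degree(v) == 1 and cur.out_degree(v) == 2)
        if cur.in_degree(t0) == 1 and t0 not in on_cycle:
            pass  # t0 itself is a deletable tree vertex: two CETs suffice
        elif [t for t in free if t != t0]:
            # CET 1: move a free tree vertex's subtree onto the edge into uj
            t = [t for t in free if t != t0][0]
            c_edge = sorted(cur.out_edges(t))[0]
            in_uj = cur.in_edges(uj)[0]
            b.apply(c_edge, in_uj, kind="cet_rooted")
            cur = b.cur
        elif cur.in_degree(t0) == 2:
            raise StructuralError(
                "chain assembly hit a reticulation parent without a free "
                "tree vertex")  # unreachable by the processing order
        # CET 2: hang the cycle directly below the root (may create the one
        # admissible parallel pair when no free tree vertex existed).  When
        # the parent of the source already is the root child, this CET would
        # reproduce the network, so it is skipped and the third CET (with
        # t'' equal to that parent) suffices.
        cur = b.cur
        t1 = cur.edges[cur.in_edges(uj)[0]][0]
        if cur.parents(t1)[0] != cur.root:
            in_uj = cur.in_edges(uj)[0]
            root_edge = cur.out_edges(cur.root)[0]
            b.apply(in_uj, root_edge, kind="cet_rooted")
        # CET 3: move the old root subtree below the cycle's sink
        cur = b.cur
        t2 = cur.children(cur.root)[0]
        wj = [c for c in cur.children(t2) if c != uj][0]
        cut = [e for e in cur.out_edges(t2) if cur.edges[e][1] == wj][0]
        sink_out = cur.out_edges(vj)[0]
        b.apply(cut, sink_out, kind="cet_rooted")
        processed.append(vj)
        gadget_costs.append(len(b.seq.records) - moves_before)
    b.seq.meta["chain_gadget_moves"] = gadget_costs

    # ---- phase 3: caterpillar assembly ----------------------------------
    import networkx as nx

    def below(cur, v):
        dg = nx.DiGraph()
        dg.add_nodes_from(cur.vertices)
        dg.add_edges_from(cur.edges.values())
        return nx.descendants(dg, v)

    v_bottom = processed[0] if processed else None

    def cat_leaves(cur):
        if v_bottom is None:
            return sorted(cur.leaf_labels.values())
        return sorted(cur.leaf_labels[w] for w in below(cur, v_bottom)
                      if w in cur.leaf_labels)

    # (a) caterpillarise the subtree below the bottom sink (whole tree if
    # k = 0)
    ys = cat_leaves(b.cur)
    if len(ys) >= 2:
        cur = b.cur
        l0, l1 = cur.leaf_of(ys[0]), cur.leaf_of(ys[1])
        if cur.parents(l0)[0] != cur.parents(l1)[0]:
            pend0 = cur.in_edges(l0)[0]
            pend1 = cur.in_edges(l1)[0]
            b.apply(pend1, pend0, kind="cet_rooted")
        for i in range(2, len(ys)):
            cur = b.cur
            li = cur.leaf_of(ys[i])
            prev_p = cur.parents(cur.leaf_of(ys[i - 1]))[0]
            pi = cur.parents(li)[0]
            if sorted(cur.children(pi)) == sorted([li, prev_p]):
                continue
            b.apply(cur.in_edges(li)[0], cur.in_edges(prev_p)[0],
                    kind="cet_rooted")

    # (b)/(c) move every remaining free leaf below the bottom sink; for
    # k = |X| - 1 the single free leaf repairs the transient 2-cycle instead
    while True:
        cur = b.cur
        crecs = cycles(cur)
        on_cycle = set().union(*(set(r.vertices) for r in crecs)) \
            if crecs else set()
        below_b = below(cur, v_bottom) if v_bottom is not None else \
            cur.vertices
        two_cycles = [r for r in crecs if r.length == 2]
        free_leaves = sorted(
            lab for v, lab in cur.leaf_labels.items()
            if v not in below_b and cur.parents(v)[0] not in on_cycle)
        if two_cycles:
            tc = two_cycles[0]
            if free_leaves:
                x = cur.leaf_of(free_leaves[0])
            else:
                # take the top leaf of the caterpillar below the bottom sink
                top = cur.children(v_bottom)[0]
                kids = [c for c in cur.children(top) if cur.is_leaf(c)]
                x = kids[0]
            b.apply(cur.in_edges(x)[0], sorted(tc.edge_ids)[0],
                    kind="cet_rooted")
            continue
        if not free_leaves:
            break
        x = cur.leaf_of(free_leaves[0])
        sink_out = cur.out_edges(v_bottom)[0]
        b.apply(cur.in_edges(x)[0], sink_out, kind="cet_rooted")

    if not is_standard_shape(b.cur):  # pragma: no cover - correctness gate
        raise StructuralError("transformation did not reach standard shape")
    return b.done()


# ---------------------------------------------------------------------------
# standard shape -> standard form (leaf-position swaps)
# ---------------------------------------------------------------------------


def _uv_edge(nr: RootedNetwork, rec) -> int:
    """The source->sink edge of a 3-cycle (or one edge of a 2-cycle)."""
    for e in rec.edge_ids:
        if nr.edges[e] == (rec.source, rec.sink):
            return e
    return sorted(rec.edge_ids)[0]


def shape_to_form(nr: RootedNetwork, order=None) -> MoveSequence:
    """CET sequence of length at most 3|X| from standard shape to standard
    form, moving each leaf to its correct position in index order.

    Each leaf costs at most three CETs (a swap with an eligible later leaf,
    possibly via a transient 4-cycle); for k = |X| - 1 a transient parallel
    pair appears, so intermediates are then almost level-1.
    """
    info = _shape_info(nr)
    if info is None:
        raise InvalidMove("input is not of standard shape")
    if order is None:
        order = natural_leaf_order(nr.labels)
    order = list(order)
    n = len(order)
    k = len(info[0])
    b = _Builder(nr, _constraint_for(nr, k), bound=3 * n)

    def structure():
        inf = _shape_info(b.cur)
        if inf is None:  # pragma: no cover - correctness gate
            raise StructuralError("intermediate lost standard shape")
        return inf

    def placed_ok(i: int, chain, middles, cat) -> bool:
        lab = order[i - 1]
        if i <= k:
            return middles[i - 1] == lab
        want = order[k:i]
        have = [x for x in cat if x in set(want)]
        if have == want:
            return True
        return (len(want) >= 2 and have[:2] == want[:2][::-1]
                and have[2:] == want[2:])

    def pendant(cur, lab):
        v = cur.leaf_of(lab)
        return cur.in_edges(v)[0]

    def cat_list(cur):
        """Bottom-up labels of the caterpillar T of the current network
        (valid also mid-case, when a cycle is transiently a 4-cycle)."""
        recs = [r for r in cycles(cur) if not r.composite]
        if recs:
            depth = _depths(cur)
            vk = max((r.sink for r in recs), key=lambda s: depth[s])
            top = cur.children(vk)[0]
        else:
            top = cur.children(cur.root)[0]
        cat = _read_caterpillar(cur, top)
        if cat is None:  # pragma: no cover - correctness gate
            raise StructuralError("caterpillar part lost its shape")
        return cat

    def t_target_edge(cur, i):
        """Recipient in the caterpillar for placing order[i-1] (i > k).

        The leaf goes directly above the topmost already-placed leaf of the
        caterpillar (the bottom cherry may be in either order, so the
        topmost placed leaf is read off the current caterpillar rather than
        assumed to be order[i-2])."""
        cat = cat_list(cur)
        if i == k + 1:
            # any caterpillar position is correct for the first one
            return pendant(cur, cat[0])
        if i == k + 2:
            return pendant(cur, order[k])  # cherry with x_{k+1}
        placed = set(order[k:i - 1])
        top_lab = [lab for lab in cat if lab in placed][-1]
        top_p = cur.parents(cur.leaf_of(top_lab))[0]
        return cur.in_edges(top_p)[0]

    for i in range(1, n + 1):
        chain, middles, cat = structure()
        if placed_ok(i, chain, middles, cat):
            continue
        cur = b.cur
        lab = order[i - 1]
        v = cur.leaf_of(lab)
        p = cur.parents(v)[0]
        on_cycle_rec = None
        for rec in chain:
            if p in rec.middles:
                on_cycle_rec = rec
                break
        if on_cycle_rec is None:
            # x_i sits in the caterpillar T
            if i > k:
                b.apply(pendant(cur, lab), t_target_edge(cur, i),
                        kind="cet_rooted")
            elif k <= n - 2:
                ci = chain[i - 1]
                xj = middles[i - 1]
                recA = b.apply(pendant(cur, lab), _uv_edge(cur, ci),
                               kind="cet_rooted")
                cur = b.cur
                b.apply(pendant(cur, xj), recA.merged_edge,
                        kind="cet_rooted")
            else:
                # k = n - 1: T is the single leaf x_i below the last sink
                ci = chain[i - 1]
                xj = middles[i - 1]
                recA = b.apply(pendant(cur, xj), pendant(cur, lab),
                               kind="cet_rooted")
                cur = b.cur
                tc = [r for r in cycles(cur) if r.length == 2][0]
                b.apply(pendant(cur, lab), sorted(tc.edge_ids)[0],
                        kind="cet_rooted")
        else:
            c_rec = on_cycle_rec
            if i <= k and c_rec is chain[i - 1]:
                continue  # already on its own cycle
            if k == n - 1:
                if i > k:
                    raise StructuralError(
                        "last leaf out of position in a saturated network")
                ci = chain[i - 1]
                xj = middles[i - 1]
                b.apply(pendant(cur, lab), _uv_edge(cur, ci),
                        kind="cet_rooted")
                cur = b.cur
                tc = [r for r in cycles(cur) if r.length == 2][0]
                b.apply(pendant(cur, xj), sorted(tc.edge_ids)[0],
                        kind="cet_rooted")
            else:
                # pick the smallest-index caterpillar leaf with index > i
                cat_set = set(cat)
                xj = None
                for j in range(i + 1, n + 1):
                    if order[j - 1] in cat_set:
                        xj = order[j - 1]
                        break
                if xj is None:  # pragma: no cover - impossible by counting
                    raise StructuralError("no eligible caterpillar leaf")
                recA = b.apply(pendant(cur, xj), _uv_edge(cur, c_rec),
                               kind="cet_rooted")
                cur = b.cur
                if i <= k:
                    ci = chain[i - 1]
                    xjp = middles[i - 1]
                    b.apply(pendant(cur, lab), _uv_edge(cur, ci),
                            kind="cet_rooted")
                    cur = b.cur
                    b.apply(pendant(cur, xjp), recA.merged_edge,
                            kind="cet_rooted")
                else:
                    if i == k + 1:
                        b.apply(pendant(cur, lab), recA.merged_edge,
                                kind="cet_rooted")
                    else:
                        b.apply(pendant(cur, lab), t_target_edge(cur, i),
                                kind="cet_rooted")

    if not is_standard_form(b.cur, order):  # pragma: no cover - gate
        raise StructuralError("transformation did not reach standard form")
    return b.done()


# ---------------------------------------------------------------------------
# sequence inversion and rebasing
# ---------------------------------------------------------------------------


def _edge_map(src: Network, dst: Network, phi: dict[int, int]) -> dict[int, int]:
    """Edge-id correspondence induced by a vertex isomorphism.

    Parallel edges between the same endpoint pair are paired in sorted id
    order (any pairing yields isomorphic results)."""
    buckets: dict[tuple, list[int]] = {}
    if isinstance(dst, RootedNetwork):
        for e, (a, b) in dst.edges.items():
            buckets.setdefault(("D", a, b), []).append(e)
    else:
        for e, (a, b, kind) in dst.edges.items():
            key = ("U",) + tuple(sorted((a, b))) if kind == "U" else ("D", a, b)
            buckets.setdefault(key, []).append(e)
    for key in buckets:
        buckets[key].sort()
    out: dict[int, int] = {}
    items = (src.edges.items() if isinstance(src, SemiDirectedNetwork)
             else {e: (a, b, "D") for e, (a, b) in src.edges.items()}.items())
    for e, (a, b, kind) in sorted(items):
        pa, pb = phi[a], phi[b]
        key = ("U",) + tuple(sorted((pa, pb))) if kind == "U" else ("D", pa, pb)
        out[e] = buckets[key].pop(0)
    return out


def _translate_record(rec: MoveRecord, src: Network, dst: Network,
                      phi: dict[int, int]) -> MoveRecord:
    """Re-express a record given on ``src`` against the isomorphic ``dst``."""
    em = _edge_map(src, dst, phi)
    out = MoveRecord(kind=rec.kind)
    if rec.kind in ("CET_rooted", "CET_sd"):
        out.cut_edge = em[rec.cut_edge]
        out.recipient = em[rec.recipient]
        if rec.suppressed_end is not None:
            out.suppressed_end = phi[rec.suppressed_end]
    elif rec.kind == "R_minus":
        out.r_edge = em[rec.r_edge]
    elif rec.kind == "R_plus":
        spec = rec.r_plus
        new_edge = em[spec.edge]
        side = spec.head_side
        edge2 = spec.edge2
        if side is not None:
            anchor = src.edges[spec.edge][side]
            side = 0 if dst.edges[new_edge][0] == phi[anchor] else 1
        if edge2 is not None:
            if edge2[0] == "orig":
                edge2 = ("orig", em[edge2[1]])
            else:
                anchor = src.edges[spec.edge][edge2[1]]
                edge2 = ("half",
                         0 if dst.edges[new_edge][0] == phi[anchor] else 1)
        out.r_plus = _moves.RPlusSpec(variant=spec.variant, edge=new_edge,
                                      edge2=edge2, head_side=side)
    return out


def append_reversed(builder: _Builder, seq: MoveSequence) -> None:
    """Append the inverse of ``seq`` to a builder whose current network is
    isomorphic to seq.final, ending isomorphic to seq.source."""
    chain = [seq.source] + list(seq.networks)
    for i in reversed(range(len(seq.records))):
        after = chain[i + 1]
        inv = seq.records[i].inverse
        phi = _partner.find_isomorphism(after, builder.cur)
        if phi is None:  # pragma: no cover - correctness gate
            raise StructuralError("reversal lost isomorphism with the "
                                  "recorded chain")
        translated = _translate_record(inv, after, builder.cur, phi)
        builder.apply(translated, kind="record", check=True)
        if not _partner.is_isomorphic(builder.cur, chain[i]):  # pragma: no cover
            raise StructuralError("inverted move did not reproduce the "
                                  "recorded predecessor")


# ---------------------------------------------------------------------------
# connectors
# ---------------------------------------------------------------------------


def connect_rooted(a: RootedNetwork, bnet: RootedNetwork,
                   order=None) -> MoveSequence:
    """CET sequence from a to b within the rooted level-1 space (almost
    level-1 when k = |X| - 1), of length at most 10|X| + 4k."""
    if a.labels != bnet.labels:
        raise InvalidMove("networks have different leaf sets")
    ka, kb = reticulation_count(a), reticulation_count(bnet)
    if ka != kb:
        raise InvalidMove("networks have different reticulation numbers")
    n = len(a.labels)
    builder = _Builder(a, _constraint_for(a, ka), bound=10 * n + 4 * ka)
    if _partner.is_isomorphic(a, bnet):
        return builder.done()
    seq_a1 = to_standard_shape(a)
    seq_a2 = shape_to_form(seq_a1.final, order)
    seq_b1 = to_standard_shape(bnet)
    seq_b2 = shape_to_form(seq_b1.final, order)
    for seq in (seq_a1, seq_a2):
        for rec, net, cert in zip(seq.records, seq.networks,
                                  seq.certificates):
            builder.cur = net
            builder.seq.records.append(rec)
            builder.seq.networks.append(net)
            builder.seq.certificates.append(cert)
    append_reversed(builder, seq_b2)
    append_reversed(builder, seq_b1)
    if not _partner.is_isomorphic(builder.cur, bnet):  # pragma: no cover
        raise StructuralError("connector did not reach the target network")
    return builder.done()


def _project_cet(rooted_before: RootedNetwork, rec: MoveRecord):
    """Project a rooted CET to semi-directed CET parameters (or None when
    the two projections are isomorphic and the step is dropped).

    Case analysis on whether the cut edge e or the recipient f is incident
    with the root child t: if neither, both carry over unchanged; if e is,
    the semi-directed cut edge is the patch edge left by removing the root;
    if f is, the recipient becomes the patch edge (possibly a loop).
    """
    sd, info = _partner.to_semidirected_with_map(rooted_before)
    t = info["root_child"]
    e, f = rec.cut_edge, rec.recipient
    u, v = rooted_before.edges[e]
    e_at_t = (u == t)
    f_at_t = f in info["removed"]
    if e_at_t and f_at_t:
        return sd, None
    if e_at_t:
        patch = info["patch"]
        pa, pb, pk = sd.edges[patch]
        if pk != "U":  # pragma: no cover - precluded by bridge structure
            raise StructuralError("patch edge expected to be undirected")
        w = pa if pb == v else pb
        return sd, (patch, w, f)
    if f_at_t:
        return sd, (e, u, info["patch"])
    return sd, (e, u, f)


def connect_sd(a: SemiDirectedNetwork, bnet: SemiDirectedNetwork,
               order=None) -> MoveSequence:
    """CET sequence between two semi-directed level-1 networks with equal
    leaf sets and reticulation numbers, obtained by projecting a rooted
    connector; length is at most that of the rooted sequence."""
    if a.labels != bnet.labels:
        raise InvalidMove("networks have different leaf sets")
    ka, kb = reticulation_count(a), reticulation_count(bnet)
    if ka != kb:
        raise InvalidMove("networks have different reticulation numbers")
    rep_a, rep_b = classify(a), classify(bnet)
    if not (rep_a.is_level1 and rep_b.is_level1):
        raise InvalidMove("both networks must be semi-directed level-1")
    n = len(a.labels)
    space = "sd-level1" if ka <= n - 2 else "sd-almost-level1"
    builder = _Builder(a, ClassConstraint(space, ka), bound=10 * n + 4 * ka)
    if _partner.is_isomorphic(a, bnet):
        return builder.done()
    pa, pb = rep_a.witness.network, rep_b.witness.network
    rseq = connect_rooted(pa, pb, order)
    rchain = [rseq.source] + list(rseq.networks)
    for i, rec in enumerate(rseq.records):
        before = rchain[i]
        sd_before, params = _project_cet(before, rec)
        if params is None:
            continue
        cut, supp, recip = params
        phi = _partner.find_isomorphism(sd_before, builder.cur)
        if phi is None:  # pragma: no cover - correctness gate
            raise StructuralError("projection lost isomorphism")
        em = _edge_map(sd_before, builder.cur, phi)
        sd_after = _partner.to_semidirected(rchain[i + 1])
        if _partner.is_isomorphic(sd_before, sd_after):
            continue
        builder.apply(em[cut], phi[supp], em[recip], kind="cet_sd",
                      check=True)
        if not _partner.is_isomorphic(builder.cur, sd_after):  # pragma: no cover
            raise StructuralError("projected CET missed the projected target")
    if not _partner.is_isomorphic(builder.cur, bnet):  # pragma: no cover
        raise StructuralError("semi-directed connector missed its target")
    return builder.done()


# ---------------------------------------------------------------------------
# extended CET connector (R-, tree walk, R+)
# ---------------------------------------------------------------------------


def _strip_reticulations(ns: SemiDirectedNetwork,
                         constraint: Optional[ClassConstraint],
                         ) -> MoveSequence:
    """Remove all reticulations by R- moves, topmost (in a rooted partner)
    first, yielding an unrooted tree."""
    b = _Builder(ns, constraint, bound=None)
    while reticulation_count(b.cur) > 0:
        cur = b.cur
        loops = cur.loops()
        candidates: list[int] = []
        if loops:
            candidates = loops
        else:
            wit = _partner.rooted_partners(cur)[0]
            depth = _depths(wit.network)
            rets = sorted(cur.reticulations(),
                          key=lambda v: (depth.get(v, 0), v))
            for v in rets:
                for e in sorted(cur.directed_in_edges(v)):
                    tail = cur.edges[e][0]
                    if not cur.is_reticulation(tail):
                        candidates.append(e)
                if candidates:
                    break
        applied = False
        for e in candidates:
            try:
                net, rec = _moves.apply_r_minus(b.cur, e, check=True)
            except InvalidMove:
                continue
            b.push(net, rec)
            applied = True
            break
        if not applied:  # pragma: no cover - topmost choice always works
            raise StructuralError("no applicable R- move found")
    return b.seq


def _caterpillar_walk(b: _Builder, order: list[str]) -> None:
    """Transform the current unrooted tree into the caterpillar on
    ``order`` by CETs (= unrooted SPR moves on trees).

    The spine is grown leaf by leaf: a cherry on the first two labels, then
    each next leaf is moved onto the current spine edge.  Leaves already in
    position are skipped, so no identity move is ever attempted."""
    labs = order
    m = len(labs)
    if m <= 3:
        return  # every tree on at most three leaves is the caterpillar
    cur = b.cur
    l0, l1 = cur.leaf_of(labs[0]), cur.leaf_of(labs[1])
    p0 = cur.other_end(cur.incident(l0)[0], l0)
    p1 = cur.other_end(cur.incident(l1)[0], l1)
    if p0 != p1:
        b.apply(cur.incident(l1)[0], p1, cur.incident(l0)[0], kind="cet_sd",
                check=True)
    cur = b.cur
    l0 = cur.leaf_of(labs[0])
    attach = cur.other_end(cur.incident(l0)[0], l0)
    l1 = cur.leaf_of(labs[1])
    spine = [e for e in cur.incident(attach)
             if cur.other_end(e, attach) not in (l0, l1)][0]
    for i in range(2, m - 2):
        cur = b.cur
        li = cur.leaf_of(labs[i])
        rest = cur.other_end(spine, attach)
        rest_edges = [e for e in cur.incident(rest) if e != spine]
        pend = [e for e in rest_edges if cur.other_end(e, rest) == li]
        if pend:
            attach = rest
            spine = [e for e in rest_edges if e != pend[0]][0]
            continue
        pe = cur.incident(li)[0]
        pv = cur.other_end(pe, li)
        b.apply(pe, pv, spine, kind="cet_sd", check=True)
        cur = b.cur
        li = cur.leaf_of(labs[i])
        attach = cur.other_end(cur.incident(li)[0], li)
        spine = [e for e in cur.incident(attach)
                 if cur.other_end(e, attach) == rest][0]


def _reachable_leaves(ns: SemiDirectedNetwork, via_edge: int,
                      start: int) -> set[str]:
    """Labels reachable from ``start`` through ``via_edge`` (not back)."""
    first = ns.other_end(via_edge, start)
    seen = {start, first}
    stack = [first]
    labs = set()
    while stack:
        v = stack.pop()
        if v in ns.leaf_labels:
            labs.add(ns.leaf_labels[v])
        for e in ns.incident(v):
            if e == via_edge and v == first:
                continue
            o = ns.other_end(e, v)
            if o not in seen:
                seen.add(o)
                stack.append(o)
    return labs


def connect_extended(a: SemiDirectedNetwork, bnet: SemiDirectedNetwork,
                     level1_only: bool = False) -> MoveSequence:
    """Extended-CET (CET, R-, R+) sequence between two semi-directed
    networks on the same leaf set.

    Strips a's reticulations with R- (ancestor-respecting order from a
    rooted partner), connects the two resulting unrooted trees by CETs via
    the caterpillar on the natural leaf order, and rebuilds b's
    reticulations by replaying its R- records in reverse.  With
    ``level1_only`` every intermediate is a semi-directed level-1 network.
    """
    if a.labels != bnet.labels:
        raise InvalidMove("networks have different leaf sets")
    constraint = ClassConstraint("sd-level1", None) if level1_only else \
        ClassConstraint("sd-all", None)
    if level1_only and not (classify(a).is_level1
                            and classify(bnet).is_level1):
        raise InvalidMove("both networks must be level-1")
    builder = _Builder(a, constraint, bound=None)
    if _partner.is_isomorphic(a, bnet):
        return builder.done()
    strip_a = _strip_reticulations(a, constraint)
    for rec, net in zip(strip_a.records, strip_a.networks):
        builder.cur = net
        builder.seq.records.append(rec)
        builder.seq.networks.append(net)
        builder.seq.certificates.append(classify(net))
    order = natural_leaf_order(a.labels)
    _caterpillar_walk(builder, order)
    strip_b = _strip_reticulations(bnet, constraint)
    # walk from b's stripped tree to the caterpillar, then reverse it
    bt = _Builder(strip_b.final, constraint, bound=None)
    _caterpillar_walk(bt, order)
    walk_b = bt.done()
    append_reversed(builder, walk_b)
    append_reversed(builder, strip_b)
    if not _partner.is_isomorphic(builder.cur, bnet):  # pragma: no cover
        raise StructuralError("extended connector missed its target")
    return builder.done()


# ---------------------------------------------------------------------------
# CET -> CET_1 decomposition
# ---------------------------------------------------------------------------


def decompose_to_cet1(ns: SemiDirectedNetwork,
                      record: MoveRecord) -> MoveSequence:
    """Decompose one CET on a semi-directed (almost) level-1 network into a
    CET_1 sequence with the isomorphic end result.

    The pruned component is walked edge by edge along a shortest undirected
    path from the suppressed endpoint to the recipient edge; every step is a
    CET_1 and every intermediate stays in the class of the endpoints.  CETs
    that relocate a parallel pair or exchange a loop for parallel pairs are
    excluded (they cannot be localised without leaving the class).
    """
    if record.kind != "CET_sd":
        raise InvalidMove("decomposition applies to semi-directed CETs")
    cut, u, recip = record.cut_edge, record.suppressed_end, record.recipient
    if _moves.changes_parallel_pair_location(ns, cut, u, recip):
        raise ExcludedMove("CET changes the location of a parallel pair")
    if _moves.exchanges_loop_for_parallel_pairs(ns, cut, u, recip):
        raise ExcludedMove("CET exchanges a loop for parallel pairs")
    rep = classify(ns)
    n = len(ns.labels)
    k = rep.k
    if k <= n - 2 and not rep.is_level1:
        raise InvalidMove("network must be level-1 when k <= |X| - 2")
    if k == n - 1 and not rep.is_almost_level1:
        raise InvalidMove("network must be almost level-1 when k = |X| - 1")
    space = "sd-level1" if k <= n - 2 else "sd-almost-level1"
    one_step, _ = apply_cet_sd(ns, cut, u, recip, check=True)

    a, bv, _ = ns.edges[cut]
    v = bv if a == u else a
    builder = _Builder(ns, ClassConstraint(space, k), bound=None)
    if _moves.is_cet1(record, ns):
        builder.apply(cut, u, recip, kind="cet_sd", check=True)
        return builder.done()

    # shortest undirected path from u to the recipient edge, avoiding the
    # component of v
    v_side = _moves._component_without(ns, cut, v)
    prev: dict[int, tuple[int, int]] = {u: (None, None)}
    frontier = [u]
    goal = None
    p_end, q_end, _ = ns.edges[recip]
    while frontier and goal is None:
        nxt = []
        for x in frontier:
            for e in sorted(ns.incident(x)):
                if e == cut or ns.is_loop(e):
                    continue
                o = ns.other_end(e, x)
                if o in v_side or o in prev:
                    continue
                prev[o] = (x, e)
                if o in (p_end, q_end):
                    goal = o
                    break
                nxt.append(o)
            if goal is not None:
                break
        frontier = nxt
    if goal is None:  # pragma: no cover - recipient is in u's component
        raise StructuralError("no path from u to the recipient edge")
    path_edges: list[int] = []
    x = goal
    while prev[x][0] is not None:
        path_edges.append(prev[x][1])
        x = prev[x][0]
    path_edges.reverse()
    if path_edges and path_edges[-1] == recip:
        pass
    else:
        path_edges.append(recip)

    # walk: step j deletes the current cut edge and subdivides path edge j
    cur_cut, cur_supp = cut, u
    for j in range(1, len(path_edges)):
        before = builder.cur
        rec = builder.apply(cur_cut, cur_supp, path_edges[j], kind="cet_sd",
                            check=True)
        if not _moves.is_cet1(rec, before):  # pragma: no cover - by design
            raise StructuralError("decomposition produced a non-CET_1 step")
        cur_cut, cur_supp = rec.new_edge, rec.new_vertex
    if not _partner.is_isomorphic(builder.cur, one_step):  # pragma: no cover
        raise StructuralError("CET_1 walk did not reach the one-step result")
    return builder.done()
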