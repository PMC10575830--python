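"""Rearrangement moves: CET (rooted and semi-directed), R- and R+.

A cut edge transfer (CET) deletes a cut edge e = (u, v) (rooted) or
e = {u, v} (semi-directed), suppresses the freed endpoint u, subdivides an
edge of the component on u's side with a new vertex u', and reattaches v to
u' with a new edge.  The two edges at u other than e are the *donor* edges;
the subdivided edge is the *recipient*.  A CET_1 is a CET whose recipient is
incident with a donor edge (the NNI-like local case).

R- removes one reticulation from a semi-directed network, R+ adds one; the
two are mutually inverse.  Every apply_* function returns the rearranged
network together with a :class:`MoveRecord` that can be replayed and that
carries the inverse move, expressed against the result network's edge ids.

Moves are parameterised by edge ids and a suppressed endpoint, never by
vertex names alone, so records remain meaningful for parallel pairs.  When a
record would reference a donor edge as recipient, the donor id is remapped to
the merged edge produced by the suppression.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import networkx as nx

from . import partner as _partner
from .netcore import (
    ClassConstraint,
    Network,
    RootedNetwork,
    SemiDirectedNetwork,
    StructuralError,
    cut_edges,
    cycles,
    reticulation_count,
    validate,
)

__all__ = [
    "MoveRecord",
    "RPlusSpec",
    "InvalidMove",
    "apply_cet_rooted",
    "cet_valid_sd",
    "apply_cet_sd",
    "apply_move",
    "enumerate_cet_neighbors",
    "is_cet1",
    "apply_r_minus",
    "apply_r_plus",
    "changes_parallel_pair_location",
    "exchanges_loop_for_parallel_pairs",
]


class InvalidMove(ValueError):
    """A move precondition is violated; the message names the clause."""


@dataclass
class RPlusSpec:
    """Parameters of an R+ move.

    variant 'loop': subdivide ``edge`` with v, attach a new vertex u by an
    undirected edge and put a directed loop on u.

    variant 'subdiv': subdivide ``edge`` with v, subdivide ``edge2`` with u,
    add the directed edge (u, v), and direct the ``head_side`` half of
    ``edge`` (0 = the half towards the stored first endpoint) into v.
    ``edge2`` is either ``("orig", edge_id)`` or ``("half", i)`` naming one
    of the two halves of ``edge`` created by the first subdivision.
    """

    variant: str
    edge: int
    edge2: Optional[tuple] = None
    head_side: Optional[int] = None


@dataclass
class MoveRecord:
    """One rearrangement event, replayable and invertible.

    ``kind`` is one of CET_rooted, CET_sd, R_minus, R_plus.  For CETs,
    ``cut_edge`` / ``suppressed_end`` / ``donor_edges`` / ``recipient``
    describe the move on the source network; ``new_edge`` / ``merged_edge`` /
    ``new_vertex`` describe the result.  ``identity`` flags a CET whose
    result is isomorphic to its source (not a move in the strict sense).
    """

    kind: str
    cut_edge: Optional[int] = None
    suppressed_end: Optional[int] = None
    donor_edges: tuple = ()
    recipient: Optional[int] = None
    r_edge: Optional[int] = None          # R-: the reticulation edge removed
    r_plus: Optional[RPlusSpec] = None    # R+: the addition parameters
    new_edge: Optional[int] = None
    merged_edge: Optional[int] = None
    new_vertex: Optional[int] = None
    identity: bool = False
    inverse: Optional["MoveRecord"] = None
    witness: Optional[object] = None      # partner witnessing sd validity


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


def _component_without(net: Network, e: int, anchor: int) -> set[int]:
    """Vertices of the component containing ``anchor`` after deleting ``e``."""
    g = nx.Graph()
    g.add_nodes_from(net.vertices if isinstance(net, RootedNetwork)
                     else net.vertices)
    items = (net.edges.items() if isinstance(net, SemiDirectedNetwork)
             else {k: (u, v, "D") for k, (u, v) in net.edges.items()}.items())
    for f, (a, b, _) in items:
        if f == e or a == b:
            continue
        g.add_edge(a, b)
    return nx.node_connected_component(g, anchor)


def _edge_endpoints(net: Network, e: int) -> tuple[int, int]:
    rec = net.edges[e]
    return rec[0], rec[1]


# ---------------------------------------------------------------------------
# rooted CET
# ---------------------------------------------------------------------------


def apply_cet_rooted(nr: RootedNetwork, cut_edge: int, recipient: int,
                     check: bool = True) -> tuple[RootedNetwork, MoveRecord]:
    """CET on a rooted network: cut (u, v), suppress u, re-attach v.

    ``recipient`` is an edge id of the source network lying in the root
    component after the cut; a donor edge id is accepted and remapped to the
    merged edge that the suppression of u produces.
    """
    if cut_edge not in nr.edges:
        raise InvalidMove(f"no such edge {cut_edge}")
    u, v = nr.edges[cut_edge]
    if check:
        if u == nr.root or v == nr.root:
            raise InvalidMove("cut edge is incident with the root")
        if nr.in_degree(u) == 2:
            raise InvalidMove("suppressed endpoint u is a reticulation")
        if cut_edge not in cut_edges(nr):
            raise InvalidMove("edge is not a cut edge")
    v_side = _component_without(nr, cut_edge, v)
    donors = tuple(sorted(set(nr.in_edges(u) + nr.out_edges(u)) - {cut_edge}))
    if recipient == cut_edge:
        raise InvalidMove("recipient cannot be the cut edge itself")
    if recipient not in nr.edges:
        raise InvalidMove(f"no such recipient edge {recipient}")
    ra, rb = nr.edges[recipient]
    if ra in v_side or rb in v_side:
        raise InvalidMove("recipient edge is not in the root component")

    m = nr.copy()
    m.remove_edge(cut_edge)
    merged = m.suppress(u)
    target = recipient if recipient in m.edges else merged
    w, _, _ = m.subdivide(target)
    new_edge = m.add_edge(w, v)

    rec = MoveRecord(kind="CET_rooted", cut_edge=cut_edge, suppressed_end=u,
                     donor_edges=donors, recipient=recipient,
                     new_edge=new_edge, merged_edge=merged, new_vertex=w)
    inv_donors = tuple(sorted(set(m.in_edges(w) + m.out_edges(w)) - {new_edge}))
    rec.inverse = MoveRecord(kind="CET_rooted", cut_edge=new_edge,
                             suppressed_end=w, donor_edges=inv_donors,
                             recipient=merged)
    if check:
        rec.identity = _partner.is_isomorphic(nr, m)
        rec.inverse.identity = rec.identity
    return m, rec


# ---------------------------------------------------------------------------
# semi-directed CET
# ---------------------------------------------------------------------------


def cet_valid_sd(ns: SemiDirectedNetwork, cut_edge: int,
                 suppressed_end: int) -> tuple[bool, Optional[object]]:
    """Whether (cut_edge, suppressed endpoint u) admits a semi-directed CET.

    True iff u is internal, not a reticulation, and some rooted partner
    either has u as a parent of v (condition 1) or has the three-cut-edge
    root configuration over {u, v} (condition 2).  Returns the witnessing
    partner.
    """
    if cut_edge not in ns.edges:
        raise InvalidMove(f"no such edge {cut_edge}")
    a, b, kind = ns.edges[cut_edge]
    if suppressed_end not in (a, b):
        raise InvalidMove("suppressed end is not an endpoint of the cut edge")
    if kind != "U" or cut_edge not in cut_edges(ns):
        raise InvalidMove("edge is not an undirected cut edge")
    u = suppressed_end
    v = b if a == u else a
    if ns.degree(u) != 3 or ns.is_reticulation(u):
        return False, None
    for wit in _partner.rooted_partners(ns):
        nr = wit.network
        # condition 1: u is a parent of v in the partner
        if any(nr.edges[e] == (u, v) for e in nr.out_edges(u)):
            return True, wit
        # condition 2: three cut edges (rho,t), (t,u), (t,v)
        t = nr.children(nr.root)[0]
        kids = nr.children(t)
        if sorted(kids) == sorted([u, v]):
            bridges = cut_edges(nr)
            t_edges = [nr.out_edges(nr.root)[0]] + nr.out_edges(t)
            if all(e in bridges for e in t_edges):
                return True, wit
    return False, None


def apply_cet_sd(ns: SemiDirectedNetwork, cut_edge: int, suppressed_end: int,
                 recipient: int, check: bool = True,
                 ) -> tuple[SemiDirectedNetwork, MoveRecord]:
    """CET on a semi-directed network.

    The recipient may be any edge (including a loop or one of a parallel
    pair) of the component not containing v; subdividing a loop produces a
    parallel directed pair.  The result is checked to be a semi-directed
    network; the partner-certified validity condition is enforced through
    :func:`cet_valid_sd` when ``check`` is set.
    """
    witness = None
    if check:
        ok, witness = cet_valid_sd(ns, cut_edge, suppressed_end)
        if not ok:
            raise InvalidMove("no rooted partner certifies this cut "
                              "edge/endpoint choice")
    a, b, _ = ns.edges[cut_edge]
    u = suppressed_end
    v = b if a == u else a
    v_side = _component_without(ns, cut_edge, v)
    donors = tuple(sorted(set(ns.incident(u)) - {cut_edge}))
    if recipient == cut_edge or recipient not in ns.edges:
        raise InvalidMove("recipient must be an existing edge other than the "
                          "cut edge")
    ra, rb, _ = ns.edges[recipient]
    if ra in v_side or rb in v_side:
        raise InvalidMove("recipient edge lies in the component containing v")

    m = ns.copy()
    m.remove_edge(cut_edge)
    merged = m.suppress(u)
    target = recipient if recipient in m.edges else merged
    w, _ = m.subdivide(target)
    new_edge = m.add_edge(w, v, "U")

    rec = MoveRecord(kind="CET_sd", cut_edge=cut_edge, suppressed_end=u,
                     donor_edges=donors, recipient=recipient,
                     new_edge=new_edge, merged_edge=merged, new_vertex=w,
                     witness=witness)
    inv_donors = tuple(sorted(set(m.incident(w)) - {new_edge}))
    rec.inverse = MoveRecord(kind="CET_sd", cut_edge=new_edge,
                             suppressed_end=w, donor_edges=inv_donors,
                             recipient=merged)
    if check:
        rep = validate(m)
        if not rep.ok:
            raise InvalidMove("result is not a semi-directed network: "
                              + "; ".join(rep.violations))
        rec.identity = _partner.is_isomorphic(ns, m)
        rec.inverse.identity = rec.identity
    return m, rec


def is_cet1(record: MoveRecord, source: Network) -> bool:
    """True iff the CET's recipient edge is incident with a donor edge."""
    if record.kind not in ("CET_rooted", "CET_sd"):
        raise ValueError("is_cet1 applies to CET records only")
    rec_edge = record.recipient
    if rec_edge in record.donor_edges:
        return True  # recipient was a donor edge itself (remapped to merged)
    r = _edge_endpoints(source, rec_edge)
    for d in record.donor_edges:
        de = _edge_endpoints(source, d)
        if set(r) & set(de):
            return True
    return False


# ---------------------------------------------------------------------------
# neighbor enumeration
# ---------------------------------------------------------------------------


def enumerate_cet_neighbors(net: Network, constraint: ClassConstraint,
                            require_cet1: bool = False,
                            ) -> list[tuple[Network, MoveRecord]]:
    """All pairwise non-isomorphic single-CET results satisfying the
    constraint, excluding results isomorphic to the input.

    With ``require_cet1`` only moves whose recipient is incident with a
    donor edge are considered (the NNI-like neighbourhood)."""
    out: list[tuple[Network, MoveRecord]] = []
    seen: set = set()
    source_key = _partner.canonical_key(net)
    if isinstance(net, RootedNetwork):
        for e in sorted(cut_edges(net)):
            u, v = net.edges[e]
            if u == net.root or net.in_degree(u) == 2:
                continue
            v_side = _component_without(net, e, v)
            for f in sorted(net.edges):
                if f == e:
                    continue
                fa, fb = net.edges[f]
                if fa in v_side or fb in v_side:
                    continue
                try:
                    m, rec = apply_cet_rooted(net, e, f, check=False)
                except (InvalidMove, StructuralError):
                    continue
                if require_cet1 and not is_cet1(rec, net):
                    continue
                _collect(m, rec, constraint, source_key, seen, out)
    else:
        for e in sorted(cut_edges(net)):
            a, b, kind = net.edges[e]
            if kind != "U":
                continue
            for u in sorted({a, b}):
                v = b if a == u else a
                if net.degree(u) != 3 or net.is_reticulation(u):
                    continue
                ok, wit = cet_valid_sd(net, e, u)
                if not ok:
                    continue
                v_side = _component_without(net, e, v)
                for f in sorted(net.edges):
                    if f == e:
                        continue
                    fa, fb, _ = net.edges[f]
                    if fa in v_side or fb in v_side:
                        continue
                    try:
                        m, rec = apply_cet_sd(net, e, u, f, check=False)
                    except (InvalidMove, StructuralError):
                        continue
                    rec.witness = wit
                    if require_cet1 and not is_cet1(rec, net):
                        continue
                    if not validate(m).ok:
                        continue
                    _collect(m, rec, constraint, source_key, seen, out)
    return out


def _collect(m, rec, constraint, source_key, seen, out):
    if not constraint.check(m):
        return
    key = _partner.canonical_key(m)
    if key == source_key:
        rec.identity = True
        return
    if key in seen:
        return
    seen.add(key)
    out.append((m, rec))


# ---------------------------------------------------------------------------
# R- and R+
# ---------------------------------------------------------------------------


def apply_r_minus(ns: SemiDirectedNetwork, r_edge: int,
                  check: bool = True) -> tuple[SemiDirectedNetwork, MoveRecord]:
    """Remove one reticulation.

    Loop case: delete the loop vertex and suppress its freed neighbour (a
    2-cycle at that neighbour collapses to a loop).  Non-loop case: undirect
    the sibling reticulation edge, delete (u, v), and suppress u and v.  The
    returned record's inverse is the matching R+.
    """
    if r_edge not in ns.edges:
        raise InvalidMove(f"no such edge {r_edge}")
    a, b, kind = ns.edges[r_edge]
    if kind != "D":
        raise InvalidMove("R- requires a reticulation edge (directed)")
    m = ns.copy()
    if a == b:  # loop at vertex a
        lv = a
        third = [e for e in m.incident(lv) if e != r_edge]
        if len(third) != 1:
            raise InvalidMove("loop vertex does not have a unique third edge")
        w = m.other_end(third[0], lv)
        m.remove_edge(r_edge)
        m.remove_edge(third[0])
        merged = m.suppress(w)
        rec = MoveRecord(kind="R_minus", r_edge=r_edge, merged_edge=merged)
        rec.inverse = MoveRecord(kind="R_plus",
                                 r_plus=RPlusSpec(variant="loop", edge=merged))
    else:
        u, v = a, b
        if ns.is_reticulation(u):
            raise InvalidMove("tail of the reticulation edge is a reticulation")
        sibling = [e for e in ns.directed_in_edges(v) if e != r_edge]
        if len(sibling) != 1:
            raise InvalidMove("head is not a two-in-edge reticulation")
        f = sibling[0]
        w = m.edges[f][0]
        # the remaining edge at u that is neither e nor f (for the parallel
        # pair case u == w, where f is consumed by the suppression of u)
        u_rest = [e for e in m.incident(u) if e not in (r_edge, f)]
        p_side_vertex = m.other_end(u_rest[0], u) if u_rest else None
        m.edges[f] = (w, v, "U")  # undirect the sibling edge
        m.remove_edge(r_edge)
        try:
            merged_u = m.suppress(u)
        except StructuralError as exc:
            raise InvalidMove(f"freed tail is not suppressible: {exc}")
        merged_v = m.suppress(v)
        x0, x1 = m.edges[merged_v][0], m.edges[merged_v][1]
        if u == w:
            # parallel-pair case: the inverse re-subdivides the half of the
            # merged edge towards u's third neighbour and directs the u-v
            # piece into v
            head_side = 0 if x0 == p_side_vertex else 1
            edge2: tuple = ("half", head_side)
        else:
            head_side = 0 if x0 == w else 1
            if merged_u in m.edges:
                edge2 = ("orig", merged_u)
            else:
                # u's merged edge was consumed when suppressing v (u and v
                # shared an extra edge): u sits on the non-w half
                edge2 = ("half", 1 - head_side)
        rec = MoveRecord(kind="R_minus", r_edge=r_edge, merged_edge=merged_v)
        rec.inverse = MoveRecord(
            kind="R_plus",
            r_plus=RPlusSpec(variant="subdiv", edge=merged_v, edge2=edge2,
                             head_side=head_side))
    if check:
        rep = validate(m)
        if not rep.ok:
            raise InvalidMove("R- result is not a semi-directed network: "
                              + "; ".join(rep.violations))
        if reticulation_count(m) != reticulation_count(ns) - 1:
            raise InvalidMove("R- did not decrease the reticulation count "
                              "by exactly one")
    return m, rec


def apply_r_plus(ns: SemiDirectedNetwork, spec: RPlusSpec,
                 check: bool = True) -> tuple[SemiDirectedNetwork, MoveRecord]:
    """Add one reticulation; raises when the result is not semi-directed
    (for example a second loop)."""
    if spec.edge not in ns.edges:
        raise InvalidMove(f"no such edge {spec.edge}")
    m = ns.copy()
    if spec.variant == "loop":
        v, _ = m.subdivide(spec.edge)
        u = m.new_vertex()
        m.add_edge(u, v, "U")
        loop = m.add_edge(u, u, "D")
        rec = MoveRecord(kind="R_plus", r_plus=spec, new_edge=loop,
                         new_vertex=u)
        rec.inverse = MoveRecord(kind="R_minus", r_edge=loop)
    elif spec.variant == "subdiv":
        v, halves = m.subdivide(spec.edge)
        if spec.edge2[0] == "orig":
            target = spec.edge2[1]
            if target not in m.edges:
                raise InvalidMove(f"no such edge {target} for the second "
                                  "subdivision")
        else:
            target = halves[spec.edge2[1]]
        u, _ = m.subdivide(target)
        new_edge = m.add_edge(u, v, "D")
        chosen = _pick_head_edge(ns, m, spec, v, u, new_edge, halves)
        x, y, k = m.edges[chosen]
        if k != "U":
            raise InvalidMove("edge to be directed into v is not undirected")
        tail = y if x == v else x
        m.edges[chosen] = (tail, v, "D")
        rec = MoveRecord(kind="R_plus", r_plus=spec, new_edge=new_edge,
                         new_vertex=v)
        rec.inverse = MoveRecord(kind="R_minus", r_edge=new_edge)
    else:
        raise InvalidMove(f"unknown R+ variant {spec.variant!r}")
    if check:
        rep = validate(m)
        if not rep.ok:
            raise InvalidMove("R+ result is not a semi-directed network: "
                              + "; ".join(rep.violations))
        if reticulation_count(m) != reticulation_count(ns) + 1:
            raise InvalidMove("R+ did not increase the reticulation count "
                              "by exactly one")
    return m, rec


def _pick_head_edge(ns, m, spec, v, u, new_edge, halves):
    """The v-incident edge on ``head_side`` of the subdivided edge."""
    # After the first subdivision v's neighbours towards side i of the
    # original edge are reached through halves[i]; the second subdivision may
    # have split one half with u, in which case the v-incident piece is the
    # edge joining u and v.
    side = spec.head_side
    half = halves[side]
    if half in m.edges:
        return half
    # the chosen half was subdivided by u: v's piece is the u-v edge that is
    # not the new directed edge
    for e in m.incident(v):
        if e == new_edge:
            continue
        x, y, _ = m.edges[e]
        if u in (x, y):
            return e
    raise InvalidMove("cannot locate the edge to direct into v")


def apply_move(net: Network, record: MoveRecord,
               check: bool = True) -> tuple[Network, MoveRecord]:
    """Replay a move record on a network (dispatch on kind)."""
    if record.kind == "CET_rooted":
        return apply_cet_rooted(net, record.cut_edge, record.recipient,
                                check=check)
    if record.kind == "CET_sd":
        return apply_cet_sd(net, record.cut_edge, record.suppressed_end,
                            record.recipient, check=check)
    if record.kind == "R_minus":
        return apply_r_minus(net, record.r_edge, check=check)
    if record.kind == "R_plus":
        return apply_r_plus(net, record.r_plus, check=check)
    raise ValueError(f"unknown move kind {record.kind!r}")


# ---------------------------------------------------------------------------
# special CET types (used by the CET_1 decomposition)
# ---------------------------------------------------------------------------


def _cycle_of_edge(recs, e: int):
    for rec in recs:
        if e in rec.edge_ids:
            return rec
    return None


def changes_parallel_pair_location(ns: SemiDirectedNetwork, cut_edge: int,
                                   suppressed_end: int, recipient: int) -> bool:
    """CET whose donors lie on a 3-cycle and whose recipient lies on a
    2-cycle: it relocates a parallel pair."""
    recs = cycles(ns)
    donors = sorted(set(ns.incident(suppressed_end)) - {cut_edge})
    donor_cycles = [_cycle_of_edge(recs, d) for d in donors]
    if any(c is None for c in donor_cycles):
        return False
    if donor_cycles[0] is not donor_cycles[1] or donor_cycles[0].length != 3:
        return False
    rc = _cycle_of_edge(recs, recipient)
    return rc is not None and rc.length == 2


def exchanges_loop_for_parallel_pairs(ns: SemiDirectedNetwork, cut_edge: int,
                                      suppressed_end: int,
                                      recipient: int) -> bool:
    """CET that trades a loop for two parallel pairs or vice versa."""
    recs = cycles(ns)
    donors = sorted(set(ns.incident(suppressed_end)) - {cut_edge})
    donor_cycles = [_cycle_of_edge(recs, d) for d in donors]
    if any(c is None for c in donor_cycles) or \
            donor_cycles[0] is not donor_cycles[1]:
        return False
    rc = _cycle_of_edge(recs, recipient)
    # (i) donors on a 3-cycle, recipient is the loop
    if donor_cycles[0].length == 3 and recipient in ns.loops():
        return True
    # (ii) donors form a 2-cycle, recipient on a (different) 2-cycle
    if (donor_cycles[0].length == 2 and rc is not None
            and rc.length == 2 and rc is not donor_cycles[0]):
        return True
    return False
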