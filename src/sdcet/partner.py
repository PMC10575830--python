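"""Conversions between rooted and semi-directed networks, and isomorphism.

A semi-directed network arises from a rooted network by undirecting all tree
edges, deleting the root and its child ``u``, and patching the hole in one of
three ways keyed on the edge types at ``u``:

* (s1) ``u`` carries a parallel pair of reticulation edges into ``w``: add a
  directed loop ``(w, w)``;
* (s2) ``u`` has one reticulation edge ``(u, v)`` and one tree edge
  ``(u, v')``: add a directed edge ``(v', v)``;
* (s3) ``u`` has two tree edges: add an undirected edge ``{v, v'}``.

``rooted_partners`` inverts this: the loop case has a unique inversion, and
otherwise every undirected and every directed edge is tried as the place to
restore the root, with the orientation of the remaining undirected edges
recovered by constraint propagation (with backtracking as a completeness
fallback).  Candidates that fail rooted validation are discarded, and the
survivors are deduplicated up to label-preserving isomorphism.

Isomorphism here always fixes leaf labels pointwise.  ``canonical_key``
provides a hashable token with key equality iff isomorphism, implemented by
iterative colour refinement seeded with leaf labels and edge kinds, falling
back to individualisation when refinement stabilises with non-singleton
cells.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .netcore import (
    Network,
    RootedNetwork,
    SemiDirectedNetwork,
    StructuralError,
    validate,
)

__all__ = [
    "PartnerWitness",
    "to_semidirected",
    "to_semidirected_with_map",
    "rooted_partners",
    "is_isomorphic",
    "find_isomorphism",
    "canonical_key",
]


@dataclass
class PartnerWitness:
    """A rooted partner together with the construction case that produced it.

    ``case`` is the construction applied in ``to_semidirected`` direction;
    ``site`` describes where the root was restored: for s1 the loop vertex,
    for s2 the directed edge id of the semi-directed network, for s3 the
    undirected edge id.
    """

    network: RootedNetwork
    case: str
    site: object = None


# ---------------------------------------------------------------------------
# rooted -> semi-directed
# ---------------------------------------------------------------------------


def to_semidirected_with_map(nr: RootedNetwork) -> tuple[SemiDirectedNetwork, dict]:
    """Project a rooted network; also report how the root was removed.

    Edge ids of edges untouched by the construction are preserved, which lets
    move records on the rooted network be projected onto the semi-directed
    one.  The info dict contains ``case``, the removed rooted edge ids, and
    the id of the freshly added patch edge (``None`` in the degenerate
    two-leaf s3 case where the patch edge simply replaces the hole).
    """
    rep = validate(nr)
    if not rep.ok:
        raise StructuralError("invalid rooted network: " + "; ".join(rep.violations))
    root = nr.root
    e_root = nr.out_edges(root)[0]
    u = nr.edges[e_root][1]
    out = sorted(nr.out_edges(u))
    if len(out) != 2:
        raise StructuralError("root child does not have out-degree two")
    heads = [nr.edges[e][1] for e in out]
    retic = {v for v in nr.vertices if nr.in_degree(v) == 2}

    sd_edges: dict[int, tuple[int, int, str]] = {}
    for e, (a, b) in nr.edges.items():
        if e == e_root or e in out:
            continue
        kind = "D" if b in retic else "U"
        sd_edges[e] = (a, b, kind)
    sd = SemiDirectedNetwork(sd_edges, nr.leaf_labels)
    info: dict = {"removed": [e_root] + out, "root_child": u}

    if heads[0] == heads[1] and heads[0] in retic:
        w = heads[0]
        patch = sd.add_edge(w, w, "D")
        info.update(case="s1", patch=patch, site=w)
    else:
        r_edges = [e for e in out if nr.edges[e][1] in retic]
        if len(r_edges) == 1:
            v = nr.edges[r_edges[0]][1]
            vp = [nr.edges[e][1] for e in out if e != r_edges[0]][0]
            patch = sd.add_edge(vp, v, "D")
            info.update(case="s2", patch=patch, site=(vp, v))
        elif len(r_edges) == 0:
            v, vp = heads
            patch = sd.add_edge(v, vp, "U")
            info.update(case="s3", patch=patch, site=(v, vp))
        else:
            raise StructuralError(
                "root child has two reticulation edges to distinct vertices")
    return sd, info


def to_semidirected(nr: RootedNetwork) -> SemiDirectedNetwork:
    """The semi-directed network obtained from a rooted network."""
    return to_semidirected_with_map(nr)[0]


# ---------------------------------------------------------------------------
# semi-directed -> rooted: orientation solver
# ---------------------------------------------------------------------------


def _orient(fixed: list[tuple[int, int]], und: list[tuple[int, int]],
            root: int, vertices: set[int]) -> Optional[list[tuple[int, int]]]:
    """Orient undirected edges so every non-root vertex has in-degree 1,
    except vertices already saturated by fixed directed in-edges.

    Returns oriented (tail, head) pairs aligned with ``und``, or None.
    Propagation assigns forced orientations; an exhaustive branch step keeps
    the search complete on the rare inputs where propagation stalls.
    """
    need: dict[int, int] = {}
    for v in vertices:
        fixed_in = sum(1 for _, h in fixed if h == v)
        if v == root:
            need[v] = 0
        elif fixed_in >= 1:
            need[v] = 0  # reticulation: both in-edges are fixed directed edges
        else:
            need[v] = 1
    if sum(need.values()) != len(und):
        return None

    incid: dict[int, list[int]] = {v: [] for v in vertices}
    for i, (a, b) in enumerate(und):
        incid[a].append(i)
        incid[b].append(i)

    orient: list[Optional[tuple[int, int]]] = [None] * len(und)

    def solve(orient, need):
        # propagate forced orientations
        changed = True
        while changed:
            changed = False
            for v in vertices:
                open_ids = [i for i in incid[v] if orient[i] is None]
                got = sum(1 for i in incid[v]
                          if orient[i] is not None and orient[i][1] == v)
                if got > need[v]:
                    return None
                remaining = need[v] - got
                if remaining < 0 or remaining > len(open_ids):
                    return None
                if open_ids and remaining == 0:
                    for i in open_ids:
                        a, b = und[i]
                        other = b if a == v else a
                        orient[i] = (v, other)
                    changed = True
                elif open_ids and remaining == len(open_ids):
                    for i in open_ids:
                        a, b = und[i]
                        other = b if a == v else a
                        orient[i] = (other, v)
                    changed = True
        if all(o is not None for o in orient):
            return orient
        # branch on the first undecided edge
        i = next(j for j, o in enumerate(orient) if o is None)
        a, b = und[i]
        for choice in ((a, b), (b, a)):
            trial = list(orient)
            trial[i] = choice
            res = solve(trial, need)
            if res is not None:
                return res
        return None

    return solve(orient, need)


def _try_root_candidate(ns: SemiDirectedNetwork, fixed: list[tuple[int, int]],
                        und: list[tuple[int, int]], root: int, root_child: int,
                        vertices: set[int],
                        leaf_labels: dict[int, str]) -> Optional[RootedNetwork]:
    oriented = _orient(fixed, und, root, vertices)
    if oriented is None:
        return None
    edges: dict[int, tuple[int, int]] = {}
    for i, pair in enumerate(fixed + oriented):
        edges[i] = pair
    cand = RootedNetwork(edges, root, leaf_labels)
    return cand if validate(cand).ok else None


def rooted_partners(ns: SemiDirectedNetwork,
                    validate_input: bool = True) -> list[PartnerWitness]:
    """All rooted partners of a semi-directed network, up to isomorphism.

    An empty result means the input is not a semi-directed phylogenetic
    network (there is nothing it can be obtained from).
    """
    if validate_input:
        rep = validate(ns, check_partner=False)
        if not rep.ok:
            raise StructuralError("invalid semi-directed network: "
                                  + "; ".join(rep.violations))
    witnesses: list[PartnerWitness] = []
    seen: set = set()
    base_vertices = ns.vertices
    next_v = max(base_vertices, default=-1) + 1
    rho, u = next_v, next_v + 1

    loops = ns.loops()
    if loops:
        if len(loops) > 1:
            return []
        loop_e = loops[0]
        w = ns.edges[loop_e][0]
        fixed = [(rho, u), (u, w), (u, w)]
        und: list[tuple[int, int]] = []
        for e, (a, b, kind) in ns.edges.items():
            if e == loop_e:
                continue
            if kind == "D":
                fixed.append((a, b))
            else:
                und.append((a, b))
        cand = _try_root_candidate(ns, fixed, und, rho, u,
                                   base_vertices | {rho, u}, ns.leaf_labels)
        if cand is not None:
            witnesses.append(PartnerWitness(cand, "s1", w))
        return witnesses

    directed = sorted(e for e, (_, _, k) in ns.edges.items() if k == "D")
    undirected = sorted(e for e, (_, _, k) in ns.edges.items() if k == "U")

    # s3 inversion: root along an undirected edge
    for e in undirected:
        a, b = ns.edges[e][0], ns.edges[e][1]
        fixed = [(rho, u), (u, a), (u, b)]
        und = []
        for f, (x, y, kind) in ns.edges.items():
            if f == e:
                continue
            if kind == "D":
                fixed.append((x, y))
            else:
                und.append((x, y))
        cand = _try_root_candidate(ns, fixed, und, rho, u,
                                   base_vertices | {rho, u}, ns.leaf_labels)
        if cand is not None:
            key = canonical_key(cand)
            if key not in seen:
                seen.add(key)
                witnesses.append(PartnerWitness(cand, "s3", e))

    # s2 inversion: replace a directed edge (v', v) by the rooted gadget
    for e in directed:
        vp, v = ns.edges[e][0], ns.edges[e][1]
        fixed = [(rho, u), (u, v), (u, vp)]
        und = []
        for f, (x, y, kind) in ns.edges.items():
            if f == e:
                continue
            if kind == "D":
                fixed.append((x, y))
            else:
                und.append((x, y))
        cand = _try_root_candidate(ns, fixed, und, rho, u,
                                   base_vertices | {rho, u}, ns.leaf_labels)
        if cand is not None:
            key = canonical_key(cand)
            if key not in seen:
                seen.add(key)
                witnesses.append(PartnerWitness(cand, "s2", e))
    return witnesses


# ---------------------------------------------------------------------------
# isomorphism
# ---------------------------------------------------------------------------


def _incidence(n: Network) -> dict[int, list[tuple[str, int]]]:
    """Per-vertex multiset of (edge tag, neighbour) entries.

    Tags: 'U' undirected, 'Do'/'Di' directed out/in, 'Lp' loop (two entries
    so a loop contributes 2 to the degree).
    """
    inc: dict[int, list[tuple[str, int]]] = {v: [] for v in _verts(n)}
    if isinstance(n, RootedNetwork):
        items = [(a, b, "D") for (a, b) in n.edges.values()]
    else:
        items = list(n.edges.values())
    for a, b, kind in items:
        if kind == "U":
            inc[a].append(("U", b))
            inc[b].append(("U", a))
        elif a == b:
            inc[a].append(("Lp", a))
            inc[a].append(("Lp", a))
        else:
            inc[a].append(("Do", b))
            inc[b].append(("Di", a))
    return inc


def _verts(n: Network) -> set[int]:
    return n.vertices


def canonical_key(n: Network):
    """Hashable token with equality iff label-preserving isomorphism."""
    inc = _incidence(n)
    verts = sorted(inc)
    root = n.root if isinstance(n, RootedNetwork) else None

    def init_colors() -> dict[int, tuple]:
        colors = {}
        for v in verts:
            if v in n.leaf_labels:
                colors[v] = ("leaf", n.leaf_labels[v])
            elif v == root:
                colors[v] = ("root",)
            else:
                colors[v] = ("int",)
        return colors

    def refine(colors: dict[int, tuple]) -> dict[int, int]:
        # compress to integers, then refine to a stable partition
        cur = _compress(colors)
        while True:
            new = {v: (cur[v], tuple(sorted((tag, cur[w])
                                            for tag, w in inc[v])))
                   for v in verts}
            newc = _compress(new)
            if _partition(newc) == _partition(cur):
                return cur
            cur = newc

    def canonical_form(cur: dict[int, int]):
        classes: dict[int, list[int]] = {}
        for v, c in cur.items():
            classes.setdefault(c, []).append(v)
        non_singleton = [c for c in sorted(classes) if len(classes[c]) > 1]
        if not non_singleton:
            order = {v: i for i, v in
                     enumerate(sorted(verts, key=lambda v: cur[v]))}
            edges = []
            if isinstance(n, RootedNetwork):
                for a, b in n.edges.values():
                    edges.append(("D", order[a], order[b]))
            else:
                for a, b, kind in n.edges.values():
                    if kind == "U":
                        x, y = sorted((order[a], order[b]))
                        edges.append(("U", x, y))
                    else:
                        edges.append(("D", order[a], order[b]))
            labels = tuple(sorted((order[v], lab)
                                  for v, lab in n.leaf_labels.items()))
            return (tuple(sorted(edges)), labels)
        # individualise each vertex of the first non-singleton class
        target = non_singleton[0]
        best = None
        for v in classes[target]:
            trial = {w: (cur[w], 1 if w == v else 0) for w in verts}
            form = canonical_form(refine(trial))
            if best is None or form < best:
                best = form
        return best

    return canonical_form(refine(init_colors()))


def _compress(colors: dict) -> dict[int, int]:
    mapping = {c: i for i, c in enumerate(sorted(set(colors.values()),
                                                 key=repr))}
    return {v: mapping[c] for v, c in colors.items()}


def _partition(colors: dict[int, int]) -> frozenset:
    classes: dict[int, frozenset] = {}
    groups: dict[int, set] = {}
    for v, c in colors.items():
        groups.setdefault(c, set()).add(v)
    return frozenset(frozenset(g) for g in groups.values())


def find_isomorphism(a: Network, b: Network) -> Optional[dict[int, int]]:
    """A leaf-label-fixing isomorphism a -> b, or None.

    Backtracking over internal vertices anchored at the leaves (which are
    fixed points of any admissible bijection); for rooted inputs the root
    maps to the root.  Edge multisets between mapped pairs are compared
    including kind and direction.
    """
    if type(a) is not type(b):
        return None
    if a.labels != b.labels:
        return None
    if len(a.edges) != len(b.edges):
        return None
    inc_a, inc_b = _incidence(a), _incidence(b)
    rooted = isinstance(a, RootedNetwork)

    def local_sig(inc, v):
        return tuple(sorted(tag for tag, _ in inc[v]))

    mapping: dict[int, int] = {}
    used: set[int] = set()
    for v, lab in a.leaf_labels.items():
        w = b.leaf_of(lab)
        mapping[v] = w
        used.add(w)
    if rooted:
        if a.root in mapping or b.root in used:
            return None
        mapping[a.root] = b.root
        used.add(b.root)

    internal_a = [v for v in sorted(_verts(a)) if v not in mapping]
    internal_b = [v for v in sorted(_verts(b)) if v not in used]
    if len(internal_a) != len(internal_b):
        return None
    # order a's internal vertices by BFS from the already-mapped anchors
    order: list[int] = []
    seen = set(mapping)
    frontier = sorted(mapping)
    while frontier:
        nxt = []
        for v in frontier:
            for _, w in inc_a[v]:
                if w not in seen:
                    seen.add(w)
                    order.append(w)
                    nxt.append(w)
        frontier = nxt
    for v in internal_a:  # disconnected leftovers (invalid nets)
        if v not in set(order):
            order.append(v)

    def edge_multiset(inc, v, w):
        return tuple(sorted(tag for tag, x in inc[v] if x == w))

    def consistent(v, w):
        if local_sig(inc_a, v) != local_sig(inc_b, w):
            return False
        for _, x in inc_a[v]:
            if x in mapping:
                if edge_multiset(inc_a, v, x) != edge_multiset(inc_b, w, mapping[x]):
                    return False
        return True

    def backtrack(i: int) -> bool:
        if i == len(order):
            return True
        v = order[i]
        for w in internal_b:
            if w in used:
                continue
            if consistent(v, w):
                mapping[v] = w
                used.add(w)
                if backtrack(i + 1):
                    return True
                del mapping[v]
                used.discard(w)
        return False

    return dict(mapping) if backtrack(0) else None


def is_isomorphic(a: Network, b: Network) -> bool:
    """True iff a label-preserving isomorphism exists (see module docs)."""
    return find_isomorphism(a, b) is not None
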