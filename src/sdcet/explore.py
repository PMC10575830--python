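"""Exhaustive enumeration of small network spaces, BFS oracles, and the
seeded random generator.

Enumeration builds every rooted binary network on a small leaf set by
repeatedly inserting a reticulation into every ordered pair of edges of
every smaller network (subdividing a tail edge with u, a head edge with v,
and adding (u, v)); candidates are validated and deduplicated by canonical
key.  Semi-directed spaces are the projections of the corresponding rooted
spaces, deduplicated again.  This is the package's independent oracle: BFS
on the resulting move graph yields exact CET distances and diameters, and a
connectivity audit checks the proven connectivity verdicts at toy scale.

The random generator draws a rooted binary tree by sequential random leaf
attachment and then inserts k vertex-disjoint cycles.  A cycle insertion
picks a path of free tree vertices (not yet on any cycle), subdivides the
edge above its top with the source and an edge below its bottom with the
sink, and adds the closing reticulation edge; a path of length p consumes p
free vertices and yields a cycle of length p + 2.  Insertions are sampled
only among paths short enough that the remaining free-vertex budget can
still accommodate the remaining cycles, which makes every requested k up to
|X| - 1 feasible without rejection, at the price of making no uniformity
claim over network space.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Optional

import networkx as nx

from . import moves as _moves
from . import partner as _partner
from .netcore import (
    ClassConstraint,
    Network,
    RootedNetwork,
    SemiDirectedNetwork,
    StructuralError,
    classify,
    validate,
)

__all__ = [
    "SpaceCatalog",
    "enumerate_networks",
    "enumerate_union",
    "build_move_graph",
    "bfs_distance",
    "diameter",
    "audit_connectivity",
    "random_tree",
    "random_level1",
    "DEFAULT_ENUM_CAP",
]

DEFAULT_ENUM_CAP = 4


@dataclass
class SpaceCatalog:
    """Complete list of a small network space up to isomorphism."""

    labels: list[str]
    k: int
    constraint: ClassConstraint
    members: list[Network]
    keys: list
    index: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.index = {key: i for i, key in enumerate(self.keys)}

    def __len__(self) -> int:
        return len(self.members)

    def locate(self, net: Network) -> Optional[int]:
        return self.index.get(_partner.canonical_key(net))


# ---------------------------------------------------------------------------
# exhaustive generation
# ---------------------------------------------------------------------------


def _all_rooted_trees(labels: list[str]) -> list[RootedNetwork]:
    first = labels[0]
    base = RootedNetwork({0: (0, 1)}, 0, {1: first})
    nets = [base]
    for lab in labels[1:]:
        nxt: list[RootedNetwork] = []
        seen: set = set()
        for net in nets:
            for e in sorted(net.edges):
                m = net.copy()
                w, _, _ = m.subdivide(e)
                leaf = m.new_vertex()
                m.add_edge(w, leaf)
                m.leaf_labels[leaf] = lab
                key = _partner.canonical_key(m)
                if key not in seen:
                    seen.add(key)
                    nxt.append(m)
        nets = nxt
    return nets


def _add_reticulation_all(nets: list[RootedNetwork],
                          level1_only: bool) -> list[RootedNetwork]:
    """Every result of inserting one reticulation, up to isomorphism.

    Completeness: removing a topmost reticulation edge of any network with
    j+1 reticulations yields a valid network with j, and the insertion that
    reverses it is among those tried here.  For level-1 targets the
    intermediate networks can be kept level-1 (the reduction of a level-1
    network is level-1), which prunes the search.
    """
    out: list[RootedNetwork] = []
    seen: set = set()
    for net in nets:
        edges = sorted(net.edges)
        for e1 in edges:
            for e2 in edges:
                for cand in _insert_retic(net, e1, e2):
                    if not validate(cand).ok:
                        continue
                    if level1_only and not classify(cand).is_level1:
                        continue
                    key = _partner.canonical_key(cand)
                    if key not in seen:
                        seen.add(key)
                        out.append(cand)
    return out


def _insert_retic(net: RootedNetwork, e1: int, e2: int):
    """Candidates from subdividing e1 with the tail u and e2 with the head
    v, then adding (u, v).  e1 == e2 yields the parallel-pair insertion."""
    if e1 == e2:
        m = net.copy()
        u, _, lower = m.subdivide(e1)
        v, _, _ = m.subdivide(lower)
        m.add_edge(u, v)
        yield m
        return
    m = net.copy()
    u, _, _ = m.subdivide(e1)
    v, _, _ = m.subdivide(e2)
    m.add_edge(u, v)
    yield m


def enumerate_networks(labels, k: int, constraint: ClassConstraint,
                       cap: int = DEFAULT_ENUM_CAP) -> SpaceCatalog:
    """Complete catalog of the space up to isomorphism (|X| <= cap)."""
    labels = sorted(set(labels))
    n = len(labels)
    if n > cap:
        raise ValueError(f"|X|={n} exceeds the enumeration cap {cap}")
    if constraint.k is not None and constraint.k != k:
        raise ValueError("constraint k disagrees with the requested k")
    space = constraint.space
    rooted_space = space.replace("sd-", "rooted-") if space.startswith("sd-") \
        else space
    level1_only = rooted_space == "rooted-level1"
    nets = _all_rooted_trees(labels)
    for _ in range(k):
        nets = _add_reticulation_all(nets, level1_only)
    if rooted_space == "rooted-level1":
        nets = [m for m in nets if classify(m).is_level1]
    elif rooted_space == "rooted-almost-level1":
        nets = [m for m in nets if classify(m).is_almost_level1]
    if space.startswith("rooted"):
        members: list[Network] = nets
    else:
        members = []
        seen: set = set()
        for m in nets:
            sd = _partner.to_semidirected(m)
            key = _partner.canonical_key(sd)
            if key not in seen:
                seen.add(key)
                members.append(sd)
    keys = [_partner.canonical_key(m) for m in members]
    return SpaceCatalog(labels=labels, k=k, constraint=constraint,
                        members=members, keys=keys)


# ---------------------------------------------------------------------------
# move graphs and BFS oracles
# ---------------------------------------------------------------------------


def _extended_neighbors(net: SemiDirectedNetwork,
                        constraint: ClassConstraint):
    """CET plus R+/R- neighbours (for the extended-CET move graph)."""
    out = list(_moves.enumerate_cet_neighbors(net, constraint))
    seen = {_partner.canonical_key(m) for m, _ in out}
    for e in sorted(net.edges):
        a, b, kind = net.edges[e]
        if kind == "D":
            try:
                m, rec = _moves.apply_r_minus(net, e, check=True)
            except _moves.InvalidMove:
                continue
            if constraint.check(m):
                key = _partner.canonical_key(m)
                if key not in seen:
                    seen.add(key)
                    out.append((m, rec))
    for e in sorted(net.edges):
        specs = [_moves.RPlusSpec(variant="loop", edge=e)]
        for e2 in sorted(net.edges):
            for side in (0, 1):
                specs.append(_moves.RPlusSpec(variant="subdiv", edge=e,
                                              edge2=("orig", e2),
                                              head_side=side))
        for half in (0, 1):
            for side in (0, 1):
                specs.append(_moves.RPlusSpec(variant="subdiv", edge=e,
                                              edge2=("half", half),
                                              head_side=side))
        for spec in specs:
            try:
                m, rec = _moves.apply_r_plus(net, spec, check=True)
            except (_moves.InvalidMove, StructuralError):
                continue
            if constraint.check(m):
                key = _partner.canonical_key(m)
                if key not in seen:
                    seen.add(key)
                    out.append((m, rec))
    return out


def build_move_graph(catalog: SpaceCatalog, move_set: str = "cet",
                     strict: bool = True) -> nx.Graph:
    """Move graph on the catalog under 'cet', 'cet1' or 'extended' moves.

    With ``strict`` a neighbour satisfying the constraint but absent from
    the catalog is an error (it would mean the enumeration is incomplete);
    non-strict mode simply drops such neighbours, which is needed for
    truncations of infinite spaces (e.g. all networks with k <= kmax)."""
    g = nx.Graph()
    g.add_nodes_from(range(len(catalog)))
    for i, net in enumerate(catalog.members):
        if move_set == "extended":
            nbrs = _extended_neighbors(net, catalog.constraint)
        else:
            nbrs = _moves.enumerate_cet_neighbors(
                net, catalog.constraint, require_cet1=(move_set == "cet1"))
        for m, _ in nbrs:
            j = catalog.locate(m)
            if j is None:
                if strict:
                    raise StructuralError(
                        "neighbour satisfies the constraint but is missing "
                        "from the catalog (enumeration incomplete)")
                continue
            g.add_edge(i, j)
    return g


def enumerate_union(labels, kmax: int, space: str = "sd-all",
                    cap: int = DEFAULT_ENUM_CAP) -> SpaceCatalog:
    """Catalog of all networks of the space with 0 <= k <= kmax, for move
    sets that change the reticulation number."""
    labels = sorted(set(labels))
    members: list[Network] = []
    keys: list = []
    seen: set = set()
    for k in range(kmax + 1):
        cat = enumerate_networks(labels, k, ClassConstraint(space, k),
                                 cap=cap)
        for m, key in zip(cat.members, cat.keys):
            if key not in seen:
                seen.add(key)
                members.append(m)
                keys.append(key)
    return SpaceCatalog(labels=labels, k=-1,
                        constraint=ClassConstraint(space, None),
                        members=members, keys=keys)


def bfs_distance(a: Network, bnet: Network, catalog: SpaceCatalog,
                 move_set: str = "cet",
                 graph: Optional[nx.Graph] = None) -> Optional[int]:
    """Exact geodesic distance in the move graph; None if unreachable."""
    i, j = catalog.locate(a), catalog.locate(bnet)
    if i is None or j is None:
        raise ValueError("network not a member of the catalog's space")
    g = graph if graph is not None else build_move_graph(catalog, move_set)
    try:
        return nx.shortest_path_length(g, i, j)
    except nx.NetworkXNoPath:
        return None


def diameter(catalog: SpaceCatalog, move_set: str = "cet",
             graph: Optional[nx.Graph] = None) -> Optional[int]:
    g = graph if graph is not None else build_move_graph(catalog, move_set)
    if len(g) == 0:
        return None
    if not nx.is_connected(g):
        return None
    return nx.diameter(g) if len(g) > 1 else 0


def audit_connectivity(labels, k: int, move_set: str = "cet",
                       cap: int = DEFAULT_ENUM_CAP) -> dict:
    """Connectivity verdict for the semi-directed level-1 space on the
    labels with exactly k reticulations.

    ``connected``: the level-1 space is connected under the move set;
    ``weakly_connected``: every pair of level-1 networks is joined inside
    the almost-level-1 closure.  Reports the component count and, when
    connected, the diameter.
    """
    labels = sorted(set(labels))
    cat = enumerate_networks(labels, k, ClassConstraint("sd-level1", k),
                             cap=cap)
    g = build_move_graph(cat, move_set)
    connected = len(cat) <= 1 or nx.is_connected(g)
    report = {
        "n_networks": len(cat),
        "connected": bool(connected),
        "component_count": nx.number_connected_components(g) if len(cat)
        else 0,
        "diameter": diameter(cat, move_set, graph=g) if connected and
        len(cat) else None,
    }
    closure = enumerate_networks(labels, k,
                                 ClassConstraint("sd-almost-level1", k),
                                 cap=cap)
    gc = build_move_graph(closure, move_set)
    level1_idx = [closure.locate(m) for m in cat.members]
    if any(i is None for i in level1_idx):
        raise StructuralError("level-1 member missing from its almost-"
                              "level-1 closure")
    comps = list(nx.connected_components(gc)) if len(closure) else []
    weak = True
    if level1_idx:
        weak = any(set(level1_idx) <= comp for comp in comps)
    report["weakly_connected"] = bool(weak)
    report["closure_size"] = len(closure)
    return report


# ---------------------------------------------------------------------------
# random generator
# ---------------------------------------------------------------------------


def random_tree(labels, rng: random.Random) -> RootedNetwork:
    """Random rooted binary tree by sequential random leaf attachment."""
    labels = list(labels)
    net = RootedNetwork({0: (0, 1)}, 0, {1: labels[0]})
    for lab in labels[1:]:
        e = rng.choice(sorted(net.edges))
        w, _, _ = net.subdivide(e)
        leaf = net.new_vertex()
        net.add_edge(w, leaf)
        net.leaf_labels[leaf] = lab
    return net


def random_level1(labels, k: int, seed=None,
                  rng: Optional[random.Random] = None,
                  max_path: int = 3) -> RootedNetwork:
    """Seeded random rooted level-1 network with exactly k reticulations.

    Cycle lengths vary between 3 and max_path + 2; the free-vertex budget
    rule guarantees success for every k <= |X| - 1 (see module docstring).
    Identical seeds yield identical networks.
    """
    labels = sorted(set(labels))
    n = len(labels)
    if not 0 <= k <= n - 1:
        raise ValueError(f"k={k} outside the feasible range 0..{n - 1}")
    if rng is None:
        rng = random.Random(seed)
    net = random_tree(labels, rng)
    for j in range(k):
        on_cycle = set()
        for rec in _cycles_vertices(net):
            on_cycle |= rec
        free = [v for v in sorted(net.vertices)
                if v != net.root and v not in on_cycle
                and net.in_degree(v) == 1 and net.out_degree(v) == 2]
        budget = len(free) - (k - j - 1)
        if budget < 1:  # pragma: no cover - impossible by the budget rule
            raise StructuralError("free-vertex budget exhausted")
        paths = []
        for start in free:
            paths.extend(_free_paths(net, start, set(on_cycle), free,
                                     min(budget, max_path)))
        path = list(rng.choice(sorted(paths)))
        top, bottom = path[0], path[-1]
        e1 = net.in_edges(top)[0]
        e2 = rng.choice(sorted(net.out_edges(bottom)))
        u, _, _ = net.subdivide(e1)
        v, _, _ = net.subdivide(e2)
        net.add_edge(u, v)
    rep = classify(net)
    if not (rep.is_level1 and rep.k == k):  # pragma: no cover - gate
        raise StructuralError("random generator produced an off-class "
                              "network")
    return net


def _cycles_vertices(net: RootedNetwork):
    from .netcore import cycles
    return [set(r.vertices) for r in cycles(net)]


def _free_paths(net: RootedNetwork, start: int, on_cycle: set,
                free: list, max_len: int):
    """Downward paths of free tree vertices starting at ``start``."""
    out = [(start,)]
    frontier = [(start,)]
    while frontier:
        nxt = []
        for path in frontier:
            if len(path) >= max_len:
                continue
            for c in sorted(net.children(path[-1])):
                if c in free:
                    p2 = path + (c,)
                    out.append(p2)
                    nxt.append(p2)
        frontier = nxt
    return out
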