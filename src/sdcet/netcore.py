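"""Core data model for rooted and semi-directed binary phylogenetic networks.

Two network types are provided.  A :class:`RootedNetwork` is a rooted acyclic
directed multigraph whose root has out-degree one, whose leaves are bijectively
labelled, and whose internal vertices are either tree vertices (in-degree 1,
out-degree 2) or reticulations (in-degree 2, out-degree 1).  A
:class:`SemiDirectedNetwork` is the mixed multigraph obtained from a rooted
network by suppressing the root and undirecting all tree edges; reticulation
edges keep their direction, and the network may carry at most one directed
loop or pairs of parallel directed edges.

Both types are multigraphs with stable integer edge identifiers: parallel
pairs and loops are unrepresentable in a plain edge-set encoding, and every
rearrangement move in this package references edges by id, never by endpoint
pair.  A loop contributes 2 to the degree of its vertex, so the loop vertex of
a one-reticulation network on two leaves has total degree 3 like every other
internal vertex.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import networkx as nx

__all__ = [
    "RootedNetwork",
    "SemiDirectedNetwork",
    "ValidationReport",
    "CycleRecord",
    "ClassConstraint",
    "ClassReport",
    "StructuralError",
    "validate",
    "reticulation_count",
    "tree_vertex_count",
    "cycles",
    "cut_edges",
    "classify",
    "find_chain",
    "max_reticulations",
]


class StructuralError(ValueError):
    """Raised for malformed input (dangling edge ids, impossible mutations)."""


# ---------------------------------------------------------------------------
# network containers
# ---------------------------------------------------------------------------


class _BaseNetwork:
    """Shared id bookkeeping for the two network types."""

    def __init__(self) -> None:
        self._next_vertex = 0
        self._next_edge = 0

    def new_vertex(self) -> int:
        v = self._next_vertex
        self._next_vertex += 1
        return v

    def _new_edge_id(self) -> int:
        e = self._next_edge
        self._next_edge += 1
        return e


class RootedNetwork(_BaseNetwork):
    """Rooted binary phylogenetic network on a leaf set X.

    Parameters
    ----------
    edges:
        Mapping edge id -> (parent, child).  Parallel edges are two ids with
        the same endpoint pair; loops are not permitted in rooted networks.
    root:
        The vertex of in-degree 0 and out-degree 1.
    leaf_labels:
        Mapping from out-degree-0 vertices to their labels.
    """

    def __init__(self, edges: dict[int, tuple[int, int]], root: int,
                 leaf_labels: dict[int, str]) -> None:
        super().__init__()
        self.edges: dict[int, tuple[int, int]] = dict(edges)
        self.root = root
        self.leaf_labels: dict[int, str] = dict(leaf_labels)
        ids = [root] + [u for u, _ in self.edges.values()] + \
              [v for _, v in self.edges.values()] + list(self.leaf_labels)
        self._next_vertex = max(ids, default=-1) + 1
        self._next_edge = max(self.edges, default=-1) + 1

    # -- basic queries ----------------------------------------------------

    @property
    def vertices(self) -> set[int]:
        vs = {self.root}
        for u, v in self.edges.values():
            vs.add(u)
            vs.add(v)
        return vs

    def in_edges(self, v: int) -> list[int]:
        return [e for e, (_, h) in self.edges.items() if h == v]

    def out_edges(self, v: int) -> list[int]:
        return [e for e, (t, _) in self.edges.items() if t == v]

    def parents(self, v: int) -> list[int]:
        return [self.edges[e][0] for e in self.in_edges(v)]

    def children(self, v: int) -> list[int]:
        return [self.edges[e][1] for e in self.out_edges(v)]

    def in_degree(self, v: int) -> int:
        return len(self.in_edges(v))

    def out_degree(self, v: int) -> int:
        return len(self.out_edges(v))

    def is_reticulation(self, v: int) -> bool:
        return self.in_degree(v) == 2

    def is_leaf(self, v: int) -> bool:
        return v in self.leaf_labels

    @property
    def labels(self) -> set[str]:
        return set(self.leaf_labels.values())

    def leaf_of(self, label: str) -> int:
        for v, lab in self.leaf_labels.items():
            if lab == label:
                return v
        raise KeyError(label)

    def copy(self) -> "RootedNetwork":
        n = RootedNetwork(self.edges, self.root, self.leaf_labels)
        n._next_vertex = self._next_vertex
        n._next_edge = self._next_edge
        return n

    # -- mutations --------------------------------------------------------

    def add_edge(self, u: int, v: int) -> int:
        e = self._new_edge_id()
        self.edges[e] = (u, v)
        return e

    def remove_edge(self, e: int) -> tuple[int, int]:
        try:
            return self.edges.pop(e)
        except KeyError:
            raise StructuralError(f"no such edge id {e}")

    def subdivide(self, e: int) -> tuple[int, int, int]:
        """Subdivide edge ``e=(u,v)``; return ``(w, top_id, bottom_id)``."""
        u, v = self.remove_edge(e)
        w = self.new_vertex()
        return w, self.add_edge(u, w), self.add_edge(w, v)

    def suppress(self, w: int) -> int:
        """Suppress the in-1/out-1 vertex ``w``; return the merged edge id."""
        ins, outs = self.in_edges(w), self.out_edges(w)
        if len(ins) != 1 or len(outs) != 1:
            raise StructuralError(f"vertex {w} is not suppressible")
        u = self.edges[ins[0]][0]
        v = self.edges[outs[0]][1]
        self.remove_edge(ins[0])
        self.remove_edge(outs[0])
        return self.add_edge(u, v)

    # -- views ------------------------------------------------------------

    def underlying(self) -> "SemiDirectedNetwork":
        """The mixed-graph view with every edge directed (for shared queries)."""
        sd = SemiDirectedNetwork.__new__(SemiDirectedNetwork)
        _BaseNetwork.__init__(sd)
        sd.edges = {e: (u, v, "D") for e, (u, v) in self.edges.items()}
        sd.leaf_labels = dict(self.leaf_labels)
        sd._next_vertex = self._next_vertex
        sd._next_edge = self._next_edge
        return sd

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (f"RootedNetwork(|X|={len(self.leaf_labels)}, "
                f"k={reticulation_count(self)}, |E|={len(self.edges)})")


class SemiDirectedNetwork(_BaseNetwork):
    """Semi-directed binary phylogenetic network: a mixed multigraph.

    ``edges`` maps edge id -> (u, v, kind) with kind ``"U"`` (undirected, the
    endpoint order is arbitrary) or ``"D"`` (directed u -> v).  A loop is a
    directed edge ``(v, v, "D")``.
    """

    def __init__(self, edges: dict[int, tuple[int, int, str]],
                 leaf_labels: dict[int, str]) -> None:
        super().__init__()
        self.edges: dict[int, tuple[int, int, str]] = dict(edges)
        self.leaf_labels: dict[int, str] = dict(leaf_labels)
        ids = [u for u, _, _ in self.edges.values()] + \
              [v for _, v, _ in self.edges.values()] + list(self.leaf_labels)
        self._next_vertex = max(ids, default=-1) + 1
        self._next_edge = max(self.edges, default=-1) + 1

    # -- basic queries ----------------------------------------------------

    @property
    def vertices(self) -> set[int]:
        vs = set()
        for u, v, _ in self.edges.values():
            vs.add(u)
            vs.add(v)
        return vs

    def incident(self, v: int) -> list[int]:
        """Edge ids incident with ``v`` (a loop appears once in the list)."""
        return [e for e, (a, b, _) in self.edges.items() if v in (a, b)]

    def degree(self, v: int) -> int:
        d = 0
        for a, b, _ in self.edges.values():
            if a == v:
                d += 1
            if b == v:
                d += 1
        return d

    def is_loop(self, e: int) -> bool:
        a, b, kind = self.edges[e]
        return a == b and kind == "D"

    def loops(self) -> list[int]:
        return [e for e in self.edges if self.is_loop(e)]

    def directed_in_edges(self, v: int) -> list[int]:
        return [e for e, (a, b, k) in self.edges.items()
                if k == "D" and b == v and a != b]

    def is_reticulation(self, v: int) -> bool:
        if any(self.edges[e][0] == v for e in self.loops()):
            return True
        return len(self.directed_in_edges(v)) == 2

    def reticulations(self) -> list[int]:
        return sorted(v for v in self.vertices if self.is_reticulation(v))

    def is_leaf(self, v: int) -> bool:
        return v in self.leaf_labels

    @property
    def labels(self) -> set[str]:
        return set(self.leaf_labels.values())

    def leaf_of(self, label: str) -> int:
        for v, lab in self.leaf_labels.items():
            if lab == label:
                return v
        raise KeyError(label)

    def other_end(self, e: int, v: int) -> int:
        a, b, _ = self.edges[e]
        if a == v:
            return b
        if b == v:
            return a
        raise StructuralError(f"edge {e} not incident with vertex {v}")

    def copy(self) -> "SemiDirectedNetwork":
        n = SemiDirectedNetwork(self.edges, self.leaf_labels)
        n._next_vertex = self._next_vertex
        n._next_edge = self._next_edge
        return n

    # -- mutations --------------------------------------------------------

    def add_edge(self, u: int, v: int, kind: str) -> int:
        e = self._new_edge_id()
        self.edges[e] = (u, v, kind)
        return e

    def remove_edge(self, e: int) -> tuple[int, int, str]:
        try:
            return self.edges.pop(e)
        except KeyError:
            raise StructuralError(f"no such edge id {e}")

    def subdivide(self, e: int) -> tuple[int, list[int]]:
        """Subdivide edge ``e`` with a new vertex ``w``.

        Mixed-graph subdivision rules: an undirected ``{u,v}`` becomes
        ``{u,w}, {w,v}``; a directed ``(u,v)`` becomes ``{u,w}, (w,v)``; a
        loop ``(v,v)`` becomes two parallel directed edges ``(w,v), (w,v)``.
        Returns ``(w, new_edge_ids)``.
        """
        u, v, kind = self.remove_edge(e)
        w = self.new_vertex()
        if kind == "U":
            return w, [self.add_edge(u, w, "U"), self.add_edge(w, v, "U")]
        if u == v:  # loop
            return w, [self.add_edge(w, v, "D"), self.add_edge(w, v, "D")]
        return w, [self.add_edge(u, w, "U"), self.add_edge(w, v, "D")]

    def suppress(self, w: int) -> int:
        """Suppress the degree-2 vertex ``w``; return the merged edge id.

        Implements the five mixed-graph suppression cases, including the
        collapse of two parallel directed out-edges into a loop.
        """
        inc = self.incident(w)
        if self.degree(w) != 2 or len(inc) != 2:
            raise StructuralError(f"vertex {w} is not suppressible")
        e1, e2 = inc
        a1, b1, k1 = self.remove_edge(e1)
        a2, b2, k2 = self.remove_edge(e2)
        # orient each record relative to w: (other endpoint, role)
        # role: 'U' undirected; 'in' directed into w; 'out' directed out of w
        def rel(a, b, k):
            if k == "U":
                return (b if a == w else a, "U")
            if a == w:
                return (b, "out")
            return (a, "in")

        (x, r1), (y, r2) = rel(a1, b1, k1), rel(a2, b2, k2)
        if r1 == "U" and r2 == "U":
            return self.add_edge(x, y, "U")
        if r1 == "U" and r2 == "out":
            return self.add_edge(x, y, "D")
        if r1 == "out" and r2 == "U":
            return self.add_edge(y, x, "D")
        # a directed in-edge paired with an undirected edge reverts to a tree
        # edge: the suppressed vertex loses its reticulation status
        if r1 == "in" and r2 == "U":
            return self.add_edge(x, y, "U")
        if r1 == "U" and r2 == "in":
            return self.add_edge(x, y, "U")
        if {r1, r2} == {"in", "out"}:
            src = x if r1 == "in" else y
            dst = y if r1 == "in" else x
            return self.add_edge(src, dst, "D")
        if r1 == r2 == "out" and x == y:
            return self.add_edge(x, x, "D")  # parallel out-pair collapses to loop
        if r1 == r2 == "in" and x == y:
            return self.add_edge(x, x, "D")  # 2-cycle collapses to a loop
        raise StructuralError(
            f"degree-2 vertex {w} with edge roles ({r1},{r2}) is not suppressible")

    def to_nx_multigraph(self) -> nx.MultiGraph:
        g = nx.MultiGraph()
        g.add_nodes_from(self.vertices)
        for e, (u, v, _) in self.edges.items():
            g.add_edge(u, v, key=e)
        return g

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (f"SemiDirectedNetwork(|X|={len(self.leaf_labels)}, "
                f"k={reticulation_count(self)}, |E|={len(self.edges)})")


Network = RootedNetwork | SemiDirectedNetwork


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------


@dataclass
class ValidationReport:
    """Every violated structural condition; empty iff the network is valid."""

    violations: list[str] = field(default_factory=list)

    def add(self, msg: str) -> None:
        self.violations.append(msg)

    @property
    def ok(self) -> bool:
        return not self.violations

    def __bool__(self) -> bool:
        return self.ok


def _validate_rooted(n: RootedNetwork, report: ValidationReport) -> None:
    if n.in_degree(n.root) != 0 or n.out_degree(n.root) != 1:
        report.add("root-degree: root must have in-degree 0 and out-degree 1")
    for e, (u, v) in n.edges.items():
        if u == v:
            report.add(f"loop: rooted networks admit no loops (edge {e})")
    for v in n.vertices:
        if v == n.root:
            continue
        din, dout = n.in_degree(v), n.out_degree(v)
        if dout == 0:
            if din != 1:
                report.add(f"leaf-degree: out-degree-0 vertex {v} has in-degree {din}")
            if v not in n.leaf_labels:
                report.add(f"label: out-degree-0 vertex {v} is unlabeled")
        else:
            if v in n.leaf_labels:
                report.add(f"label: labeled vertex {v} has out-degree {dout}")
            if not ((din, dout) == (1, 2) or (din, dout) == (2, 1)):
                report.add(f"degree: internal vertex {v} has (in,out)=({din},{dout})")
    for v in n.leaf_labels:
        if v not in n.vertices:
            report.add(f"label: labeled vertex {v} does not exist")
        elif n.out_degree(v) != 0:
            pass  # already reported above
    if len(set(n.leaf_labels.values())) != len(n.leaf_labels):
        report.add("label: leaf labels are not distinct")
    dg = nx.MultiDiGraph()
    dg.add_nodes_from(n.vertices)
    dg.add_edges_from(n.edges.values())
    if not nx.is_directed_acyclic_graph(dg):
        report.add("acyclic: directed graph contains a directed cycle")
    elif not all(nx.has_path(dg, n.root, v) for v in n.vertices):
        report.add("connectivity: not every vertex is reachable from the root")


def _validate_semidirected(n: SemiDirectedNetwork, report: ValidationReport,
                           check_partner: bool = True) -> None:
    loops = n.loops()
    if len(loops) > 1:
        report.add(f"loop: {len(loops)} loops present, at most one allowed")
    for e, (u, v, kind) in n.edges.items():
        if kind == "U" and u == v:
            report.add(f"loop: undirected loop (edge {e}) is not allowed")
    # every directed non-loop edge points into a reticulation
    for e, (u, v, kind) in n.edges.items():
        if kind == "D" and u != v and not n.is_reticulation(v):
            report.add(f"reticulation-edge: directed edge {e} does not enter a "
                       "reticulation")
    for v in n.vertices:
        d = n.degree(v)
        if d == 1:
            if v not in n.leaf_labels:
                report.add(f"label: degree-1 vertex {v} is unlabeled")
        else:
            if v in n.leaf_labels:
                report.add(f"label: labeled vertex {v} has degree {d}")
            if d != 3:
                report.add(f"degree: internal vertex {v} has degree {d}")
        nin = len(n.directed_in_edges(v))
        has_loop = any(n.edges[e][0] == v for e in loops)
        if nin not in (0, 2) and not (nin == 0 and has_loop):
            report.add(f"reticulation: vertex {v} has {nin} directed in-edges")
        if has_loop and nin > 0:
            report.add(f"reticulation: loop vertex {v} also has directed in-edges")
    if len(set(n.leaf_labels.values())) != len(n.leaf_labels):
        report.add("label: leaf labels are not distinct")
    if n.edges and not nx.is_connected(n.to_nx_multigraph()):
        report.add("connectivity: underlying graph is not connected")
    if report.ok:
        # structural invariant: no cut edge may be a reticulation edge
        for e in cut_edges(n):
            if n.edges[e][2] == "D":
                report.add(f"cut-edge: directed edge {e} is a bridge")
    if report.ok and check_partner:
        from . import partner as _partner
        if not _partner.rooted_partners(n, validate_input=False):
            report.add("partner: no rooted partner exists")


def validate(network: Network, check_partner: bool = True) -> ValidationReport:
    """Structural validation; returns a report listing every violation.

    Invalid structure yields a populated report, never an exception.  For
    semi-directed networks the final check is existence of a rooted partner,
    which is what makes a mixed graph a semi-directed phylogenetic network.
    """
    report = ValidationReport()
    if isinstance(network, RootedNetwork):
        _validate_rooted(network, report)
    else:
        _validate_semidirected(network, report, check_partner=check_partner)
    return report


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------


def reticulation_count(network: Network) -> int:
    """Number of reticulations r(N)."""
    if isinstance(network, RootedNetwork):
        return sum(1 for v in network.vertices if network.in_degree(v) == 2)
    return len(network.reticulations())


def tree_vertex_count(network: RootedNetwork) -> int:
    """Number of tree vertices t; asserts the identity t = k + |X| - 1."""
    t = sum(1 for v in network.vertices
            if network.in_degree(v) == 1 and network.out_degree(v) == 2)
    k = reticulation_count(network)
    expected = k + len(network.leaf_labels) - 1
    if t != expected:
        raise StructuralError(
            f"tree-vertex identity violated: t={t}, k+|X|-1={expected}")
    return t


def max_reticulations(labels: Iterable[str]) -> int:
    """Upper bound |X| - 1 on the reticulation number of a level-1 network."""
    n = len(set(labels))
    if n < 1:
        raise ValueError("label set must be non-empty")
    return n - 1


# ---------------------------------------------------------------------------
# cycles and cut edges
# ---------------------------------------------------------------------------


@dataclass
class CycleRecord:
    """One cycle of the underlying multigraph.

    ``length`` 1 is a loop, 2 a parallel pair.  ``composite`` flags a
    biconnected component that is not a single cycle (the network is then not
    level-1).  For rooted networks ``source`` and ``sink`` are filled in.
    """

    vertices: list[int]
    edge_ids: list[int]
    composite: bool = False
    source: Optional[int] = None
    sink: Optional[int] = None

    @property
    def length(self) -> int:
        return len(self.vertices)

    @property
    def middles(self) -> list[int]:
        return [v for v in self.vertices if v not in (self.source, self.sink)]


def _as_sd(network: Network) -> SemiDirectedNetwork:
    return network.underlying() if isinstance(network, RootedNetwork) else network


def cycles(network: Network) -> list[CycleRecord]:
    """Cycle records via biconnected components of the underlying multigraph.

    Parallel edges and loops are handled by subdividing every edge with a
    marker node before running the (simple-graph) biconnected-component
    machinery.  A component in which every vertex has degree two is a single
    cycle; anything larger is returned flagged composite.
    """
    sd = _as_sd(network)
    records: list[CycleRecord] = []
    for e in sorted(sd.loops()):
        v = sd.edges[e][0]
        records.append(CycleRecord(vertices=[v], edge_ids=[e]))
    h = nx.Graph()
    h.add_nodes_from(sd.vertices)
    for e, (u, v, _) in sd.edges.items():
        if u == v:
            continue
        h.add_edge(u, ("edge", e))
        h.add_edge(("edge", e), v)
    for comp in nx.biconnected_components(h):
        if len(comp) <= 2:
            continue
        real = sorted(v for v in comp if not isinstance(v, tuple))
        eids = sorted(v[1] for v in comp if isinstance(v, tuple))
        if len(eids) <= 1:
            continue  # a single subdivided bridge, not a cycle
        sub = h.subgraph(comp)
        if all(sub.degree(v) == 2 for v in comp):
            ordered = _cycle_order(sd, real, eids)
            rec = CycleRecord(vertices=ordered, edge_ids=eids)
        else:
            rec = CycleRecord(vertices=real, edge_ids=eids, composite=True)
        if isinstance(network, RootedNetwork) and not rec.composite:
            _annotate_rooted_cycle(network, rec)
        records.append(rec)
    records.sort(key=lambda r: min(r.vertices))
    return records


def _cycle_order(sd: SemiDirectedNetwork, verts: list[int],
                 eids: list[int]) -> list[int]:
    """Order the vertices of a single-cycle component along the cycle."""
    if len(verts) == 1:
        return verts
    adj: dict[int, list[tuple[int, int]]] = {v: [] for v in verts}
    for e in eids:
        u, v, _ = sd.edges[e]
        adj[u].append((e, v))
        adj[v].append((e, u))
    start = min(verts)
    order = [start]
    prev_edge = None
    cur = start
    while len(order) < len(verts):
        for e, w in sorted(adj[cur]):
            if e != prev_edge and w not in order:
                order.append(w)
                prev_edge, cur = e, w
                break
        else:  # pragma: no cover - defensive
            break
    return order


def _annotate_rooted_cycle(n: RootedNetwork, rec: CycleRecord) -> None:
    on_cycle = set(rec.vertices)
    eset = set(rec.edge_ids)
    for v in rec.vertices:
        in_on = [e for e in n.in_edges(v) if e in eset]
        if not in_on:
            rec.source = v
        if n.in_degree(v) == 2 and len(in_on) == 2:
            rec.sink = v
    # In a level-1 cycle both are unique; composite components skip this.
    del on_cycle


def cut_edges(network: Network) -> set[int]:
    """Edge ids of the bridges of the underlying multigraph."""
    sd = _as_sd(network)
    h = nx.Graph()
    h.add_nodes_from(sd.vertices)
    for e, (u, v, _) in sd.edges.items():
        if u == v:
            continue
        h.add_edge(u, ("edge", e))
        h.add_edge(("edge", e), v)
    bridges = set()
    for a, b in nx.bridges(h):
        marker = a if isinstance(a, tuple) else b
        bridges.add(marker[1])
    return bridges


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------


@dataclass
class ClassReport:
    is_level1: bool
    is_almost_level1: bool
    k: int
    parallel_pair_count: int
    loop_count: int
    witness: Optional[object] = None  # PartnerWitness for semi-directed inputs


def _classify_rooted(n: RootedNetwork) -> ClassReport:
    recs = cycles(n)
    k = reticulation_count(n)
    two = sum(1 for r in recs if r.length == 2)
    composite = any(r.composite for r in recs)
    level1 = not composite and two == 0
    almost = not composite and two <= 1
    return ClassReport(is_level1=level1, is_almost_level1=almost, k=k,
                       parallel_pair_count=two, loop_count=0)


def classify(network: Network) -> ClassReport:
    """Class membership report.

    Rooted: level-1 iff no parallel pair and all biconnected components are
    single cycles (hence vertex-disjoint); almost level-1 additionally allows
    exactly one 2-cycle.  Semi-directed: decided by scanning rooted partners
    for one of the corresponding class, which is the defining condition; the
    witnessing partner is recorded on the report.
    """
    if isinstance(network, RootedNetwork):
        return _classify_rooted(network)
    from . import partner as _partner
    recs = cycles(network)
    k = reticulation_count(network)
    two = sum(1 for r in recs if r.length == 2)
    loops = sum(1 for r in recs if r.length == 1)
    level1 = False
    almost = False
    witness = None
    almost_witness = None
    for w in _partner.rooted_partners(network, validate_input=False):
        rep = _classify_rooted(w.network)
        if rep.is_level1 and not level1:
            level1 = True
            witness = w
        if rep.is_almost_level1 and not almost:
            almost = True
            almost_witness = w
        if level1 and almost:
            break
    return ClassReport(is_level1=level1, is_almost_level1=almost, k=k,
                       parallel_pair_count=two, loop_count=loops,
                       witness=witness or almost_witness)


@dataclass(frozen=True)
class ClassConstraint:
    """Membership predicate for a network space.

    ``space`` is one of ``rooted-level1``, ``rooted-almost-level1``,
    ``sd-level1``, ``sd-almost-level1``, ``sd-all``, ``rooted-all``; ``k`` is
    a fixed reticulation count or None for unconstrained.
    """

    space: str
    k: Optional[int] = None

    _ROOTED = {"rooted-level1", "rooted-almost-level1", "rooted-all"}

    @property
    def rooted(self) -> bool:
        return self.space in self._ROOTED

    def check(self, network: Network) -> bool:
        if self.k is not None and reticulation_count(network) != self.k:
            return False
        if self.space in ("rooted-all", "sd-all"):
            return validate(network).ok
        rep = classify(network)
        if self.space.endswith("almost-level1"):
            return rep.is_almost_level1
        return rep.is_level1


# ---------------------------------------------------------------------------
# chains
# ---------------------------------------------------------------------------


def find_chain(network: RootedNetwork) -> Optional[list[CycleRecord]]:
    """An ordering (C_1..C_k) of the cycles forming a chain, or None.

    The ordering must satisfy: the path from the root to the source of C_1
    contains only tree vertices, and each sink v_i is an ancestor of all
    later sinks.  k = 0 yields the empty (vacuous) chain.
    """
    recs = [r for r in cycles(network) if not r.composite]
    if any(r.composite for r in cycles(network)):
        return None
    if not recs:
        return []
    dg = nx.DiGraph()
    dg.add_nodes_from(network.vertices)
    dg.add_edges_from(network.edges.values())
    desc = {v: nx.descendants(dg, v) for v in network.vertices}
    # total ancestor order on sinks
    sinks = [r.sink for r in recs]
    if any(s is None for s in sinks):
        return None
    ordered = sorted(recs, key=lambda r: len(desc[r.sink]), reverse=True)
    for i in range(len(ordered) - 1):
        vi = ordered[i].sink
        for j in range(i + 1, len(ordered)):
            if ordered[j].sink not in desc[vi]:
                return None
    # path from root to source of C_1 contains only tree vertices
    u1 = ordered[0].source
    path_ok = True
    cur = u1
    while cur != network.root:
        ps = network.parents(cur)
        if len(ps) != 1:
            path_ok = False
            break
        cur = ps[0]
        if cur != network.root and network.in_degree(cur) != 1:
            path_ok = False
            break
    if not path_ok:
        return None
    return ordered
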