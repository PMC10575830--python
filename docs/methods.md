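# Methods

## Network model

A **rooted binary phylogenetic network** on a leaf set X is a rooted acyclic
directed multigraph without loops in which the root has in-degree 0 and
out-degree 1, the out-degree-0 vertices are bijectively labelled by X and
have in-degree 1, and every other vertex is a tree vertex (in 1, out 2) or a
reticulation (in 2, out 1).  Parallel edges are admitted in general rooted
networks but excluded from rooted level-1 networks.  A **semi-directed
network** is what remains after suppressing the root: tree edges lose their
direction, reticulation edges keep it, and the hole left by the root and its
child is patched in one of three ways keyed on the edge types at the root
child — a parallel reticulation pair becomes a directed loop, one
reticulation edge plus one tree edge becomes a new directed edge, two tree
edges become a new undirected edge.  A rooted network producing a given
semi-directed network is a **rooted partner**; a loop forces a unique
partner, otherwise several root placements usually work.

Both containers are multigraphs with stable integer edge ids.  Parallel
pairs and loops are unrepresentable in an edge-set encoding, and every move
is parameterised by edge ids, so records stay unambiguous and replayable.
A loop contributes 2 to its vertex's degree; with that convention every
internal vertex of a semi-directed network has total degree 3.

**Classes.**  A rooted network is *level-1* when its cycles (of the
underlying graph) are vertex-disjoint and no parallel pair exists, and
*almost level-1* when at most one 2-cycle is allowed.  A semi-directed
network belongs to a class when some rooted partner does; `classify`
decides this by scanning the partner list, which is exhaustive at the
package's scale, rather than through a direct combinatorial
characterisation (none is available for the semi-directed side).  Cycle
detection runs on the biconnected components of the underlying multigraph
(computed after subdividing every edge with a marker node so that parallel
pairs and loops survive the simple-graph machinery); a component that is not
a single cycle is returned flagged *composite*, which is exactly the
level-≥2 case and is not decomposed further.

**Partner enumeration.**  Inverting the root-suppression tries the loop
inversion when a loop is present, and otherwise every undirected edge (tree
rooting) and every directed edge (reticulation-edge rooting) as the restore
site.  The orientation of the remaining undirected edges is recovered by
constraint propagation — every non-root vertex needs in-degree exactly 1
unless its two fixed directed in-edges already saturate it — with an
exhaustive two-way branch as a completeness fallback on the rare inputs
where propagation stalls.  Candidates failing rooted validation are
discarded; survivors are deduplicated up to label-preserving isomorphism.
The unit tests compare this against a no-pruning oracle that tries every
root site and every orientation bit vector.

**Isomorphism.**  All isomorphism here fixes leaf labels pointwise (and
maps root to root for rooted networks).  `find_isomorphism` backtracks over
internal vertices anchored at the leaves; `canonical_key` is an
individualisation-refinement canonical form seeded with leaf labels and
edge kinds.  The two implementations are independent and cross-checked
against each other and against an exhaustive bijection search in the tests.

## The moves

A **CET** deletes a cut edge e = {u, v}, suppresses u, subdivides an edge f
of the component on u's side with u′, and adds {u′, v}; the two other edges
at u are the *donor edges* and f the *recipient*.  On the semi-directed
side the choice of (e, u) must be certified by a rooted partner in which u
is a parent of v, or in which the root child sits on e with three cut edges
below the root; `cet_valid_sd` searches the partner list for either
condition and caches the witness.  Mixed-graph subdivision and suppression
follow fixed rules (subdividing a directed edge yields an undirected upper
half; subdividing a loop yields a parallel directed pair; suppressing a
vertex with two parallel out-edges yields a loop, and a 2-cycle collapsing
during R⁻ likewise becomes a loop).  Results isomorphic to the input are
representable but flagged, because a CET is only defined between
non-isomorphic networks; enumeration drops them.

Every `apply_*` returns a `MoveRecord` carrying the inverse move expressed
against the result's edge ids, so `apply(apply(N).inverse)` is isomorphic to
N — asserted property-style over the random corpus.  R⁻ removes a
reticulation (loop case: delete the loop vertex and suppress the freed
neighbour; otherwise undirect the sibling reticulation edge, delete, and
suppress both endpoints); R⁺ is its inverse and is validated after
application, since adding a second loop or mis-directing an edge can leave
the semi-directed class.  An R⁻ whose suppression step would create an
undirected loop (the freed vertex sits on an undirected 2-cycle) is
rejected with an error rather than silently producing an invalid graph;
for every reticulation some incident edge admits a valid R⁻, which is what
the connectors rely on.

## Standard form and the connectors

The **standard form** on an ordered leaf set x₁…xₙ with k reticulations is
the unique level-1 network consisting of a chain of k 3-cycles below the
root — leaf xᵢ on the middle vertex of the i-th cycle, each sink feeding the
next source — followed by a caterpillar on x_{k+1}…xₙ below the last sink.
*Standard shape* is the same up to a leaf permutation.  The default leaf
order is the natural sort of the labels (digit runs compared numerically).

`to_standard_shape` works in three phases.  (1) *Cycle shrinking*: for each
cycle longer than three, pendant subtrees of cycle middles are relocated
onto the root edge, deepest cycle first; each relocated subtree contains a
leaf that is never relocated again, bounding the phase by |X| moves.
(2) *Chain assembly*: each cycle is stacked directly below the root by a
gadget of at most three CETs — optionally move a free tree vertex's subtree
onto the edge entering the cycle's source, then hang the source under the
root, then move the old root subtree below the cycle's sink.  Cycles are
processed shallowest-source first, preferring cycles whose source parent is
not a reticulation; when the network is saturated (k = |X| − 1, no free
tree vertex) the first gadget deletes a cycle middle's out-edge and thereby
creates the single admissible parallel pair, which also frees a tree vertex
for all later gadgets.  A cycle whose source parent already is the root
child skips the redundant second CET (it would reproduce the network).
(3) *Caterpillar assembly*: the subtree below the bottom sink is combed
into a caterpillar (one CET per leaf), every remaining free leaf is moved
below that sink, and for k = |X| − 1 the one free leaf is inserted into the
transient 2-cycle, restoring all-3-cycles.  The total is bounded by
2|X| + 2k, asserted on every run, with intermediates level-1 for
k ≤ |X| − 2 and almost level-1 for k = |X| − 1.

`shape_to_form` then moves each leaf to its correct position in index
order, at most three CETs per leaf (bounded by 3|X|): a caterpillar leaf
out of order moves directly above the topmost already-placed caterpillar
leaf (read off the current caterpillar, since the bottom cherry may sit in
either order); a leaf that belongs on cycle Cᵢ swaps with the middle leaf of
Cᵢ through a transient 4-cycle; in the saturated case the swap passes
through a transient parallel pair instead.  Degenerate sub-cases (the
caterpillar reduced to a single leaf, the swap partner adjacent to the
recipient) are handled by remapping donor-edge recipients to the merged
edge that the suppression produces.

`connect_rooted` concatenates a forward transformation of A with the
reversed transformation of B (≤ 10|X| + 4k moves).  Reversal replays stored
inverse records; because records are id-based, each inverse is first
re-expressed against the current network through a leaf-anchored
isomorphism and the induced edge-id correspondence (parallel edges paired
in sorted order, which is harmless up to isomorphism).

`connect_sd` projects the rooted connector: each rooted CET maps to at most
one semi-directed CET by a three-way case analysis on whether the cut edge
or the recipient is incident with the root child (in which case the patch
edge left by root suppression stands in for it); steps whose projections
are isomorphic are dropped.  The projected move is applied with full
validity checking and the result is asserted isomorphic to the projection
of the next rooted network.  The level-1 partners used are the witnesses
returned by `classify`; any witness works, the choice only affects the
sequence's identity.

`connect_extended` strips A's reticulations by R⁻ (choosing, per step, a
reticulation that is topmost in a rooted partner, so the edge tail is never
a reticulation), walks between the two resulting unrooted trees by CETs
through the caterpillar on the natural leaf order, and rebuilds B's
reticulations by replaying its strip records in reverse.  With the level-1
flag every intermediate is level-1; without it merely semi-directed.

`decompose_to_cet1` walks the pruned component along a shortest undirected
path (BFS, avoiding the detached component; loops skipped) from the
suppressed endpoint to the recipient edge; each step is verified to be a
CET₁ and to keep the class certificate, and the endpoint is asserted
isomorphic to the one-step result.  The two special move types — relocating
a parallel pair, exchanging a loop for parallel pairs — are recognised by
donor/recipient cycle-length predicates and rejected, as they cannot be
localised without leaving the class.

## Enumeration oracle and the random generator

`enumerate_networks` builds every rooted binary network on a small leaf set
(default cap |X| ≤ 4) by inserting reticulations one at a time into every
ordered edge pair of every smaller network, with the same-edge case
producing parallel pairs; candidates are validated and deduplicated by
canonical key.  Completeness follows because deleting a topmost
reticulation edge of any network yields a valid smaller one, and that
deletion is reversed by one of the insertions tried.  For level-1 targets
intermediate networks may be kept level-1 (the reduction of a level-1
network is level-1), which prunes the search; almost-level-1 and
unrestricted spaces are generated without pruning and filtered at the end.
Semi-directed spaces are the deduplicated projections of the corresponding
rooted spaces, which is their definition.  BFS on the move graph gives
exact distances and diameters; `audit_connectivity` reports the
connected/weakly-connected verdicts, with weak connectivity evaluated by
embedding the level-1 space into its almost-level-1 closure.  The
extended-CET graph on a k-truncated union catalog is built in a non-strict
mode that drops neighbours outside the truncation; its graph metric is what
the metric-axiom checks exercise.

`random_level1` draws a rooted binary tree by sequential random leaf
attachment, then inserts k vertex-disjoint cycles.  One insertion picks a
downward path of tree vertices not yet on any cycle, subdivides the edge
above the path with the source and an edge below it with the sink, and adds
the closing reticulation edge; a path of p vertices consumes p free
vertices and yields a cycle of length p + 2 (lengths 3–5 by default).
Sampling only among paths short enough that the remaining free-vertex
budget still accommodates the remaining cycles makes every k ≤ |X| − 1
succeed without rejection — including the saturated all-3-cycle case —
at the price that no uniformity over network space is claimed.  Identical
seeds give identical networks and byte-identical SDN serialisations.

## Problem sizes and numerical choices

The test suite and the acceptance script run the bound suite on 200 seeded
random networks with |X| = 8 and k cycling through 0…7, the identity corpus
on 1000 networks with |X| ≤ 8, and the exhaustive oracles on |X| ≤ 3 (all
feasible k) plus |X| = 4 at k = 0; these sizes keep the full enumeration
honest (the |X| = 3, k = 2 almost-level-1 closure already has 54 networks)
while the whole suite completes in about two minutes on one CPU.  All
deterministic tie-breaks are lexicographic on (label, edge id): cycle
middles to relocate are chosen by the smallest leaf below them, swap
partners by smallest index, recipient edges among parallel pairs by
smallest id.  Empty sequences are returned for isomorphic inputs
everywhere, since the moves are defined only between non-isomorphic
networks.

## Limitations

Connecting sequences realise the proven bounds, not geodesics; exact CET
distances are only available through the BFS oracle at toy scale, and the
complexity of computing the distance in general is open.  Level-k classes
for k ≥ 2 are only flagged (composite biconnected components), never
decomposed.  Networks are binary with unlabelled internal vertices and
carry no branch lengths or inheritance probabilities, so nothing here
touches statistical inference from data; the package addresses the
combinatorial search space, not the likelihood surface on it.  Partner
scanning and canonical labelling are exponential in the worst case and are
intended for the tens-of-vertices networks this calculus targets.
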