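# sdcet — cut edge transfer rearrangements for semi-directed level-1 networks

Phylogenetic network inference tools such as SNaQ/PhyloNetworks, NANUQ and
PhyNEST search a space of **semi-directed level-1 networks**: mixed graphs
obtained from a rooted binary network by suppressing the root and
undirecting every tree edge, keeping only the reticulation edges directed.
Whether a local-rearrangement search can in principle reach every network in
that space is a connectivity question about the space itself.

`sdcet` implements the rearrangement calculus that settles it:

* **CET (cut edge transfer)** — delete a cut edge e = {u, v}, suppress the
  freed endpoint u, subdivide an edge of the component on u's side with a
  new vertex u′, and add {u′, v}.  On trees (k = 0) this is exactly unrooted
  SPR.  A rooted variant is provided as well.
* **CET₁** — a CET whose recipient edge is incident with one of the two
  donor edges at u; on trees this is exactly NNI, and it matches the local
  moves used by network search software.
* **R⁺ / R⁻** — add or remove one reticulation; an *extended CET* is exactly
  one of CET, R⁺, R⁻.

The central structural results the package makes executable, for a leaf set
X and reticulation number k:

* every rooted level-1 network reaches the unique **standard form** (a chain
  of k 3-cycles followed by a caterpillar) via ≤ 2|X| + 2k CETs to standard
  shape plus ≤ 3|X| CETs of leaf-position swaps, so any two rooted level-1
  networks with equal (X, k) are ≤ 10|X| + 4k CETs apart;
* the space of semi-directed level-1 networks with fixed (X, k) is
  **connected under CET** when k ≤ |X| − 2 and **weakly connected** (through
  almost-level-1 intermediates carrying one extra 2-cycle or loop) when
  k = |X| − 1, with diameter O(|X| + k); the same verdicts hold under CET₁;
* with R⁺/R⁻ added, the spaces of all semi-directed (level-1) networks on X
  are connected, and the extended-CET distance is a metric;
* any single CET that does not relocate a parallel pair and does not
  exchange a loop for parallel pairs decomposes into a CET₁ walk.

Everything is constructive: each transformation returns a `MoveSequence`
whose records replay deterministically, carry their inverses, and store a
per-step class certificate.  An exhaustive enumerator with BFS distances
serves as the independent oracle at small |X|.

## Worked example

```python
from sdcet.netcore import ClassConstraint
from sdcet import explore, partner
from sdcet.standard import connect_sd, standard_form

pair = partner.to_semidirected(standard_form(["x1", "x2"], 1))
swap = pair.copy()
swap.leaf_labels = {v: ("x2" if lab == "x1" else "x1")
                    for v, lab in swap.leaf_labels.items()}

strict = explore.enumerate_networks(["x1", "x2"], 1,
                                    ClassConstraint("sd-level1", 1))
closure = explore.enumerate_networks(["x1", "x2"], 1,
                                     ClassConstraint("sd-almost-level1", 1))
print(explore.bfs_distance(pair, swap, strict))    # None
print(explore.bfs_distance(pair, swap, closure))   # 2

seq = connect_sd(pair, swap)
print(len(seq))                                    # 2
print([(c.is_level1, c.is_almost_level1) for c in seq.certificates])
# [(False, True), (True, True)]
```

The two-leaf, one-reticulation space contains exactly two level-1 networks
(a parallel-pair network and its label swap).  `None` says they cannot reach
each other while staying strictly level-1; `2` says two CETs suffice once
one almost-level-1 intermediate is allowed, and the certificate list shows
that intermediate is exactly the first of the two steps.  This is the
canonical instance of weak connectivity at k = |X| − 1.

The `examples/` directory holds one short script per capability
(validation/classification, partner enumeration, the moves, the
standard-form pipeline, the connectivity oracle, the CET₁ decomposition);
each prints the numbers it computes with a line on what they mean.

## Command line

A thin CLI mirrors the library:

```bash
sdcet random --n 8 --k 3 --seed 42 --semi-directed --out net.sdn
sdcet classify --in net.sdn
sdcet neighbors --in net.sdn --space sd-level1
sdcet connect --a a.sdn --b b.sdn --space sd-level1 --emit-sequence seq.jsonl
sdcet replay --in seq.jsonl
sdcet distance --a a.sdn --b b.sdn --space sd-almost-level1
```

Semi-directed networks travel in the plain-text **SDN v1** format (`L`
leaf lines, `U`/`D` edge lines, a loop as `D v v`, a duplicated `D` line as
a parallel pair); rooted networks in an extended-Newick dialect with `#Hi`
hybrid tags where a parallel pair is a hybrid node repeated under one
parent.  Both formats are documented in `sdcet/io.py`.

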