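"""Build the two classic two-leaf networks and classify them.

One network carries a directed loop (its unique rooted partner has a
parallel pair at the root child), the other a parallel directed pair (its
partner's root child is the source of a 3-cycle).  The first is almost
level-1 but not level-1; the second is level-1 despite the pair.
"""

from sdcet.netcore import RootedNetwork, classify, reticulation_count, \
    tree_vertex_count, validate
from sdcet.partner import to_semidirected

loop_rooted = RootedNetwork(
    edges={0: (0, 1), 1: (1, 2), 2: (1, 2), 3: (2, 3), 4: (3, 4),
           5: (3, 5)},
    root=0, leaf_labels={4: "x1", 5: "x2"})
pair_rooted = RootedNetwork(
    edges={0: (0, 1), 1: (1, 2), 2: (1, 3), 3: (2, 3), 4: (2, 4),
           5: (3, 5)},
    root=0, leaf_labels={4: "x1", 5: "x2"})

for name, nr in [("loop network", loop_rooted), ("pair network",
                                                 pair_rooted)]:
    sd = to_semidirected(nr)
    rep = classify(sd)
    print(f"{name}: valid={validate(sd).ok} k={reticulation_count(sd)} "
          f"level1={rep.is_level1} almost_level1={rep.is_almost_level1} "
          f"loops={rep.loop_count} parallel_pairs={rep.parallel_pair_count}")
    print(f"  rooted tree vertices t = {tree_vertex_count(nr)} "
          f"(= k + |X| - 1)")

# the loop network is the canonical example of a semi-directed network
# that is almost level-1 without being level-1; the pair network shows
# that one parallel pair is compatible with level-1
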