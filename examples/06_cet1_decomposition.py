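"""Decompose a long-range CET into local CET_1 steps.

A CET can reattach the pruned component anywhere; a CET_1 only across an
edge incident with a donor edge (the NNI-like move used by network search
software).  Any CET that does not relocate a parallel pair and does not
exchange a loop for parallel pairs factors into CET_1 steps walked along a
path, staying level-1 throughout.
"""

from sdcet.netcore import ClassConstraint, reticulation_count
from sdcet import explore, moves, partner
from sdcet.standard import decompose_to_cet1

ns = partner.to_semidirected(
    explore.random_level1([f"x{i}" for i in range(1, 7)], 2, seed=15))
k = reticulation_count(ns)
con = ClassConstraint("sd-level1", k)

for target, rec in moves.enumerate_cet_neighbors(ns, con):
    if moves.is_cet1(rec, ns):
        continue  # pick a genuinely non-local move
    seq = decompose_to_cet1(ns, rec)
    print(f"one CET (cut edge {rec.cut_edge} -> recipient {rec.recipient}) "
          f"decomposes into {len(seq)} CET_1 steps")
    print("end result isomorphic to the one-step result:",
          partner.is_isomorphic(seq.final, target))
    print("all intermediates level-1 with the same k:",
          all(c.is_level1 and c.k == k for c in seq.certificates))
    break
# the walk length equals the number of edges stepped along the connecting
# path, so local moves suffice for any such rearrangement
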