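"""The rearrangement moves: CET, its CET_1 restriction, R- and R+.

On a tree (k = 0) a semi-directed CET is exactly an unrooted SPR move and a
CET_1 exactly an NNI move; the neighbourhood sizes below are the classic
2(n-3)(2n-7) and 2(n-3) counts.  R- removes one reticulation, R+ its
inverse puts it back.
"""

from sdcet.netcore import ClassConstraint, reticulation_count
from sdcet import explore, moves, partner
from sdcet.standard import standard_form

n = 6
tree = partner.to_semidirected(
    standard_form([f"x{i}" for i in range(1, n + 1)], 0))
con = ClassConstraint("sd-level1", 0)
spr = moves.enumerate_cet_neighbors(tree, con)
nni = moves.enumerate_cet_neighbors(tree, con, require_cet1=True)
print(f"6-leaf caterpillar: {len(spr)} CET (=SPR) neighbours, "
      f"{len(nni)} CET_1 (=NNI) neighbours")
print(f"  expected: 2(n-3)(2n-7) = {2*(n-3)*(2*n-7)}, "
      f"2(n-3) = {2*(n-3)}")

ns = partner.to_semidirected(
    explore.random_level1([f"x{i}" for i in range(1, 6)], 2, seed=7))
print(f"\nrandom 5-leaf network: k = {reticulation_count(ns)}")
for e in sorted(ns.edges):
    if ns.edges[e][2] != "D":
        continue
    try:
        smaller, rec = moves.apply_r_minus(ns, e)
    except moves.InvalidMove:
        continue
    print(f"R- on edge {e}: k -> {reticulation_count(smaller)}")
    back, _ = moves.apply_move(smaller, rec.inverse)
    print("R+ (the stored inverse) restores the network:",
          partner.is_isomorphic(back, ns))
    break
# every move record carries a replayable inverse, so a search can always
# back out of a proposal
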