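"""Rooted partners of a semi-directed network, and leaf-fixing isomorphism.

A semi-directed network generally has several rooted partners (one per
admissible root location); a loop forces a unique one.  Isomorphism here
always fixes leaf labels, so swapping two labels usually changes the
network.
"""

from sdcet import explore
from sdcet.io import enewick_dumps
from sdcet.partner import (canonical_key, is_isomorphic, rooted_partners,
                           to_semidirected)

nr = explore.random_level1([f"x{i}" for i in range(1, 6)], 2, seed=42)
sd = to_semidirected(nr)
wits = rooted_partners(sd)
print(f"random 5-leaf network with k=2: {len(wits)} rooted partners")
for w in wits[:4]:
    print(f"  case {w.case}: {enewick_dumps(w.network)}")
print("every partner projects back to the same semi-directed network:",
      all(is_isomorphic(to_semidirected(w.network), sd) for w in wits))

swapped = sd.copy()
swapped.leaf_labels = {v: ("x2" if lab == "x1" else
                           "x1" if lab == "x2" else lab)
                       for v, lab in sd.leaf_labels.items()}
print("isomorphic to its x1/x2 label swap:", is_isomorphic(sd, swapped))
print("canonical keys equal:", canonical_key(sd) == canonical_key(swapped))
# partner count > 1 shows root placement is not identifiable from the
# semi-directed network alone; the label swap shows isomorphism is anchored
# at the leaves
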