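"""Drive a random level-1 network into standard form, within the bounds.

Any rooted level-1 network reaches standard shape in at most 2|X| + 2k
CETs (cycle shrinking, chain assembly at <= 3 CETs per cycle, caterpillar
assembly) and standard form in at most 3|X| more; two networks are
connected through the standard form in at most 10|X| + 4k CETs.
"""

from sdcet.netcore import reticulation_count
from sdcet import explore, partner
from sdcet.standard import (connect_rooted, is_standard_form,
                            is_standard_shape, shape_to_form,
                            to_standard_shape)

n, k = 8, 5
labels = [f"x{i}" for i in range(1, n + 1)]
nr = explore.random_level1(labels, k, seed=2024)
seq1 = to_standard_shape(nr)
print(f"to_standard_shape: {len(seq1)} CETs (bound {2*n + 2*k}); "
      f"standard shape reached: {is_standard_shape(seq1.final)}")
print(f"  chain gadget cost per cycle: "
      f"{seq1.meta['chain_gadget_moves']} (each <= 3)")
seq2 = shape_to_form(seq1.final)
print(f"shape_to_form: {len(seq2)} CETs (bound {3*n}); "
      f"standard form reached: {is_standard_form(seq2.final)}")
print("every intermediate stayed level-1:",
      all(c.is_level1 for c in seq1.certificates + seq2.certificates))

other = explore.random_level1(labels, k, seed=4048)
seq = connect_rooted(nr, other)
print(f"\nconnect_rooted between two random networks: {len(seq)} CETs "
      f"(bound {10*n + 4*k}); target reached: "
      f"{partner.is_isomorphic(seq.final, other)}")
# the bound certifies the space of rooted level-1 networks with fixed
# (|X|, k) has diameter O(|X| + k)
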