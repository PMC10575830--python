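"""Exhaustive enumeration and exact CET distances at toy scale.

The two-leaf space with one reticulation has exactly two level-1 networks
(the pair network and its label swap).  They are NOT connected inside the
strict level-1 space, but are two CETs apart once the almost-level-1
closure (one extra loop network) is allowed - the canonical example of
weak connectivity.
"""

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
print(f"|X|=2, k=1: {len(strict)} level-1 networks, "
      f"{len(closure)} almost-level-1 networks")
print("distance in the strict space:",
      explore.bfs_distance(pair, swap, strict))
print("distance in the almost-level-1 closure:",
      explore.bfs_distance(pair, swap, closure))

seq = connect_sd(pair, swap)
print(f"constructive sequence: {len(seq)} CETs; intermediate classes:",
      [(c.is_level1, c.is_almost_level1) for c in seq.certificates])

for n, k in [(3, 1), (3, 2)]:
    rep = explore.audit_connectivity([f"x{i}" for i in range(1, n + 1)], k)
    print(f"|X|={n}, k={k}: connected={rep['connected']} "
          f"weakly_connected={rep['weakly_connected']} "
          f"({rep['n_networks']} networks, diameter {rep['diameter']})")
# k <= |X|-2 gives a connected space; k = |X|-1 only a weakly connected one
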