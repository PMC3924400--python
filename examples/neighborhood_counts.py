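"""Common d-neighborhoods and the closed-form Hamming-ball size.

The d-neighborhood of one l-mer has exactly sum_i C(l,i)(sigma-1)^i
members; the common neighborhood of several l-mers is the intersection
of their balls and shrinks fast as members are added.
"""

from pms8 import generate_common_neighborhood, neighborhood_size

single = generate_common_neighborhood(["AAAA"], [1])
print(f"|1-neighborhood of AAAA| = {len(single)} "
      f"(closed form: {neighborhood_size(4, 4, 1)})")

pair = generate_common_neighborhood(["AAAA", "TTTT"], [2, 2])
print(f"common 2-neighborhood of AAAA and TTTT ({len(pair)} members): {pair}")
# Only strings with two A's and two T's can be within 2 of both ends.

triple = generate_common_neighborhood(["ACGTAC", "ACGTTT", "TCGTAC"], [2, 3, 2])
print(f"3-way common neighborhood: {len(triple)} members")
# Each added member multiplies the constraints; the enumeration prunes
# the sigma^l tree with consensus-distance bounds instead of scanning it.
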