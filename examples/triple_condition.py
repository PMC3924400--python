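"""The necessary-and-sufficient condition for three l-mers.

Three l-mers have a common d-neighbor iff every pair is within the
summed budgets AND the consensus total distance is within the total
budget. The proof is constructive — a witness is built whenever the
condition holds.
"""

from pms8 import construct_common_neighbor, triple_condition
from pms8.distance import consensus_total_distance, hamming_distance

# pairwise bounds hold (each pair distance 2 <= 1+1) but the consensus
# total distance C(T) = 4 exceeds d1+d2+d3 = 3: no common neighbor
T = ["AA", "CC", "GG"]
print(f"C({T}) = {consensus_total_distance(T)}")
print("common neighbor within (1,1,1)?", triple_condition(*T, [1, 1, 1]))

# both conditions hold -> a witness exists and is constructed
T = ["AAAA", "AACC", "CCAA"]
M = construct_common_neighbor(*T, [2, 2, 2])
print(f"witness for {T} within (2,2,2): {M}")
for t in T:
    print(f"  H({M},{t}) = {hamming_distance(M, t)}")
# The witness meets every budget; the search uses exactly this test to
# discard candidate windows that cannot extend to a motif.
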