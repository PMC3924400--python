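"""Which (l,d) combinations are 'challenging'?

For fixed l, increasing d eventually makes random chance alone produce
motifs. The challenging d is the smallest one where the expected count
of such spurious motifs reaches 1 at the standard 20x600 DNA benchmark.
"""

from pms8 import expected_spurious_motifs, smallest_challenging_d
from pms8.stats import expectation_model

for l in (11, 13, 15, 17, 19):
    d = smallest_challenging_d(l)
    E = expected_spurious_motifs(20, 600, l, d, 4)
    print(f"l={l:2d}: challenging d = {d:2d}   E[spurious] = {E:8.3f}")

model = expectation_model(20, 600, 13, 4, 4)
print(f"\nchain for (13,4): N={model.N}  p={model.p:.3e}  "
      f"q={model.q:.4f}  E={model.E:.2f}")
# N is the Hamming-ball size, p the chance a random window is a
# neighbor, q the chance a whole sequence contains one, E = sigma^l q^n.
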