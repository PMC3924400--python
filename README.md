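# pms8 — exact planted (l,d)-motif search

Motif search looks for short, approximately conserved sites — e.g.
transcription-factor binding sites — shared by a set of DNA or protein
sequences. In the planted (l,d)-motif formulation we are given `n`
sequences and two integers `l` and `d`, and must report **every** l-mer
`M` that occurs in **each** sequence with at most `d` mismatches:

```
M is a motif  ⇔  ∀i ∃j : H(M, S_i[j .. j+l)) ≤ d
```

where `H` is the Hamming distance. The problem is NP-complete, and the
interesting ("challenging") parameter combinations — (13,4), (15,5),
(17,6), … at the standard benchmark of 20 DNA sequences of length
600 — defeat naive enumeration.

This package implements an exact solver built around three ideas:

1. **Consensus total distance.** For a tuple `T` of l-mers,
   `C(T) = Σ_columns (|T| − max symbol frequency)` lower-bounds the
   total distance from *any* string to all of `T`, so
   `C(T) > Σ d_i` proves no common d-neighbor exists (a sound prune
   for tuples of any size).
2. **A necessary-and-sufficient triple condition.** Three l-mers have
   a common neighbor within budgets (d₁,d₂,d₃) **iff** every pair
   satisfies `H(T_i,T_j) ≤ d_i+d_j` and `C(T) ≤ d₁+d₂+d₃`. The proof
   is constructive: `construct_common_neighbor` builds a witness
   whenever the condition holds.
3. **A hybrid sample-driven / pattern-driven search.** Windows are
   pushed onto a stack (one per sequence) while the candidate matrix
   is filtered in place with the conditions above; once the stack
   reaches a heuristic depth `t`, the common d-neighborhood of the
   stack is enumerated by a pruned depth-first traversal of Σ^l and
   survivors are verified against the remaining sequences.

Speed knobs — row sorting, packed 16-bit distance chunks, a
precomputed pair-compatibility table, the n′-subset trick and a
process-pool work queue — never change the result; the output always
equals the brute-force motif set.

## Worked example

```python
from pms8 import generate_planted_instance, pms8_search, smallest_challenging_d

# the classic benchmark: 20 DNA strings of length 600, motif length 13
print(smallest_challenging_d(13))        # -> 4   (smallest d with E[spurious] >= 1)

inst, plant = generate_planted_instance(n=20, m=200, l=13, d=4, seed=1)
result = pms8_search(inst, l=13, d=4)
print(plant.motif)                       # -> AGGTTATCGCGTG   (the planted motif)
print(result.motifs)                     # -> ['AGGTTATCGCGTG']
print(plant.motif in result.motifs)      # -> True
print(result.stats)                      # -> {'tuples_explored': 37952,
                                         #     'neighborhoods_generated': 113,
                                         #     'candidates_verified': 9}
```

The search recovered exactly one motif — the planted one — after
exploring ~38k stack tuples and generating 113 common neighborhoods.
At `m=200` the expected number of *spurious* (chance) motifs is far
below 1, so a single reported motif is the expected outcome.

The same is available from the shell:

```
pms8 generate --n 20 --m 200 --l 13 --d 4 --seed 1 -o inst.fa --motif-out plant.tsv
pms8 search --input inst.fa --l 13 --d 4
pms8 challenging --l 13        # prints 4
pms8 expect --l 13 --d 4       # prints 5.2325208916  (E at n=20, m=600)
```

See `examples/` for narrative scripts covering the generator, the
pruning conditions, neighborhood enumeration, the statistics and the
parallel driver.

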