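# Methods

## Problem and model

Given `n` sequences over an alphabet Σ and integers `l`, `d`, the
planted (l,d)-motif problem asks for every l-mer `M` such that each
sequence contains a window within Hamming distance `d` of `M`. The
solver is exact: its output is, by construction and by test, the same
set a brute-force scan produces.

The synthetic generator reproduces the field's standard evaluation
model: `n` i.i.d.-uniform strings of length `m`, one uniformly random
l-mer motif, and one mutated copy of it written into each string at a
uniformly random offset. Benchmark defaults are the canonical shape
n=20, m=600, DNA. The generator's default mutation mode substitutes
**exactly** `d` distinct positions with a uniformly chosen different
symbol. The looser reading of the model — each copy differs in *at
most* `d` positions — is available as `mutation_mode="at_most"`; the
exact-d default is the standard convention and the harder instance
family, and a motif valid under exact-d mutation is also valid under
at-most-d. Coordinates are 0-based, windows half-open `[j, j+l)`.

What the generator does **not** emulate: real regulatory sequences are
not i.i.d. (composition bias, repeats), motif instances are not
equally likely at every offset, and insertions/deletions never occur.
Passing tests therefore demonstrate correctness of the combinatorial
search, not biological sensitivity on genomic data; on real data the
method enumerates exactly the l-mers satisfying the same Hamming
criterion, no more and no less.

## Pruning mathematics

For a tuple `T` of l-mers, the consensus total distance
`C(T) = Σ_cols (|T| − max symbol frequency)` is a columnwise lower
bound on `Σ_u H(M,u)` over any `M`, attained by a columnwise majority
string. Consequences used by the solver:

* **pair condition** (exact): a common neighbor within `(d_a, d_b)`
  exists iff `H(a,b) ≤ d_a + d_b`;
* **triple condition** (exact): for three l-mers it exists iff all
  three pairwise bounds hold and `C(T) ≤ d_1+d_2+d_3`. The proof is a
  two-case construction over the column types N0–N4 (all agree /
  exactly member i deviates / all distinct), and
  `construct_common_neighbor` implements it literally. Where the proof
  allows an arbitrary choice of columns we fix a deterministic one:
  Case 1 uses the *leftmost* `d_i` columns of type N_i; Case 2 assigns
  leftmost unused N4 columns for members 1, 2, 3 in that order, with
  leftover N4 columns taking member 1's symbol. Any choice is valid;
  fixing one makes outputs reproducible.
* **tuple necessary condition** (any size): `C(T) > Σ d_i` proves
  non-existence; the converse is not conclusive for |T| ≥ 4.

Exactness of the triple condition is pinned by tests against
exhaustive common-neighbor existence: the complete grid of all 64³
DNA 3-mer triples under all 4³ budget vectors, plus ≥10⁵ random
triples for l = 4..8, with witness verification.

## Neighborhood enumeration

The common d-neighborhood of a tuple is enumerated by depth-first
traversal of the Σ-ary prefix tree, one column per level, children in
alphabet-code order (hence lexicographic, duplicate-free emission). A
node at depth k is cut when (a) some partial distance exceeds its
budget, (b) the tuple necessary condition fails on the remaining
columns (`Σh_i + C(suffixes) > Σd_i`), or (c) some pair violates its
pairwise bound on the remaining columns. Rules (b) and (c) instantiate
the pruning conditions above on the uncommitted columns and are
therefore sound; tests verify the enumeration is identical with
pruning disabled. Suffix statistics are precomputed once per tuple in
O(l·|T|²), making each node check O(|T|²).

## The search

The candidate matrix `R` holds, per sequence, the indices of its
windows, all rows in fixed buffers. A recursion over rows picks a
window `x` from the next unconsumed row, pushes it on the stack and
filters every remaining row: a candidate `u` survives only if

* `H(u, x) ≤ 2d` (pair condition with budgets (d,d)),
* the triple condition holds for `(s, x, u)` for **every** stack item
  `s` below `x`, and
* `C(stack ∪ {x, u}) ≤ (|stack|+2)·d` (tuple necessary condition).

The literal formulation only requires the pair test against the new
top and the triple test with the first two stack items; the stronger
variant above is still sound (all three are necessary conditions) and
filters harder. A `minimal_filter` flag restores the literal variant;
tests confirm both produce identical motif sets.

Filtering is in place: survivors are moved to the row prefix and the
old sizes pushed on a snapshot stack, so backtracking is a size
restore and row contents are preserved as sets — the single-buffer
scheme that also gives good cache behaviour. If a row empties the
branch is abandoned. When the stack reaches `t` items their common
d-neighborhood is enumerated and each neighbor is kept only if every
remaining row still contains a window within `d`; these candidates are
finally verified against the held-out sequences (below). Soundness of
checking only the *filtered* rows follows because every filter rule is
a necessary condition: a window within `d` of a true motif can never
be removed.

## Heuristics t and n′

`t = max(2, ⌊(2(d+1)·ln σ − ln m)/ln σ⌋)`, clamped to `[2, n]`:
deeper stacks for larger d and σ (neighborhoods shrink exponentially
with each added tuple member), shallower for longer sequences (more
filtering work per push). The log base and rounding are fixed here as
natural log and floor; `m` is taken as the longest sequence length.
`n′ = clamp(⌊t + n/4 − ln t⌋, t, n)`: the search runs on the first n′
sequences only and candidates are then verified against the remaining
n − n′ by direct scan. Both are performance knobs only; the test
suite sweeps `t`, `n′`, all speedup toggles and worker counts and
requires bit-identical motif sets.

## Statistics

With `N(σ,l,d) = Σ_{i≤d} C(l,i)(σ−1)^i` (Hamming-ball size),
`p = N/σ^l`, `q = 1 − (1−p)^{m−l+1}`, the expected number of chance
("spurious") motifs is `E = σ^l·q^n`. `E` is assembled in log space
(`q^n` reaches ~1e-25 in relevant regimes; a naive product would
flush to zero). An (l,d) pair is *challenging* when `d` is minimal
with `E ≥ 1`; at the 20×600 DNA benchmark this yields (13,4) and
(15,5), which the acceptance script recomputes. Under this exact
formula chain E for (17,6) falls marginally below 1, so the
conventional continuation of the challenging list is sensitive to
rounding conventions there; the implementation follows the formula
strictly.

## Parallelism

The problem splits into m₁−l+1 independent subproblems, one per
first-sequence window. Their runtimes vary wildly, so jobs are pulled
dynamically by idle workers (process pool, chunk size 1) rather than
pre-assigned; results are merged as a sorted set, making the output
independent of completion order and worker count. A failed job is
retried once, then the error propagates. Cluster-scale deployment is
out of scope; the scheduler/worker contract is the same.

## Numerical and degenerate-input choices

* Consensus tie-break: lowest symbol code wins (only the distance
  value matters to pruning; the choice fixes reproducibility).
* Packed distances: ⌈log₂σ⌉ bits per symbol, ⌊16/bits⌋ symbols per
  16-bit chunk (8 for DNA, 3 for protein); the final partial chunk is
  masked so distances are exact for any l. Overlapping windows share
  the per-position chunk array, keeping storage linear in total
  sequence length. Equality with plain distances is property-tested;
  all packing/pair-table toggles are output-invariant.
* d = 0 degenerates to exact common-substring search through the same
  code path; n = 1 reduces to single-l-mer neighborhood enumeration.
* Sequences of unequal length are accepted; `l` must not exceed the
  shortest.
* Unknown characters (N, X) are rejected in strict FASTA mode and the
  sequence is dropped otherwise — Hamming semantics for wildcards is
  deliberately not defined.

## Problem sizes used in the test suite

The exactness suite compares the search against the brute-force
reference on 50 randomized instances (n ∈ [3,10], m ∈ [20,60],
l ∈ [4,8], d ∈ [0,2], DNA and a 5-letter alphabet). Plant recovery at
benchmark difficulty runs a (13,4) instance with n=20 at m=200 — the
same challenging regime with a desk-scale sequence length — while the
acceptance script's analytic targets use the full n=20, m=600 shape.
Triple-condition equivalence uses the complete l=3 grid plus ~10⁵
random triples spread over l = 4..8.

## Known limitations

* Single forward strand; no reverse-complement handling.
* Quorum variants (motif present in only q < n sequences) are not
  implemented.
* The brute-force oracle is anchored on first-sequence windows and is
  intended for small l·d only (it guards itself with a work cap).
* Runtime grows steeply with d; the pure-Python/numpy implementation
  targets correctness and desk-scale instances, not the wall-clock
  performance of a tuned native implementation.
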