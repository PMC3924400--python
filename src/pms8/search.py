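"""The PMS8 exact motif search.

Given n sequences and parameters (l, d), find every l-mer M that lies
within Hamming distance d of at least one window in *every* sequence.

The search is a hybrid of two phases:

* **sample driven** — build tuples of windows, one per sequence, on a
  stack. Each push filters the remaining candidate rows: a surviving
  candidate must be within 2d of the new item (pairwise condition),
  pass the necessary-and-sufficient triple condition with every item
  already on the stack, and keep the consensus total distance of the
  whole tuple within its summed budget. If a row empties, the branch
  is dead and the stack pops.
* **pattern driven** — once the stack holds t items, enumerate their
  common d-neighborhood and keep the neighbors that still have a
  within-d window in every remaining row.

The candidate matrix R stores all rows in a single buffer: filtering
moves survivors to the row prefix and pushes the old size on a stack,
so a pop is just a size restore (the paper's in-place / cache-locality
scheme). Optionally the search runs on only the first n′ sequences and
verifies each candidate motif against the held-out n − n′ sequences.

Correctness is independent of every speed knob: the threshold t, the
subset size n′, row sorting, the packed distance table, the
precomputed pair mask, the strong-vs-minimal filter variant and the
worker count only trade work between phases.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .distance import (
    cross_distance_matrix,
    cross_distance_matrix_direct,
    hamming_distance,
    pack_all_lmers,
    precompute_pair_flags,
    window_matrix,
)
from .instances import Instance
from .neighborhood import generate_common_neighborhood_codes
from .pruning import consensus_after_adding_batch, triple_condition_batch

__all__ = [
    "SearchParams",
    "MotifResult",
    "CandidateMatrix",
    "pms8_search",
    "verify_motif",
    "choose_threshold_t",
    "choose_n_prime",
    "filter_row",
    "sort_rows_by_size",
    "candidate_keep_mask",
]


@dataclass
class SearchParams:
    """Tuning knobs of the search; none of them affects the result set.

    ``threshold_t`` / ``n_prime``: explicit phase-switch depth and
    subset size, or None for the built-in heuristics. ``seed`` is
    reserved for future randomized heuristics; the search itself is
    deterministic.
    """

    threshold_t: int | None = None
    n_prime: int | None = None
    sort_rows: bool = True
    pair_table: bool = True
    packing: bool = True
    minimal_filter: bool = False
    workers: int = 1
    seed: int | None = None
    debug_checks: bool = False


@dataclass
class MotifResult:
    """Deduplicated, lexicographically sorted motifs plus run counters."""

    motifs: list[str]
    positions: dict[str, list[int]] | None = None
    stats: dict[str, int] = field(default_factory=dict)


def choose_threshold_t(m: int, d: int, sigma: int) -> int:
    """Heuristic stack depth at which to switch to neighborhood generation.

    t = max(2, ⌊(2(d+1)·ln σ − ln m) / ln σ⌋): grows with d and σ (to
    avoid huge neighborhoods), shrinks with m (to avoid over-filtering).
    Purely a performance knob — any t gives the same motif set.
    """
    if m <= 0 or sigma < 2:
        raise ValueError("need m > 0 and sigma >= 2")
    val = (2 * (d + 1) * math.log(sigma) - math.log(m)) / math.log(sigma)
    return max(2, math.floor(val))


def choose_n_prime(n: int, t: int) -> int:
    """Heuristic subset size n′ = clamp(⌊t + n/4 − ln t⌋, t, n).

    Motifs are searched on the first n′ sequences and verified against
    the rest; the output is invariant to any valid n′.
    """
    if n < 1 or t < 1:
        raise ValueError("need n >= 1 and t >= 1")
    val = math.floor(t + n / 4 - math.log(t))
    return min(n, max(t, val))


def verify_motif(M: str, instance: Instance, l: int, d: int, from_row: int = 0) -> bool:
    """True iff every sequence with index ≥ from_row has a window within d of M."""
    if len(M) != l:
        raise ValueError(f"motif length {len(M)} != l={l}")
    mc = instance.alphabet.encode(M)
    for codes in instance.encoded()[from_row:]:
        win = window_matrix(codes, l)
        dist = np.zeros(win.shape[0], dtype=np.int32)
        for c in range(l):
            dist += win[:, c] != mc[c]
        if not (dist <= d).any():
            return False
    return True


def candidate_keep_mask(
    U: np.ndarray,
    new_codes: np.ndarray,
    stack_codes: list[np.ndarray],
    d: int,
    sigma: int,
    minimal: bool = False,
    pair_ok: np.ndarray | None = None,
) -> np.ndarray:
    """Which rows of U survive a push of ``new_codes`` onto the stack.

    ``stack_codes`` are the items already below the new one. A
    candidate u is kept iff (pairwise) H(u, new) ≤ 2d, (triples) the
    necessary-and-sufficient condition holds for (s, new, u) with every
    s below — or only with the first stack item in ``minimal`` mode, as
    in the literal formulation — and (tuple) the consensus total
    distance of stack ∪ {new, u} is at most its summed budget.
    ``pair_ok`` can supply the precomputed pairwise verdicts.
    """
    l = U.shape[1]
    if pair_ok is not None:
        keep = pair_ok.copy()
    else:
        dist = np.zeros(U.shape[0], dtype=np.int32)
        for c in range(l):
            dist += U[:, c] != new_codes[c]
        keep = dist <= 2 * d
    if not keep.any() or not stack_codes:
        return keep

    below = stack_codes[:1] if minimal else stack_codes
    for s in below:
        keep &= triple_condition_batch(s, new_codes, U, d, d, d)
        if not keep.any():
            return keep

    if not minimal:
        members = stack_codes + [new_codes]
        counts = np.zeros((l, sigma), dtype=np.int32)
        for s in members:
            counts[np.arange(l), s] += 1
        col_max = counts.max(axis=1)
        cd = consensus_after_adding_batch(counts, col_max, U)
        keep &= cd <= (len(members) + 1) * d
    return keep


def filter_row(row, new_item, stack, d: int, alphabet=None, minimal: bool = False):
    """Filter a row of candidate l-mers against a newly pushed l-mer.

    String-level convenience wrapper over :func:`candidate_keep_mask`:
    ``row`` is a list of candidate l-mers, ``new_item`` the l-mer just
    pushed, ``stack`` the l-mers already below it. Returns the kept
    candidates, order preserved.
    """
    from .alphabet import DNA

    ab = alphabet or DNA
    U = np.vstack([ab.encode(u) for u in row])
    keep = candidate_keep_mask(
        U, ab.encode(new_item), [ab.encode(s) for s in stack], d, ab.size,
        minimal=minimal,
    )
    return [u for u, k in zip(row, keep) if k]


class CandidateMatrix:
    """Rows of candidate window indices with snapshot push/pop filtering.

    All rows live in fixed buffers; filtering partitions a row so the
    survivors occupy the prefix and records the old size, so reverting
    is a size restore (row contents are preserved as sets, possibly
    permuted — exactly the in-place scheme the search relies on).
    """

    def __init__(self, row_sizes: list[int]):
        self.rows = [np.arange(s, dtype=np.int64) for s in row_sizes]
        self.sizes = list(row_sizes)
        self.row_order = list(range(len(row_sizes)))
        self._snapshots: list[tuple[list[int], list[int]]] = []

    @property
    def depth(self) -> int:
        return len(self._snapshots)

    def active(self, r: int) -> np.ndarray:
        return self.rows[r][: self.sizes[r]]

    def push_snapshot(self) -> None:
        self._snapshots.append((list(self.sizes), list(self.row_order)))

    def pop_snapshot(self) -> None:
        self.sizes, self.row_order = self._snapshots.pop()

    def apply_keep(self, r: int, keep: np.ndarray) -> int:
        """Move kept elements to the row prefix; returns the new size."""
        idx = self.rows[r][: self.sizes[r]]
        kept = idx[keep]
        dropped = idx[~keep]
        self.rows[r][: len(kept)] = kept
        self.rows[r][len(kept) : self.sizes[r]] = dropped
        self.sizes[r] = len(kept)
        return self.sizes[r]


def sort_rows_by_size(matrix: CandidateMatrix, from_pos: int = 0) -> list[int]:
    """Stably reorder the unconsumed rows (positions ≥ from_pos) by size.

    Returns the new row order; ties keep their previous relative order.
    """
    tail = matrix.row_order[from_pos:]
    tail_sorted = sorted(tail, key=lambda r: matrix.sizes[r])
    matrix.row_order[from_pos:] = tail_sorted
    return list(matrix.row_order)


class _CoreSearch:
    """Sample-driven / pattern-driven search over the first n′ sequences."""

    def __init__(self, codes: list[np.ndarray], l: int, d: int, t: int,
                 sigma: int, params: SearchParams, stats: dict):
        self.codes = codes
        self.l = l
        self.d = d
        self.sigma = sigma
        self.params = params
        self.stats = stats
        self.windows = [window_matrix(c, l) for c in codes]
        self.n_rows = len(codes)
        self.t_eff = min(t, self.n_rows)
        self.pair_mask = None
        if params.pair_table:
            inst = _codes_instance(codes, sigma)
            if params.packing:
                table = pack_all_lmers(inst, l)
                self.pair_mask = precompute_pair_flags(table, 2 * d)
            else:
                masks = {}
                for i in range(self.n_rows):
                    for j in range(i + 1, self.n_rows):
                        dm = cross_distance_matrix_direct(
                            self.windows[i], self.windows[j]
                        )
                        masks[(i, j)] = dm <= 2 * d
                from .distance import PairCompatibilityMask

                self.pair_mask = PairCompatibilityMask(2 * d, masks)

    def run(self) -> set[bytes]:
        self.matrix = CandidateMatrix([w.shape[0] for w in self.windows])
        if self.params.sort_rows:
            sort_rows_by_size(self.matrix, 0)
        self.stack: list[tuple[int, int]] = []  # (row, window index)
        self.stack_codes: list[np.ndarray] = []
        self.found: set[bytes] = set()
        self._recurse(0)
        return self.found

    # -- recursion ---------------------------------------------------------

    def _recurse(self, depth: int) -> None:
        if depth == self.t_eff:
            self._emit(depth)
            return
        r = self.matrix.row_order[depth]
        # the row is consumed at this depth: deeper filtering never touches
        # it, so iterating over its current prefix is stable
        count = self.matrix.sizes[r]
        for pos in range(count):
            widx = int(self.matrix.rows[r][pos])
            x_codes = self.windows[r][widx]
            self.stats["tuples_explored"] += 1
            self.matrix.push_snapshot()
            ok = True
            for rpos in range(depth + 1, self.n_rows):
                rr = self.matrix.row_order[rpos]
                if self._filter(rr, r, widx, x_codes) == 0:
                    ok = False
                    break
            if ok:
                if self.params.sort_rows:
                    sort_rows_by_size(self.matrix, depth + 1)
                self.stack.append((r, widx))
                self.stack_codes.append(x_codes)
                if self.params.debug_checks:
                    self._assert_stack_invariants()
                self._recurse(depth + 1)
                self.stack.pop()
                self.stack_codes.pop()
            self.matrix.pop_snapshot()

    def _filter(self, row: int, x_row: int, x_widx: int, x_codes: np.ndarray) -> int:
        idx = self.matrix.active(row)
        U = self.windows[row][idx]
        pair_ok = None
        if self.pair_mask is not None:
            pair_ok = self.pair_mask.matrix(x_row, row)[x_widx, idx]
        keep = candidate_keep_mask(
            U, x_codes, self.stack_codes, self.d, self.sigma,
            minimal=self.params.minimal_filter, pair_ok=pair_ok,
        )
        if keep.all():
            return self.matrix.sizes[row]
        return self.matrix.apply_keep(row, keep)

    def _emit(self, depth: int) -> None:
        self.stats["neighborhoods_generated"] += 1
        T = np.vstack(self.stack_codes)
        neighbors = generate_common_neighborhood_codes(
            T, [self.d] * len(self.stack_codes), self.sigma
        )
        if not neighbors:
            return
        nb = np.vstack(neighbors)
        alive = np.ones(nb.shape[0], dtype=bool)
        for rpos in range(depth, self.n_rows):
            r = self.matrix.row_order[rpos]
            idx = self.matrix.active(r)
            U = self.windows[r][idx]
            dist = np.zeros((nb.shape[0], U.shape[0]), dtype=np.int32)
            for c in range(self.l):
                dist += nb[:, c][:, None] != U[None, :, c]
            alive &= (dist <= self.d).any(axis=1)
            if not alive.any():
                return
        self.stats["candidates_verified"] += int(alive.sum())
        for m in nb[alive]:
            self.found.add(m.tobytes())

    def _assert_stack_invariants(self) -> None:
        from .pruning import pair_condition, triple_condition

        d = self.d
        k = len(self.stack_codes)
        for i in range(k):
            for j in range(i + 1, k):
                assert pair_condition(self.stack_codes[i], self.stack_codes[j], d, d)
        for i in range(2, k):
            assert triple_condition(
                self.stack_codes[0], self.stack_codes[1], self.stack_codes[i],
                [d, d, d],
            )


def _codes_instance(codes: list[np.ndarray], sigma: int) -> Instance:
    """Wrap raw code arrays as an Instance over a synthetic code alphabet."""
    from .alphabet import Alphabet

    symbols = "".join(chr(ord("A") + i) for i in range(sigma))
    ab = Alphabet(f"codes{sigma}", symbols)
    inst = Instance.__new__(Instance)
    inst.sequences = [ab.decode(c) for c in codes]
    inst.alphabet = ab
    inst._codes = [np.asarray(c, dtype=np.uint8) for c in codes]
    return inst


def pms8_search(
    instance: Instance,
    l: int,
    d: int,
    params: SearchParams | None = None,
    with_positions: bool = False,
) -> MotifResult:
    """Exact (l,d)-motif search: all l-mers within d of every sequence.

    The result is exactly the brute-force motif set, independent of all
    tuning parameters in ``params``.
    """
    params = params or SearchParams()
    if d > l:
        raise ValueError(f"d={d} exceeds l={l}")
    if any(m < l for m in instance.lengths):
        raise ValueError(f"l={l} exceeds the shortest sequence length")
    if params.workers > 1:
        from .parallel import run_parallel_search

        return run_parallel_search(
            instance, l, d, replace(params, workers=1),
            workers=params.workers, with_positions=with_positions,
        )

    sigma = instance.alphabet.size
    n = instance.n
    t = params.threshold_t
    if t is None:
        t = choose_threshold_t(max(instance.lengths), d, sigma)
    t = min(max(1, t), n)
    n_prime = params.n_prime
    if n_prime is None:
        n_prime = choose_n_prime(n, t)
    n_prime = min(max(t, n_prime), n)

    stats = {"tuples_explored": 0, "neighborhoods_generated": 0,
             "candidates_verified": 0}
    codes = instance.encoded()[:n_prime]
    core = _CoreSearch(codes, l, d, t, sigma, params, stats)
    raw = core.run()

    decode = instance.alphabet.decode
    motifs = []
    for b in raw:
        m = decode(np.frombuffer(b, dtype=np.uint8))
        if n_prime == n or verify_motif(m, instance, l, d, from_row=n_prime):
            motifs.append(m)
    motifs.sort()

    positions = None
    if with_positions:
        positions = {m: _witness_positions(m, instance, l, d) for m in motifs}
    return MotifResult(motifs=motifs, positions=positions, stats=stats)


def _witness_positions(M: str, instance: Instance, l: int, d: int) -> list[int]:
    """First within-d window offset of M in each sequence."""
    mc = instance.alphabet.encode(M)
    out = []
    for codes in instance.encoded():
        win = window_matrix(codes, l)
        dist = np.zeros(win.shape[0], dtype=np.int32)
        for c in range(l):
            dist += win[:, c] != mc[c]
        hits = np.flatnonzero(dist <= d)
        out.append(int(hits[0]) if hits.size else -1)
    return out


def brute_check_motif(M: str, instance: Instance, l: int, d: int) -> bool:
    """Plain-Python motif check (used by debug assertions and tests)."""
    return all(
        min(
            hamming_distance(M, s[j : j + l]) for j in range(len(s) - l + 1)
        ) <= d
        for s in instance.sequences
    )
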