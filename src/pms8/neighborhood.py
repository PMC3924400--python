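"""Common d-neighborhood enumeration.

The common neighborhood of a tuple T of l-mers under budgets d_1..d_k
is {M ∈ Σ^l : H(M, T_i) ≤ d_i ∀i}. It is enumerated by depth-first
traversal of the |Σ|-ary tree of prefixes, fixing one column per level
in alphabet-code order (so emission is lexicographic). A node at depth
k holds the partial distances h_i = H(prefix, T_i[0..k)); three sound
pruning rules cut subtrees that provably contain no valid completion:

(a) budget overflow — some h_i > d_i (partial distances only grow);
(b) consensus suffix bound — Σ h_i + C(suffixes of T from k) > Σ d_i,
    the tuple necessary condition applied to the uncommitted columns;
(c) pairwise suffix bound — for some pair (i, j),
    h_i + h_j + H(suffix of T_i, suffix of T_j) > d_i + d_j.

Suffix statistics are precomputed once per tuple in O(l·|T|²) so each
node check is O(|T|²).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .alphabet import DNA, Alphabet
from .pruning import DistanceBudgets

__all__ = [
    "SuffixStats",
    "TraversalState",
    "prune_partial",
    "generate_common_neighborhood",
    "generate_common_neighborhood_codes",
]


@dataclass
class SuffixStats:
    """Per-suffix consensus and pairwise distances of a tuple T.

    ``consensus[k]`` is C(T restricted to columns k..l-1);
    ``pairwise[i, j, k]`` is H of the same suffixes of T_i and T_j.
    """

    consensus: np.ndarray
    pairwise: np.ndarray

    @classmethod
    def build(cls, T: np.ndarray, sigma: int) -> "SuffixStats":
        k, l = T.shape
        col_cd = np.empty(l, dtype=np.int64)
        for j in range(l):
            counts = np.bincount(T[:, j], minlength=sigma)
            col_cd[j] = k - counts.max()
        consensus = np.zeros(l + 1, dtype=np.int64)
        consensus[:l] = col_cd[::-1].cumsum()[::-1]

        pairwise = np.zeros((k, k, l + 1), dtype=np.int64)
        for i in range(k):
            for j in range(i + 1, k):
                ne = (T[i] != T[j]).astype(np.int64)
                suff = np.zeros(l + 1, dtype=np.int64)
                suff[:l] = ne[::-1].cumsum()[::-1]
                pairwise[i, j] = suff
                pairwise[j, i] = suff
        return cls(consensus=consensus, pairwise=pairwise)


@dataclass
class TraversalState:
    """A node of the prefix tree: ``depth`` columns fixed so far."""

    depth: int
    prefix: np.ndarray           # codes of the fixed columns, length >= depth
    partial_dists: np.ndarray    # h_i per tuple member
    suffix_stats: SuffixStats


def prune_partial(state: TraversalState, budgets: DistanceBudgets) -> bool:
    """True when no completion of the prefix can satisfy all budgets.

    Sound: never prunes a subtree containing a valid neighbor.
    """
    h = state.partial_dists
    d = np.asarray(budgets)
    k = state.depth
    if np.any(h > d):
        return True
    stats = state.suffix_stats
    if h.sum() + stats.consensus[k] > d.sum():
        return True
    kk = len(h)
    for i in range(kk):
        for j in range(i + 1, kk):
            if h[i] + h[j] + stats.pairwise[i, j, k] > d[i] + d[j]:
                return True
    return False


def generate_common_neighborhood_codes(
    T: np.ndarray,
    budgets: DistanceBudgets,
    sigma: int,
    visitor: Callable[[np.ndarray], None] | None = None,
    prune: bool = True,
) -> list[np.ndarray]:
    """Enumerate the common neighborhood over code arrays.

    ``T`` is a (k, l) code matrix. Emits each neighbor exactly once, in
    lexicographic order of codes. ``prune=False`` disables rules (b)
    and (c) (rule (a) alone already guarantees correctness) and exists
    to verify that pruning never changes the output.
    """
    T = np.ascontiguousarray(T)
    if T.ndim != 2 or T.shape[0] < 1:
        raise ValueError("T must be a non-empty (k, l) matrix")
    k, l = T.shape
    d = np.asarray(list(budgets), dtype=np.int64)
    if len(d) != k:
        raise ValueError("budgets must match |T|")
    stats = SuffixStats.build(T, sigma)
    sum_d = int(d.sum())

    pair_idx = [(i, j) for i in range(k) for j in range(i + 1, k)]
    out: list[np.ndarray] = []
    prefix = np.empty(l, dtype=np.uint8)
    h = np.zeros(k, dtype=np.int64)

    def rec(depth: int) -> None:
        if depth == l:
            m = prefix.copy()
            out.append(m)
            if visitor is not None:
                visitor(m)
            return
        col = T[:, depth]
        for c in range(sigma):
            inc = (col != c).astype(np.int64)
            h_new = h + inc
            if np.any(h_new > d):
                continue
            if prune:
                nd = depth + 1
                if h_new.sum() + stats.consensus[nd] > sum_d:
                    continue
                bad = False
                for i, j in pair_idx:
                    if h_new[i] + h_new[j] + stats.pairwise[i, j, nd] > d[i] + d[j]:
                        bad = True
                        break
                if bad:
                    continue
            prefix[depth] = c
            old = h.copy()
            h[:] = h_new
            rec(depth + 1)
            h[:] = old

    rec(0)
    return out


def generate_common_neighborhood(
    T: Sequence[str],
    budgets: DistanceBudgets,
    alphabet: Alphabet = DNA,
    visitor: Callable[[str], None] | None = None,
    prune: bool = True,
) -> list[str]:
    """String-level wrapper over :func:`generate_common_neighborhood_codes`."""
    if len(T) == 0:
        raise ValueError("T must be non-empty")
    mat = np.vstack([alphabet.encode(t) for t in T])
    decode = alphabet.decode
    result: list[str] = []

    def emit(codes: np.ndarray) -> None:
        s = decode(codes)
        result.append(s)
        if visitor is not None:
            visitor(s)

    generate_common_neighborhood_codes(mat, budgets, alphabet.size, emit, prune)
    return result
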