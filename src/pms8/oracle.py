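"""Independent brute-force references.

These are deliberately naive, separate code paths — they share nothing
with the search or pruning machinery beyond plain Hamming distance —
so that agreement between the two routes is meaningful evidence of
correctness rather than a correlated bug.
"""

from __future__ import annotations

from itertools import combinations, product

import numpy as np

from .instances import Instance
from .pruning import DistanceBudgets

__all__ = [
    "brute_force_search",
    "exists_common_neighbor_exhaustive",
    "all_lmers_codes",
    "common_neighbor_truth_table",
]

_DEFAULT_CAP = 2_000_000


def _ball(word: str, d: int, symbols: str) -> set[str]:
    """All strings within Hamming distance d of ``word`` (plain enumeration)."""
    l = len(word)
    out = {word}
    for k in range(1, d + 1):
        for sites in combinations(range(l), k):
            alts = [[c for c in symbols if c != word[i]] for i in sites]
            for repl in product(*alts):
                w = list(word)
                for i, c in zip(sites, repl):
                    w[i] = c
                out.add("".join(w))
    return out


def brute_force_search(instance: Instance, l: int, d: int, cap: int = _DEFAULT_CAP):
    """Exhaustive motif search: the reference the fast search is tested against.

    Candidates are the union of d-neighborhoods of the first sequence's
    windows (every motif must be within d of some first-sequence
    window); each candidate is verified by direct scanning of every
    sequence. Returns the sorted motif list.
    """
    from .stats import neighborhood_size  # local: avoids cycle at import time

    if any(m < l for m in instance.lengths):
        raise ValueError(f"l={l} exceeds the shortest sequence length")
    if d > l:
        raise ValueError(f"d={d} exceeds l={l}")
    symbols = instance.alphabet.symbols
    n_windows = len(instance.sequences[0]) - l + 1
    est = n_windows * neighborhood_size(instance.alphabet.size, l, d)
    if est > cap:
        raise ValueError(
            f"brute force would enumerate ~{est} candidates (cap {cap}); "
            "use smaller l or d"
        )

    candidates: set[str] = set()
    first = instance.sequences[0]
    for j in range(n_windows):
        candidates |= _ball(first[j : j + l], d, symbols)

    # verify by direct scan, vectorised over candidates per sequence
    cand = sorted(candidates)
    enc = instance.alphabet.encode
    cmat = np.vstack([enc(c) for c in cand])
    alive = np.ones(len(cand), dtype=bool)
    for codes in instance.encoded():
        win = np.lib.stride_tricks.sliding_window_view(codes, l)
        dist = np.zeros((cmat.shape[0], win.shape[0]), dtype=np.int32)
        for c in range(l):
            dist += cmat[:, c][:, None] != win[None, :, c]
        alive &= (dist <= d).any(axis=1)
    return [c for c, ok in zip(cand, alive) if ok]


def exists_common_neighbor_exhaustive(
    T, budgets: DistanceBudgets, symbols: str = "ACGT", cap: int = _DEFAULT_CAP
) -> bool:
    """True iff some string in Σ^l meets every budget — by full scan."""
    if len(T) != len(budgets) or len(T) < 1:
        raise ValueError("T and budgets must have equal, positive length")
    l = len(T[0])
    if len(symbols) ** l > cap:
        raise ValueError(f"|Sigma|^l = {len(symbols) ** l} exceeds cap {cap}")
    for m in product(symbols, repeat=l):
        if all(
            sum(a != b for a, b in zip(m, t)) <= di for t, di in zip(T, budgets)
        ):
            return True
    return False


def all_lmers_codes(sigma: int, l: int) -> np.ndarray:
    """All σ^l code words as a (σ^l, l) matrix, lexicographic order."""
    grids = np.meshgrid(*([np.arange(sigma, dtype=np.uint8)] * l), indexing="ij")
    return np.stack([g.ravel() for g in grids], axis=1)


def common_neighbor_truth_table(
    sigma: int, l: int, budgets: DistanceBudgets
) -> np.ndarray:
    """Exhaustive common-neighbor existence for *all* σ^l triples at once.

    Returns a boolean (σ^l, σ^l, σ^l) tensor E with
    E[a, b, c] = ∃M: H(M,a) ≤ d1 ∧ H(M,b) ≤ d2 ∧ H(M,c) ≤ d3,
    computed from the full pairwise distance matrix — no pruning logic
    involved. Intended for small σ^l (e.g. all DNA 3-mers).
    """
    d1, d2, d3 = budgets
    words = all_lmers_codes(sigma, l)
    q = words.shape[0]
    dist = np.zeros((q, q), dtype=np.int16)
    for c in range(l):
        dist += words[:, c][:, None] != words[None, :, c]
    b1 = dist <= d1
    b2 = dist <= d2
    b3 = dist <= d3
    # E[a,b,c] = any_M b1[a,M] & b2[b,M] & b3[c,M]
    ab = b1[:, None, :] & b2[None, :, :]              # (q, q, M)
    return np.tensordot(ab, b3, axes=([2], [1])) > 0  # sum over M
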