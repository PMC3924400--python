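"""Pruning conditions for common d-neighbor existence.

For l-mers T_1..T_k and per-member distance budgets d_1..d_k, when does
an l-mer M exist with H(M, T_i) ≤ d_i for every i?

* k = 2: exactly when H(T_1, T_2) ≤ d_1 + d_2 (necessary and
  sufficient).
* k = 3: exactly when every pair satisfies the pairwise bound AND the
  consensus total distance satisfies C(T) ≤ d_1 + d_2 + d_3. The proof
  is constructive and :func:`construct_common_neighbor` builds a
  witness whenever the condition holds.
* k ≥ 4: C(T) ≤ Σ d_i is necessary only; a False answer is a sound
  prune, a True answer is non-conclusive.

The triple condition is evaluated through the column classification of
a 3-tuple: a column is of type N0 if all three symbols agree, N1/N2/N3
if exactly member 1/2/3 disagrees with the other two, and N4 if all
three differ. Writing n_i for the count of type-N_i columns,

    H(T_1,T_2) = n1 + n2 + n4        (similarly for the other pairs)
    C(T)       = n1 + n2 + n3 + 2·n4

Batch (vectorised) forms of the pair and triple conditions are provided
for the search's row filtering, where one new l-mer is tested against a
whole candidate row at once.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .distance import _as_code_rows, consensus_total_distance, hamming_distance

__all__ = [
    "DistanceBudgets",
    "ColumnTypeCounts",
    "pair_condition",
    "column_type_counts",
    "triple_condition",
    "construct_common_neighbor",
    "tuple_necessary_condition",
    "triple_condition_batch",
    "triple_condition_grid",
    "consensus_after_adding_batch",
]


DistanceBudgets = Sequence[int]


@dataclass(frozen=True)
class ColumnTypeCounts:
    """Counts n0..n4 of the five column types of a 3-tuple."""

    n0: int
    n1: int
    n2: int
    n3: int
    n4: int

    @property
    def total(self) -> int:
        return self.n0 + self.n1 + self.n2 + self.n3 + self.n4


def pair_condition(a, b, da: int, db: int) -> bool:
    """True iff a and b have a common neighbor within budgets (da, db).

    Exact for two l-mers: such an M exists iff H(a,b) ≤ da + db.
    """
    return hamming_distance(a, b) <= da + db


def column_type_counts(t1, t2, t3) -> ColumnTypeCounts:
    """Classify every column of the 3-tuple into types N0..N4."""
    mat = _as_code_rows([t1, t2, t3])
    a, b, c = mat
    eq_ab, eq_ac, eq_bc = a == b, a == c, b == c
    n0 = int(np.count_nonzero(eq_ab & eq_ac))
    n1 = int(np.count_nonzero(~eq_ab & eq_bc))      # t1 is the odd one out
    n2 = int(np.count_nonzero(~eq_ab & eq_ac))      # t2 is the odd one out
    n3 = int(np.count_nonzero(eq_ab & ~eq_ac))      # t3 is the odd one out
    n4 = int(np.count_nonzero(~eq_ab & ~eq_ac & ~eq_bc))
    return ColumnTypeCounts(n0, n1, n2, n3, n4)


def triple_condition(t1, t2, t3, budgets: DistanceBudgets) -> bool:
    """Necessary-and-sufficient common-neighbor test for three l-mers.

    True iff H(T_i,T_j) ≤ d_i + d_j for all three pairs and
    C(T) ≤ d_1 + d_2 + d_3.
    """
    d1, d2, d3 = budgets
    ct = column_type_counts(t1, t2, t3)
    h12 = ct.n1 + ct.n2 + ct.n4
    h13 = ct.n1 + ct.n3 + ct.n4
    h23 = ct.n2 + ct.n3 + ct.n4
    cd = ct.n1 + ct.n2 + ct.n3 + 2 * ct.n4
    return h12 <= d1 + d2 and h13 <= d1 + d3 and h23 <= d2 + d3 and cd <= d1 + d2 + d3


def tuple_necessary_condition(T, budgets: DistanceBudgets) -> bool:
    """Consensus-distance prune for any tuple size.

    False guarantees no common neighbor exists within the budgets
    (pigeonhole on the columnwise lower bound); True is conclusive only
    for |T| ≤ 3 when combined with the pairwise conditions.
    """
    if len(T) != len(budgets) or len(T) < 1:
        raise ValueError("T and budgets must have equal, positive length")
    return consensus_total_distance(T) <= sum(budgets)


def construct_common_neighbor(t1, t2, t3, budgets: DistanceBudgets):
    """Build a common neighbor of three l-mers, or None if none exists.

    Returns None exactly when :func:`triple_condition` is False;
    otherwise an l-mer M with H(M, t_i) ≤ d_i for all i, built by the
    constructive case analysis:

    * Case 1 — some n_i ≥ d_i: copy t_i, except in the leftmost d_i
      columns of type N_i where the other two members' shared symbol is
      used.
    * Case 2 — all n_i < d_i: columns of type N0/N2/N3 take t1's
      symbol, N1 columns take t2's; then for each i the leftmost unused
      max(0, n_i + n4 − d_i) columns of type N4 take t_i's symbol
      (always feasible when the condition holds); leftover N4 columns
      default to t1's symbol.
    """
    if not triple_condition(t1, t2, t3, budgets):
        return None
    as_str = isinstance(t1, str)
    mat = _as_code_rows([t1, t2, t3])
    rows = [mat[0], mat[1], mat[2]]
    eq_ab = mat[0] == mat[1]
    eq_ac = mat[0] == mat[2]
    eq_bc = mat[1] == mat[2]
    type_cols = {
        1: np.flatnonzero(~eq_ab & eq_bc),
        2: np.flatnonzero(~eq_ab & eq_ac),
        3: np.flatnonzero(eq_ab & ~eq_ac),
        4: np.flatnonzero(~eq_ab & ~eq_ac & ~eq_bc),
    }
    counts = {i: len(type_cols[i]) for i in (1, 2, 3, 4)}

    case1 = next((i for i in (1, 2, 3) if counts[i] >= budgets[i - 1]), None)
    if case1 is not None:
        i = case1
        other = 2 if i == 1 else 1  # any j != i carries the shared symbol
        M = rows[i - 1].copy()
        chosen = type_cols[i][: budgets[i - 1]]
        M[chosen] = rows[other - 1][chosen]
    else:
        M = rows[0].copy()
        M[type_cols[1]] = rows[1][type_cols[1]]
        n4 = counts[4]
        used = 0
        for i in (1, 2, 3):
            need = max(0, counts[i] + n4 - budgets[i - 1])
            cols = type_cols[4][used : used + need]
            M[cols] = rows[i - 1][cols]
            used += need
        # leftover N4 columns keep t1's symbol (already copied)
    if as_str:
        return "".join(chr(c) for c in M)
    return M


def triple_condition_batch(
    a: np.ndarray, b: np.ndarray, U: np.ndarray, da: int, db: int, du: int
) -> np.ndarray:
    """Vectorised triple condition for (a, b, u) over all rows u of U.

    ``a`` and ``b`` are (l,) code arrays, ``U`` is (K, l). Returns a
    boolean keep-vector of length K. The caller is expected to have
    already established H(a, b) ≤ da + db.
    """
    eq_ab = a == b
    eq_au = U == a
    eq_bu = U == b
    h_au = U.shape[1] - eq_au.sum(axis=1)
    h_bu = U.shape[1] - eq_bu.sum(axis=1)
    n0 = (eq_ab & eq_au).sum(axis=1)
    n4 = (~eq_ab & ~eq_au & ~eq_bu).sum(axis=1)
    cd = U.shape[1] - n0 + n4
    return (h_au <= da + du) & (h_bu <= db + du) & (cd <= da + db + du)


def triple_condition_grid(words: np.ndarray, budgets: DistanceBudgets) -> np.ndarray:
    """Triple condition for *every* ordered triple of a word set at once.

    ``words`` is a (q, l) code matrix; returns a boolean (q, q, q)
    tensor V with V[a, b, c] = triple_condition(words[a], words[b],
    words[c], budgets). Used to sweep all triples of a small alphabet
    (e.g. all DNA 3-mers) without a Python-level loop.
    """
    d1, d2, d3 = budgets
    q, l = words.shape
    eq = words[:, None, :] == words[None, :, :]          # (q, q, l)
    dist = l - eq.sum(axis=2)                            # pairwise H
    n0 = np.zeros((q, q, q), dtype=np.int16)
    n4 = np.zeros((q, q, q), dtype=np.int16)
    for j in range(l):
        e_ab = eq[:, :, j][:, :, None]                   # a vs b
        e_ac = eq[:, :, j][:, None, :]                   # a vs c
        e_bc = eq[:, :, j][None, :, :]                   # b vs c
        n0 += e_ab & e_ac
        n4 += ~e_ab & ~e_ac & ~e_bc
    cd = l - n0 + n4                                     # n1+n2+n3+2*n4
    return (
        (dist[:, :, None] <= d1 + d2)
        & (dist[:, None, :] <= d1 + d3)
        & (dist[None, :, :] <= d2 + d3)
        & (cd <= d1 + d2 + d3)
    )


def consensus_after_adding_batch(
    column_counts: np.ndarray, column_max: np.ndarray, U: np.ndarray
) -> np.ndarray:
    """C(stack ∪ {u}) for every row u of U, from precomputed stack stats.

    ``column_counts`` is (l, sigma): per-column symbol counts over the k
    stack members; ``column_max`` is (l,): the per-column maxima.
    Returns an int vector of consensus total distances for k+1 strings.
    """
    l = column_counts.shape[0]
    k = int(column_counts[0].sum())
    with_u = column_counts[np.arange(l), U] + 1  # (K, l)
    newmax = np.maximum(column_max[None, :], with_u)
    return (k + 1) * l - newmax.sum(axis=1)
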