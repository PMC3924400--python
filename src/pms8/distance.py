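"""Hamming-distance primitives.

Three layers, all exact and interchangeable:

* plain character/code-wise distance (:func:`hamming_distance`);
* a packed representation that stores several symbols per 16-bit chunk
  so one XOR plus one table lookup yields the distance over a whole
  chunk (:class:`PackedLmerTable`) — a pure optimization, verified
  against the plain layer;
* a precomputed boolean pair-compatibility mask answering
  "is H(u,v) ≤ threshold?" for every cross-sequence window pair
  (:class:`PairCompatibilityMask`), used by the search's 2d filter.

The module also provides the consensus total distance C(T): the
columnwise sum of (|T| − max symbol frequency), which is the minimum
achievable total distance from any single string to all members of T.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .instances import Instance

__all__ = [
    "LmerRef",
    "PackedLmerTable",
    "PairCompatibilityMask",
    "hamming_distance",
    "window_matrix",
    "pack_all_lmers",
    "packed_distance",
    "cross_distance_matrix",
    "precompute_pair_flags",
    "consensus_total_distance",
    "consensus_string",
]


class LmerRef(NamedTuple):
    """Reference to the l-length window of a sequence starting at ``offset``."""

    seq_index: int
    offset: int


def hamming_distance(u, v) -> int:
    """Number of mismatching positions between two equal-length strings.

    Accepts plain strings or integer code arrays.
    """
    if len(u) != len(v):
        raise ValueError(f"length mismatch: {len(u)} vs {len(v)}")
    if isinstance(u, np.ndarray) or isinstance(v, np.ndarray):
        return int(np.count_nonzero(np.asarray(u) != np.asarray(v)))
    return sum(a != b for a, b in zip(u, v))


def window_matrix(codes: np.ndarray, l: int) -> np.ndarray:
    """All l-length windows of a code array as a (m-l+1, l) view."""
    if len(codes) < l:
        raise ValueError(f"sequence length {len(codes)} < l={l}")
    return np.lib.stride_tricks.sliding_window_view(codes, l)


@dataclass
class PackedLmerTable:
    """Chunk-packed windows of every sequence of an instance.

    ``bits`` bits encode one symbol; ``chunk_width`` symbols share one
    16-bit chunk (8 for DNA, 3 for protein). ``packed[i][j]`` packs
    symbols ``[j, j+chunk_width)`` of sequence i, so overlapping windows
    share storage and the table stays linear in total sequence length.
    XOR of two chunks has a zero group exactly where the symbols agree;
    ``popgroup`` maps any 16-bit value to its count of nonzero groups.
    """

    l: int
    bits: int
    chunk_width: int
    n_chunks: int
    last_mask: int
    packed: list[np.ndarray]
    popgroup: np.ndarray
    codes: list[np.ndarray]

    def window_codes(self, ref: LmerRef) -> np.ndarray:
        self._check(ref)
        return self.codes[ref.seq_index][ref.offset : ref.offset + self.l]

    def unpack(self, ref: LmerRef) -> np.ndarray:
        """Decode a window from its packed chunks (round-trip check path)."""
        self._check(ref)
        out = np.empty(self.l, dtype=np.uint8)
        mask = (1 << self.bits) - 1
        for k in range(self.n_chunks):
            chunk = int(self.packed[ref.seq_index][ref.offset + k * self.chunk_width])
            for t in range(min(self.chunk_width, self.l - k * self.chunk_width)):
                out[k * self.chunk_width + t] = (chunk >> (self.bits * t)) & mask
        return out

    def n_windows(self, seq_index: int) -> int:
        return len(self.codes[seq_index]) - self.l + 1

    def _check(self, ref: LmerRef) -> None:
        if not 0 <= ref.seq_index < len(self.codes):
            raise IndexError(f"sequence index {ref.seq_index} out of range")
        if not 0 <= ref.offset <= len(self.codes[ref.seq_index]) - self.l:
            raise IndexError(
                f"offset {ref.offset} out of range for sequence {ref.seq_index}"
            )


def _popgroup_table(bits: int, chunk_width: int) -> np.ndarray:
    vals = np.arange(1 << 16, dtype=np.uint32)
    mask = (1 << bits) - 1
    counts = np.zeros(1 << 16, dtype=np.uint8)
    for t in range(chunk_width):
        counts += (((vals >> (bits * t)) & mask) != 0).astype(np.uint8)
    return counts


def pack_all_lmers(instance: Instance, l: int) -> PackedLmerTable:
    """Build the packed table for every window of every sequence."""
    if any(m < l for m in instance.lengths):
        raise ValueError(f"l={l} exceeds the shortest sequence length")
    sigma = instance.alphabet.size
    bits = max(1, int(np.ceil(np.log2(sigma))))
    if bits > 8:
        raise ValueError("alphabet too large to pack")
    chunk_width = 16 // bits
    n_chunks = -(-l // chunk_width)
    rem = l - (n_chunks - 1) * chunk_width
    last_mask = (1 << (bits * rem)) - 1

    packed = []
    for codes in instance.encoded():
        padded = np.zeros(len(codes) + chunk_width - 1, dtype=np.uint16)
        padded[: len(codes)] = codes
        acc = np.zeros(len(codes), dtype=np.uint16)
        for t in range(chunk_width):
            acc |= padded[t : t + len(codes)] << (bits * t)
        packed.append(acc)

    return PackedLmerTable(
        l=l,
        bits=bits,
        chunk_width=chunk_width,
        n_chunks=n_chunks,
        last_mask=last_mask,
        packed=packed,
        popgroup=_popgroup_table(bits, chunk_width),
        codes=instance.encoded(),
    )


def packed_distance(table: PackedLmerTable, a: LmerRef, b: LmerRef) -> int:
    """Hamming distance of two windows via chunk XOR + table lookup."""
    table._check(a)
    table._check(b)
    pa, pb = table.packed[a.seq_index], table.packed[b.seq_index]
    cw = table.chunk_width
    total = 0
    for k in range(table.n_chunks - 1):
        total += int(table.popgroup[pa[a.offset + k * cw] ^ pb[b.offset + k * cw]])
    k = table.n_chunks - 1
    x = (pa[a.offset + k * cw] ^ pb[b.offset + k * cw]) & table.last_mask
    return total + int(table.popgroup[x])


def cross_distance_matrix(table: PackedLmerTable, i: int, j: int) -> np.ndarray:
    """All-pairs window distances between sequences i and j (packed path)."""
    cw = table.chunk_width
    wi, wj = table.n_windows(i), table.n_windows(j)
    pi, pj = table.packed[i], table.packed[j]
    out = np.zeros((wi, wj), dtype=np.int16)
    for k in range(table.n_chunks):
        ci = pi[k * cw : k * cw + wi]
        cj = pj[k * cw : k * cw + wj]
        x = ci[:, None] ^ cj[None, :]
        if k == table.n_chunks - 1:
            x &= table.last_mask
        out += table.popgroup[x]
    return out


def cross_distance_matrix_direct(wi: np.ndarray, wj: np.ndarray) -> np.ndarray:
    """All-pairs distances between two window matrices, columnwise."""
    out = np.zeros((wi.shape[0], wj.shape[0]), dtype=np.int16)
    for c in range(wi.shape[1]):
        out += wi[:, c][:, None] != wj[None, :, c]
    return out


@dataclass
class PairCompatibilityMask:
    """For every cross-sequence window pair, whether H ≤ ``threshold``.

    Stored only for pairs in distinct sequences (the only pairs the
    search compares); symmetric by construction.
    """

    threshold: int
    masks: dict  # (i, j) with i < j -> bool matrix (windows_i x windows_j)

    def get(self, a: LmerRef, b: LmerRef) -> bool:
        i, j = a.seq_index, b.seq_index
        if i == j:
            raise ValueError("mask is defined for distinct sequences only")
        if i < j:
            return bool(self.masks[(i, j)][a.offset, b.offset])
        return bool(self.masks[(j, i)][b.offset, a.offset])

    def matrix(self, i: int, j: int) -> np.ndarray:
        """Mask rows indexed by windows of i, columns by windows of j."""
        if i < j:
            return self.masks[(i, j)]
        return self.masks[(j, i)].T


def precompute_pair_flags(
    table: PackedLmerTable, threshold: int
) -> PairCompatibilityMask:
    """Precompute H ≤ threshold for all cross-sequence window pairs."""
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    n = len(table.codes)
    masks = {}
    for i in range(n):
        for j in range(i + 1, n):
            masks[(i, j)] = cross_distance_matrix(table, i, j) <= threshold
    return PairCompatibilityMask(threshold=threshold, masks=masks)


def _as_code_rows(T) -> np.ndarray:
    rows = []
    length = None
    for t in T:
        arr = (
            np.asarray(t)
            if isinstance(t, np.ndarray)
            else np.frombuffer(t.encode("ascii"), dtype=np.uint8)
        )
        if length is None:
            length = len(arr)
        elif len(arr) != length:
            raise ValueError("all strings in T must have equal length")
        rows.append(arr)
    if not rows:
        raise ValueError("T must be non-empty")
    return np.vstack(rows)


def consensus_total_distance(T) -> int:
    """C(T) = Σ over columns of (|T| − max symbol frequency).

    Equals min over all strings M of Σ_u H(M, u); the minimum is
    achieved by any columnwise-consensus string. For |T| = 2 it equals
    the Hamming distance of the pair.
    """
    mat = _as_code_rows(T)
    k = mat.shape[0]
    total = 0
    for col in mat.T:
        _, counts = np.unique(col, return_counts=True)
        total += k - int(counts.max())
    return total


def consensus_string(T):
    """A columnwise majority string; ties go to the lowest symbol code.

    Returns the same type as the inputs (str in, str out).
    """
    as_str = isinstance(T[0], str)
    mat = _as_code_rows(T)
    out = []
    for col in mat.T:
        counts = Counter(col.tolist())
        best = min(counts, key=lambda c: (-counts[c], c))
        out.append(best)
    if as_str:
        return "".join(chr(c) for c in out)
    return np.array(out, dtype=np.uint8)
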