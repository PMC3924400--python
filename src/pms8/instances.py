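"""Problem instances: FASTA I/O and the planted-motif simulator.

An :class:`Instance` is a set of ``n`` sequences over a common alphabet
together with the search parameters supplied separately at search time.
The synthetic generator reproduces the standard evaluation model for
planted (l,d)-motif search: i.i.d. uniform background sequences, one
random l-mer motif, and one mutated copy of it planted at a uniformly
random offset in every sequence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .alphabet import DNA, Alphabet

__all__ = [
    "Instance",
    "PlantRecord",
    "read_fasta",
    "write_fasta",
    "generate_planted_instance",
    "write_plant_record",
    "read_plant_record",
]

logger = logging.getLogger(__name__)


@dataclass
class Instance:
    """``n`` sequences S_1..S_n over one alphabet.

    Sequence lengths m_i may differ; the uniform-m planted model is a
    property of the generator's output, not an input requirement.
    """

    sequences: list[str]
    alphabet: Alphabet = DNA
    _codes: list[np.ndarray] | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(self.sequences) < 1:
            raise ValueError("an instance needs at least one sequence")
        for i, s in enumerate(self.sequences):
            bad = next((c for c in s if c not in self.alphabet), None)
            if bad is not None:
                raise ValueError(
                    f"sequence {i}: character {bad!r} not in alphabet "
                    f"{self.alphabet.name!r}"
                )

    @property
    def n(self) -> int:
        return len(self.sequences)

    @property
    def lengths(self) -> list[int]:
        return [len(s) for s in self.sequences]

    def encoded(self) -> list[np.ndarray]:
        """Per-sequence uint8 code arrays (cached)."""
        if self._codes is None:
            self._codes = [self.alphabet.encode(s) for s in self.sequences]
        return self._codes


@dataclass
class PlantRecord:
    """Ground truth of a planted instance.

    ``positions[i]`` is the 0-based plant offset j_i in sequence i;
    ``mutated_copies[i]`` is the variant actually written into the
    half-open window ``[j_i, j_i + l)``; ``distances[i]`` its Hamming
    distance to the motif (≤ d by construction).
    """

    motif: str
    positions: list[int]
    mutated_copies: list[str]
    distances: list[int]


def read_fasta(path, alphabet: Alphabet = DNA, strict: bool = True) -> Instance:
    """Read a multi-FASTA file into an :class:`Instance`.

    Characters are uppercased before validation. In strict mode an
    out-of-alphabet character is an error naming the record and 1-based
    position; otherwise the offending sequence is dropped with a warning.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    sequences: list[str] = []
    for ridx, rec in enumerate(records, start=1):
        seq = str(rec.seq).upper()
        bad = next(
            ((pos, c) for pos, c in enumerate(seq, start=1) if c not in alphabet),
            None,
        )
        if bad is not None:
            pos, c = bad
            if strict:
                raise ValueError(
                    f"record {ridx} ({rec.id}): character {c!r} at position "
                    f"{pos} not in alphabet {alphabet.name!r}"
                )
            logger.warning(
                "dropping record %d (%s): character %r at position %d "
                "not in alphabet %r",
                ridx, rec.id, c, pos, alphabet.name,
            )
            continue
        sequences.append(seq)
    if not sequences:
        raise ValueError(f"no sequences from {path} pass alphabet validation")
    return Instance(sequences, alphabet)


def write_fasta(instance: Instance, path) -> None:
    """Write an instance as multi-FASTA; round-trips through :func:`read_fasta`."""
    records = [
        SeqRecord(Seq(s), id=f"seq{i}", description="")
        for i, s in enumerate(instance.sequences)
    ]
    SeqIO.write(records, str(path), "fasta")


def generate_planted_instance(
    n: int,
    m: int,
    l: int,
    d: int,
    alphabet: Alphabet = DNA,
    seed: int | None = None,
    mutation_mode: Literal["exact", "at_most"] = "exact",
) -> tuple[Instance, PlantRecord]:
    """Generate a planted (l,d) instance.

    ``n`` i.i.d.-uniform strings of length ``m``; a uniformly random
    l-mer motif; in each string an independently mutated copy of the
    motif overwrites a uniformly chosen window. ``exact`` mode
    substitutes exactly ``d`` distinct positions with a different
    symbol (the hardest variant of the model); ``at_most`` draws the
    mutation count uniformly from ``{0..d}``.
    """
    if l > m:
        raise ValueError(f"l={l} exceeds sequence length m={m}")
    if d > l:
        raise ValueError(f"d={d} exceeds motif length l={l}")
    if n < 1:
        raise ValueError("n must be >= 1")
    if mutation_mode not in ("exact", "at_most"):
        raise ValueError(f"unknown mutation_mode {mutation_mode!r}")

    rng = np.random.default_rng(seed)
    sigma = alphabet.size
    background = rng.integers(0, sigma, size=(n, m), dtype=np.uint8)
    motif_codes = rng.integers(0, sigma, size=l, dtype=np.uint8)

    positions: list[int] = []
    copies: list[str] = []
    distances: list[int] = []
    sequences: list[str] = []
    for i in range(n):
        k = d if mutation_mode == "exact" else int(rng.integers(0, d + 1))
        copy = motif_codes.copy()
        if k > 0:
            sites = rng.choice(l, size=k, replace=False)
            # adding 1..sigma-1 mod sigma guarantees a *different* symbol
            shift = rng.integers(1, sigma, size=k, dtype=np.uint8)
            copy[sites] = (copy[sites] + shift) % sigma
        j = int(rng.integers(0, m - l + 1))
        background[i, j : j + l] = copy
        positions.append(j)
        copies.append(alphabet.decode(copy))
        distances.append(int(np.count_nonzero(copy != motif_codes)))
        sequences.append(alphabet.decode(background[i]))

    instance = Instance(sequences, alphabet)
    record = PlantRecord(alphabet.decode(motif_codes), positions, copies, distances)
    return instance, record


def write_plant_record(record: PlantRecord, path) -> None:
    """Serialize the plant ground truth as a small TSV sidecar.

    Line 1 is the motif; then one line per sequence:
    ``seq_index<TAB>offset<TAB>mutated_copy``.
    """
    with open(path, "w") as fh:
        fh.write(record.motif + "\n")
        for i, (j, c) in enumerate(zip(record.positions, record.mutated_copies)):
            fh.write(f"{i}\t{j}\t{c}\n")


def read_plant_record(path) -> PlantRecord:
    """Inverse of :func:`write_plant_record` (distances recomputed)."""
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise ValueError(f"empty plant record file {path}")
    motif = lines[0].strip()
    positions, copies, distances = [], [], []
    for line in lines[1:]:
        if not line.strip():
            continue
        _, off, copy = line.split("\t")
        positions.append(int(off))
        copies.append(copy)
        distances.append(sum(a != b for a, b in zip(copy, motif)))
    return PlantRecord(motif, positions, copies, distances)
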