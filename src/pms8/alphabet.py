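"""Sequence alphabets and integer encoding.

Every symbol maps to a unique code in ``[0, size)``; all distance and
pruning machinery operates on these code arrays rather than on raw
strings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Alphabet", "DNA", "PROTEIN", "alphabet_from_name"]


@dataclass(frozen=True)
class Alphabet:
    """An ordered symbol set Σ with a fixed integer coding.

    Parameters
    ----------
    name:
        Identifier, e.g. ``"dna"``.
    symbols:
        The symbols in code order; code of ``symbols[i]`` is ``i``.
    """

    name: str
    symbols: str
    _index: dict = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(set(self.symbols)) != len(self.symbols):
            raise ValueError("alphabet symbols must be distinct")
        if len(self.symbols) < 2:
            raise ValueError("alphabet needs at least 2 symbols")
        object.__setattr__(
            self, "_index", {c: i for i, c in enumerate(self.symbols)}
        )

    @property
    def size(self) -> int:
        """|Σ| — 4 for DNA, 20 for protein."""
        return len(self.symbols)

    def __contains__(self, ch: str) -> bool:
        return ch in self._index

    def encode(self, s: str) -> np.ndarray:
        """Map a string to a uint8 code array."""
        try:
            return np.array([self._index[c] for c in s], dtype=np.uint8)
        except KeyError as exc:  # pragma: no cover - message formatting
            raise ValueError(
                f"character {exc.args[0]!r} not in alphabet {self.name!r}"
            ) from None

    def decode(self, codes) -> str:
        """Inverse of :meth:`encode`."""
        return "".join(self.symbols[int(c)] for c in codes)


DNA = Alphabet("dna", "ACGT")
PROTEIN = Alphabet("protein", "ACDEFGHIKLMNPQRSTVWY")


def alphabet_from_name(name: str) -> Alphabet:
    """Resolve ``"dna"``, ``"protein"`` or ``"custom:<symbols>"``."""
    if name == "dna":
        return DNA
    if name == "protein":
        return PROTEIN
    if name.startswith("custom:"):
        return Alphabet("custom", name.split(":", 1)[1].upper())
    raise ValueError(f"unknown alphabet {name!r}")
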