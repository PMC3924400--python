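"""Closed-form instance statistics for the planted (l,d) model.

For i.i.d. uniform sequences over an alphabet of size σ:

* N(σ,l,d) = Σ_{i=0}^{d} C(l,i)(σ−1)^i — the Hamming-ball
  (d-neighborhood) size of one l-mer;
* p = N/σ^l — probability that a fixed l-mer is a d-neighbor of a
  random l-mer;
* q = 1 − (1 − p)^(m−l+1) — probability that it has at least one
  d-neighbor among the windows of a random length-m string;
* E = σ^l · q^n — the expected number of spurious motifs (l-mers that
  are motifs of the instance by random chance alone).

An instance (l,d) is called *challenging* when d is the smallest
integer for which E ≥ 1 (at the standard benchmark shape n=20, m=600,
DNA, the challenging instances start (13,4), (15,5), ...).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .alphabet import DNA, Alphabet

__all__ = [
    "ExpectationModel",
    "neighborhood_size",
    "expected_spurious_motifs",
    "expectation_model",
    "smallest_challenging_d",
]


@dataclass(frozen=True)
class ExpectationModel:
    """The full quantity chain N → p → q → E for one parameter set."""

    sigma: int
    l: int
    d: int
    m: int
    n: int
    N: int
    p: float
    q: float
    E: float


def neighborhood_size(sigma: int, l: int, d: int) -> int:
    """Exact d-neighborhood size Σ_{i=0}^{d} C(l,i)(σ−1)^i."""
    if sigma < 2:
        raise ValueError("sigma must be >= 2")
    if not 0 <= d <= l:
        raise ValueError(f"need 0 <= d <= l, got d={d}, l={l}")
    return sum(math.comb(l, i) * (sigma - 1) ** i for i in range(d + 1))


def expectation_model(
    n: int, m: int, l: int, d: int, sigma: int = 4
) -> ExpectationModel:
    """Evaluate the spurious-motif expectation chain in log space.

    q^n can underflow double precision (≈1e-25 in interesting regimes),
    so E is assembled as exp(l·ln σ + n·ln q).
    """
    if l > m:
        raise ValueError(f"l={l} exceeds m={m}")
    if not 0 <= d <= l:
        raise ValueError(f"need 0 <= d <= l, got d={d}, l={l}")
    if n < 1 or sigma < 2:
        raise ValueError("need n >= 1 and sigma >= 2")
    N = neighborhood_size(sigma, l, d)
    log_p = math.log(N) - l * math.log(sigma)
    p = math.exp(log_p)
    if p >= 1.0:
        q = 1.0
        E = float(sigma) ** l
    else:
        # q = 1 - (1-p)^(m-l+1), stable for tiny p
        log_one_minus_q = (m - l + 1) * math.log1p(-p)
        q = -math.expm1(log_one_minus_q)
        if q <= 0.0:
            E = 0.0
        else:
            E = math.exp(l * math.log(sigma) + n * math.log(q))
    return ExpectationModel(sigma=sigma, l=l, d=d, m=m, n=n, N=N, p=p, q=q, E=E)


def expected_spurious_motifs(n: int, m: int, l: int, d: int, sigma: int = 4) -> float:
    """E = σ^l · q(m,σ,l,d)^n, the expected spurious-motif count."""
    return expectation_model(n, m, l, d, sigma).E


def smallest_challenging_d(
    l: int, n: int = 20, m: int = 600, alphabet: Alphabet | int = DNA
) -> int:
    """Smallest d with expected spurious-motif count ≥ 1.

    Defaults to the standard benchmark shape (20 strings of length
    600). d = l always qualifies, so the scan terminates.
    """
    sigma = alphabet if isinstance(alphabet, int) else alphabet.size
    for d in range(l + 1):
        if expected_spurious_motifs(n, m, l, d, sigma) >= 1.0:
            return d
    return l  # unreachable: d = l gives E = sigma**l >= 1
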