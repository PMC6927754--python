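"""Independent brute-force oracles used only by the tests.

The hypergeometric tail is computed by exhaustively enumerating every
placement of a gene's n guides among N ranks with exact rational
arithmetic — no shared code with the package's gammaln-based
implementation.
"""

from __future__ import annotations

import math
from fractions import Fraction
from functools import lru_cache
from itertools import combinations


@lru_cache(maxsize=None)
def tail_prob_enum(N: int, n: int, r: int, i: int) -> Fraction:
    """P(at least i of the gene's n guides land in the top r of N ranks).

    Exact Fraction, by enumerating all C(N, n) equally likely placements.
    """
    hits = total = 0
    for subset in combinations(range(1, N + 1), n):
        total += 1
        if sum(1 for rank in subset if rank <= r) >= i:
            hits += 1
    return Fraction(hits, total)


def rsa_logp_enum(ranks, N: int) -> float:
    """RSA log10 P via the enumeration oracle: min tail over cutoffs."""
    ordered = sorted(ranks)
    n = len(ordered)
    best = min(tail_prob_enum(N, n, r, i) for i, r in enumerate(ordered, start=1))
    return math.log10(best)
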