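"""Independent brute-force oracles used across the test suite.

These deliberately avoid the implementation's code paths: the motif oracle
slides a window and compares characters; the enrichment oracle sums exact
binomial-coefficient ratios (equivalently, enumerates all draws)."""

from __future__ import annotations

from fractions import Fraction
from math import comb

CARG_PATTERNS = {
    "AT6": ("CC", 6, "GG"),
    "AT5": ("CC", 5, "GG"),
}


def brute_force_carg(sequence: str, variants=("AT6", "AT5")) -> list[tuple[int, str]]:
    """All (position, variant) CArG matches by explicit character comparison."""
    seq = sequence.upper()
    hits: list[tuple[int, str]] = []
    for name in variants:
        head, n_wobble, tail = CARG_PATTERNS[name]
        length = len(head) + n_wobble + len(tail)
        for i in range(len(seq) - length + 1):
            window = seq[i : i + length]
            if (
                window.startswith(head)
                and window.endswith(tail)
                and all(c in "AT" for c in window[2 : 2 + n_wobble])
            ):
                hits.append((i, name))
    hits.sort()
    return hits


def hypergeom_upper_tail_exact(k: int, K: int, n: int, N: int) -> Fraction:
    """P(X >= k) for X ~ Hypergeometric(N, K, n), as an exact fraction.

    Equivalent to enumerating all C(N, n) draws of n genes from the universe
    and counting those sharing >= k genes with the K-set.
    """
    total = comb(N, n)
    favorable = sum(
        comb(K, j) * comb(N - K, n - j)
        for j in range(max(k, 0), min(K, n) + 1)
    )
    return Fraction(favorable, total)
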