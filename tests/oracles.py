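"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's dynamic programs: structures are
produced by exhaustive recursive enumeration and scored one by one, and the
hypergeometric tail is summed term by term from binomial coefficients.
"""

from functools import lru_cache
from math import comb

from mirsnp.fold.pairs import MIN_HAIRPIN_LOOP, can_pair


def enumerate_structures(seq: str):
    """All valid secondary structures (pair sets) of a short RNA."""
    n = len(seq)

    @lru_cache(maxsize=None)
    def rec(i: int, j: int):
        if j - i < MIN_HAIRPIN_LOOP + 1:
            return (frozenset(),)
        out = list(rec(i + 1, j))
        for k in range(i + MIN_HAIRPIN_LOOP + 1, j + 1):
            if can_pair(seq[i], seq[k]):
                for a in rec(i + 1, k - 1):
                    for b in rec(k + 1, j):
                        out.append(a | b | {(i, k)})
        return tuple(out)

    return rec(0, n - 1)


def hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) by explicit combinatorial summation."""
    denom = comb(N, n)
    return sum(comb(K, x) * comb(N - K, n - x) for x in range(k, min(K, n) + 1)) / denom
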