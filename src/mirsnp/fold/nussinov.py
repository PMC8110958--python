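"""Base-pair-maximization folding (Nussinov-style dynamic program).

Intended as a teaching/oracle engine: the "energy" it reports is the negated
pair count (pseudo-energy), not kcal/mol. Co-optimal structures are resolved
deterministically by preferring to pair the 5'-most base, then the
shortest-range partner.
"""

from __future__ import annotations

from .pairs import MIN_HAIRPIN_LOOP, can_pair


def max_pairs(seq: str) -> tuple[int, frozenset]:
    """Return (number of pairs, pair set) of a maximum-pairing structure."""
    n = len(seq)
    N = [[0] * n for _ in range(n)]
    for span in range(MIN_HAIRPIN_LOOP + 1, n):
        for i in range(n - span):
            j = i + span
            best = N[i + 1][j]  # i unpaired
            for k in range(i + MIN_HAIRPIN_LOOP + 1, j + 1):
                if can_pair(seq[i], seq[k]):
                    inner = N[i + 1][k - 1] if k - i > MIN_HAIRPIN_LOOP + 1 else 0
                    right = N[k + 1][j] if k + 1 <= j else 0
                    best = max(best, 1 + inner + right)
            N[i][j] = best

    pairs = set()

    def trace(i: int, j: int) -> None:
        while i < j:
            if j - i <= MIN_HAIRPIN_LOOP or N[i][j] == 0:
                return
            target = N[i][j]
            # prefer pairing the 5'-most base i, with the closest partner k
            paired = False
            for k in range(i + MIN_HAIRPIN_LOOP + 1, j + 1):
                if not can_pair(seq[i], seq[k]):
                    continue
                inner = N[i + 1][k - 1] if k - i > MIN_HAIRPIN_LOOP + 1 else 0
                right = N[k + 1][j] if k + 1 <= j else 0
                if 1 + inner + right == target:
                    pairs.add((i, k))
                    trace(i + 1, k - 1)
                    i = k + 1
                    paired = True
                    break
            if not paired:
                i += 1

    trace(0, n - 1)
    assert len(pairs) == N[0][n - 1]
    return N[0][n - 1], frozenset(pairs)
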