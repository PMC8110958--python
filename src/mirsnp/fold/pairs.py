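"""Base-pair rules and dot-bracket utilities shared by all fold engines."""

from __future__ import annotations

RNA_ALPHABET = frozenset("ACGU")

#: Watson-Crick plus G.U wobble pairs, as (5' base, 3' base).
CANONICAL_PAIRS = frozenset(
    {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}
)

#: Minimum number of unpaired bases in a hairpin loop.
MIN_HAIRPIN_LOOP = 3


def validate_rna(seq: str) -> str:
    seq = seq.upper()
    bad = set(seq) - RNA_ALPHABET
    if bad:
        raise ValueError(f"invalid RNA characters: {sorted(bad)}")
    return seq


def can_pair(a: str, b: str) -> bool:
    return (a, b) in CANONICAL_PAIRS


def pairs_to_dotbracket(n: int, pairs) -> str:
    chars = ["."] * n
    for i, j in pairs:
        chars[i] = "("
        chars[j] = ")"
    return "".join(chars)


def dotbracket_to_pairs(structure: str) -> frozenset:
    stack: list[int] = []
    pairs = set()
    for i, c in enumerate(structure):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise ValueError("unbalanced dot-bracket string")
            pairs.add((stack.pop(), i))
        elif c != ".":
            raise ValueError(f"invalid dot-bracket character {c!r}")
    if stack:
        raise ValueError("unbalanced dot-bracket string")
    return frozenset(pairs)


def check_structure(seq: str, structure: str) -> frozenset:
    """Validate a dot-bracket structure against a sequence; return its pairs."""
    if len(structure) != len(seq):
        raise ValueError("structure/sequence length mismatch")
    pairs = dotbracket_to_pairs(structure)
    for i, j in pairs:
        if j - i <= MIN_HAIRPIN_LOOP:
            raise ValueError(f"hairpin loop below minimum at pair ({i},{j})")
        if not can_pair(seq[i], seq[j]):
            raise ValueError(f"non-canonical pair {seq[i]}{seq[j]} at ({i},{j})")
    return pairs
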