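"""Small DNA-string helpers shared across modules.

Sequences are plain upper-case Python strings over {A, C, G, T, N}.
``N`` never matches anything, including another ``N``.
"""

from __future__ import annotations

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

DNA_ALPHABET = frozenset("ACGT")


def clean_sequence(seq: str) -> str:
    """Upper-case *seq* and map every letter outside {A,C,G,T} to N."""
    seq = seq.upper()
    if set(seq) <= DNA_ALPHABET:
        return seq
    return "".join(c if c in DNA_ALPHABET else "N" for c in seq)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def rotate(seq: str, k: int) -> str:
    """Cyclic rotation: ``rotate("ABCD", 1) == "BCDA"``."""
    if not seq:
        return seq
    k %= len(seq)
    return seq[k:] + seq[:k]


def identity(a: str, b: str) -> float:
    """Ungapped position-wise identity of two equal-length strings.

    N counts as a mismatch against everything.
    """
    if len(a) != len(b):
        raise ValueError("identity() requires equal-length sequences")
    if not a:
        return 0.0
    m = sum(1 for x, y in zip(a, b) if x == y and x != "N")
    return m / len(a)
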