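"""Alphabets and base-pair complementarity.

Two alphabets are supported: the standard 4-letter nucleic-acid alphabet
``{A, C, G, U}`` with Watson-Crick pairs (A·U, C·G), and an abstract 8-letter
alphabet ``{A, C, G, U, P, Q, X, Y}`` that adds two synthetic complementary
pairs (P·Q, X·Y).  G·U wobble pairs are deliberately *not* complementary in
either alphabet: the abstract energy models used throughout this package admit
exactly the listed pairs and nothing else.
"""

from __future__ import annotations

EIGHT_LETTER = "ACGUPQXY"
FOUR_LETTER = "ACGU"

#: complement partner of each symbol (symmetric)
COMPLEMENT = {
    "A": "U", "U": "A",
    "C": "G", "G": "C",
    "P": "Q", "Q": "P",
    "X": "Y", "Y": "X",
}

#: unordered complementary pairs per alphabet tag
_PAIRS = {
    "eight": {frozenset(p) for p in ("AU", "CG", "PQ", "XY")},
    "four": {frozenset(p) for p in ("AU", "CG")},
}

_SYMBOLS = {"eight": set(EIGHT_LETTER), "four": set(FOUR_LETTER)}


def symbols(alphabet: str) -> set[str]:
    """Allowed symbols for an alphabet tag (``"four"`` or ``"eight"``)."""
    try:
        return _SYMBOLS[alphabet]
    except KeyError:
        raise ValueError(f"unknown alphabet {alphabet!r}") from None


def complementary(a: str, b: str, alphabet: str = "eight") -> bool:
    """True iff symbols *a* and *b* may pair under the given alphabet."""
    return frozenset((a, b)) in _PAIRS[alphabet]


def check_symbols(seq: str, alphabet: str) -> None:
    """Raise ``ValueError`` on the first symbol not in the alphabet."""
    allowed = symbols(alphabet)
    for i, ch in enumerate(seq):
        if ch not in allowed:
            raise ValueError(
                f"symbol {ch!r} at position {i} not in {alphabet}-letter alphabet"
            )
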