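"""Pseudoknot-free secondary structures: data model, validation, dot-bracket I/O.

A secondary structure over a sequence of length *n* is a set of *arcs*
(base pairs) ``(i, j)`` with ``0 <= i < j < n`` such that

* each position belongs to at most one arc,
* no two arcs cross (``i < i' < j < j'`` is forbidden), and
* paired symbols are complementary under the active alphabet.

The structure-level energy functionals are the arc count ``AC`` and the
stacked-pair count ``SAC`` (number of index pairs where both ``(i, j)`` and
``(i+1, j-1)`` are arcs).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

from .alphabet import complementary

Arc = tuple[int, int]


@dataclass(frozen=True)
class Violation:
    """A single validation failure: which rule broke and the offending arcs."""

    rule: str  # one of: range, duplicate-endpoint, crossing, complementarity
    arcs: tuple[Arc, ...]
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.rule}: {self.message}"


@dataclass(frozen=True)
class SecondaryStructure:
    """An immutable set of arcs over a sequence of length ``n``.

    Arcs are stored sorted by left endpoint so that equality and diffing are
    deterministic.
    """

    n: int
    arcs: tuple[Arc, ...] = ()
    _pair: dict = field(init=False, repr=False, compare=False, hash=False)

    def __post_init__(self) -> None:
        ordered = tuple(sorted((min(a), max(a)) for a in self.arcs))
        object.__setattr__(self, "arcs", ordered)
        pair: dict[int, int] = {}
        for i, j in ordered:
            pair[i] = j
            pair[j] = i
        object.__setattr__(self, "_pair", pair)

    # -- basic counts -----------------------------------------------------

    def arc_count(self) -> int:
        """AC: the number of arcs."""
        return len(self.arcs)

    def stacked_pair_count(self) -> int:
        """SAC: pairs of consecutive arcs ``(i, j)`` and ``(i+1, j-1)``."""
        # the inner partner must be a distinct arc, so j - i >= 3
        return sum(1 for i, j in self.arcs
                   if j - i >= 3 and self._pair.get(i + 1) == j - 1)

    # -- queries ----------------------------------------------------------

    def partner(self, i: int) -> int | None:
        return self._pair.get(i)

    def is_paired(self, i: int) -> bool:
        return i in self._pair

    def has_arc(self, arc: Arc) -> bool:
        i, j = min(arc), max(arc)
        return self._pair.get(i) == j

    def arc_set(self) -> frozenset[Arc]:
        return frozenset(self.arcs)

    # -- single-arc moves -------------------------------------------------

    def with_arc(self, arc: Arc) -> "SecondaryStructure":
        i, j = min(arc), max(arc)
        if i in self._pair or j in self._pair:
            raise ValueError(f"endpoint of arc ({i},{j}) already paired")
        return SecondaryStructure(self.n, self.arcs + ((i, j),))

    def without_arc(self, arc: Arc) -> "SecondaryStructure":
        i, j = min(arc), max(arc)
        if self._pair.get(i) != j:
            raise ValueError(f"arc ({i},{j}) not present")
        return SecondaryStructure(self.n, tuple(a for a in self.arcs if a != (i, j)))

    def crosses(self, arc: Arc) -> bool:
        """Would adding *arc* cross an existing arc?"""
        i, j = min(arc), max(arc)
        for a, b in self.arcs:
            if (a < i < b < j) or (i < a < j < b):
                return True
        return False

    def __iter__(self) -> Iterator[Arc]:
        return iter(self.arcs)

    def __len__(self) -> int:
        return len(self.arcs)


def validate(structure: SecondaryStructure, sequence, alphabet: str | None = None) -> list[Violation]:
    """Check the three structural invariants; return [] iff all hold.

    *sequence* may be a plain string or a :class:`~switchlock.design.Sequence`;
    in the latter case its alphabet tag is used unless *alphabet* overrides it.
    Out-of-range indices are reported as violations, not raised.
    """
    if hasattr(sequence, "symbols"):
        seq = sequence.symbols
        alphabet = alphabet or sequence.alphabet
    else:
        seq = sequence
        alphabet = alphabet or "four"

    out: list[Violation] = []
    n = len(seq)
    seen: dict[int, Arc] = {}
    for arc in structure.arcs:
        i, j = arc
        if not (0 <= i < j < n):
            out.append(Violation("range", (arc,), f"arc {arc} outside [0,{n})"))
            continue
        for e in (i, j):
            if e in seen and seen[e] != arc:
                out.append(
                    Violation("duplicate-endpoint", (seen[e], arc),
                              f"position {e} in arcs {seen[e]} and {arc}")
                )
            seen[e] = arc
        if not complementary(seq[i], seq[j], alphabet):
            out.append(
                Violation("complementarity", (arc,),
                          f"{seq[i]}·{seq[j]} at {arc} is not a complementary pair")
            )
    arcs = structure.arcs
    for a in range(len(arcs)):
        i, j = arcs[a]
        for b in range(a + 1, len(arcs)):
            p, q = arcs[b]
            if p > j:
                break  # sorted by left endpoint: no later arc can cross (i,j)
            if i < p < j < q:
                out.append(
                    Violation("crossing", (arcs[a], arcs[b]),
                              f"arcs {arcs[a]} and {arcs[b]} cross")
                )
    return out


# -- dot-bracket ----------------------------------------------------------
# Only '.', '(' and ')' are used: the model forbids pseudoknots, so no
# extra bracket families are needed.


def to_dot_bracket(structure: SecondaryStructure) -> str:
    chars = ["."] * structure.n
    for i, j in structure.arcs:
        chars[i] = "("
        chars[j] = ")"
    return "".join(chars)


def from_dot_bracket(text: str, n: int | None = None) -> SecondaryStructure:
    """Parse one dot-bracket line; reject unbalanced input."""
    text = text.strip()
    if n is not None and len(text) != n:
        raise ValueError(f"dot-bracket length {len(text)} != sequence length {n}")
    stack: list[int] = []
    arcs: list[Arc] = []
    for pos, ch in enumerate(text):
        if ch == "(":
            stack.append(pos)
        elif ch == ")":
            if not stack:
                raise ValueError(f"unbalanced ')' at position {pos}")
            arcs.append((stack.pop(), pos))
        elif ch != ".":
            raise ValueError(f"unexpected character {ch!r} at position {pos}")
    if stack:
        raise ValueError(f"unbalanced '(' at position {stack[-1]}")
    return SecondaryStructure(len(text), tuple(arcs))


def read_structure_file(path) -> tuple[str, list[SecondaryStructure]]:
    """Read a dot-bracket file: line 1 sequence, then one structure per line."""
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip() and not ln.startswith(">")]
    if not lines:
        raise ValueError(f"{path}: empty structure file")
    seq, structs = lines[0], lines[1:]
    return seq, [from_dot_bracket(s, len(seq)) for s in structs]


def write_structure_file(path, sequence: str, structures: Iterable[SecondaryStructure]) -> None:
    with open(path, "w") as fh:
        fh.write(sequence + "\n")
        for s in structures:
            fh.write(to_dot_bracket(s) + "\n")
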