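"""Switch-lock sequence families, region decompositions, initial/target structures.

The designs are parameterised by a band width ``k``, an even number of switch
bands ``A`` and an even number of lock bands ``B``.  The *switch* is the first
half of the molecule: ``A`` alternating G/U and C/A regions of width ``k``
whose bands can sit in a "left" or a "right" position.  The *lock* is the
second half: ``B`` bands of wide center arcs (l·r) that are removed along the
designed pathway and replaced by x·y and p·q bands.

Two flavours exist:

* the 8-letter design ``switch-lock(k, A, B)`` (length ``2kA + 8kB``), whose
  synthetic symbols P, Q, X, Y form two extra complementary pairs; and
* the 4-letter design ``switch-lock'(k, A, B)`` (length ``2kA + (8k+6)B``,
  ``k`` even), where the synthetic regions become alternating-dinucleotide
  runs of width ``k+1`` and the center regions widen to ``2k+1``.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field

from .alphabet import check_symbols
from .structure import Arc, SecondaryStructure

__all__ = [
    "DesignParams", "Sequence", "Region", "RegionMap",
    "build_switch", "build_lock", "build_switch_lock",
    "build_switch_lock_prime", "initial_structure", "target_structure",
    "region_map_of", "write_fasta", "read_fasta",
]

ALPHABETS = ("eight_letter", "four_letter_mapped", "four_letter_prime")


class ParameterError(ValueError):
    """Invalid design parameters (odd A/B, k < 1, ...)."""


@dataclass(frozen=True)
class DesignParams:
    """The design triple (k, A, B) plus the alphabet flavour."""

    k: int
    A: int
    B: int
    alphabet: str = "eight_letter"

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ParameterError(f"k must be >= 1, got {self.k}")
        if self.A < 2 or self.A % 2:
            raise ParameterError(f"A must be a positive even integer, got {self.A}")
        if self.B < 2 or self.B % 2:
            raise ParameterError(f"B must be a positive even integer, got {self.B}")
        if self.alphabet not in ALPHABETS:
            raise ParameterError(f"alphabet must be one of {ALPHABETS}")
        if self.alphabet == "four_letter_prime" and self.k % 2:
            raise ParameterError("the 4-letter prime design requires even k")

    @property
    def length(self) -> int:
        if self.alphabet == "four_letter_prime":
            return 2 * self.k * self.A + (8 * self.k + 6) * self.B
        return 2 * self.k * self.A + 8 * self.k * self.B


@dataclass(frozen=True)
class Sequence:
    """A sequence with an alphabet tag (``"eight"`` or ``"four"``)."""

    symbols: str
    alphabet: str = "eight"

    def __post_init__(self) -> None:
        check_symbols(self.symbols, self.alphabet)

    def __len__(self) -> int:
        return len(self.symbols)

    def __getitem__(self, i):
        return self.symbols[i]


@dataclass(frozen=True)
class Region:
    """A labeled contiguous block: design symbol + half-open span.

    ``kind`` is one of L, R (switch) and x, l, y, p, r, q (lock); ``index`` is
    the band number (1-based).  ``symbol`` is the *design* (8-letter) symbol
    of the region even when the realised sequence is 4-letter.
    """

    kind: str
    index: int
    symbol: str
    start: int
    end: int  # exclusive

    @property
    def label(self) -> str:
        return f"{self.kind}{self.index}"

    @property
    def width(self) -> int:
        return self.end - self.start

    def base(self, i: int) -> int:
        """Absolute position of the i-th base (1-based).

        Counted from the left for L/l/x/y/p/q regions and from the *right*
        for R and r regions, matching the convention that R_{a,i} / r_{a,i}
        is the i-th rightmost base.
        """
        if not 1 <= i <= self.width:
            raise IndexError(f"base {i} outside region {self.label} of width {self.width}")
        if self.kind in ("R", "r"):
            return self.end - i
        return self.start + i - 1


@dataclass(frozen=True)
class RegionMap:
    """The ordered decomposition of a designed sequence into labeled regions."""

    regions: tuple[Region, ...]
    _starts: tuple[int, ...] = field(init=False, repr=False, compare=False)
    _by_label: dict = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "_starts", tuple(r.start for r in self.regions))
        object.__setattr__(self, "_by_label", {r.label: r for r in self.regions})

    def __iter__(self):
        return iter(self.regions)

    def __len__(self) -> int:
        return len(self.regions)

    def __getitem__(self, label: str) -> Region:
        return self._by_label[label]

    def region_at(self, pos: int) -> Region:
        """The region containing absolute position *pos*."""
        idx = bisect.bisect_right(self._starts, pos) - 1
        r = self.regions[idx]
        if not (r.start <= pos < r.end):
            raise IndexError(f"position {pos} outside the region map")
        return r

    def length(self) -> int:
        return self.regions[-1].end

    def tiles(self) -> bool:
        """True iff regions tile [0, n) with no gaps or overlaps."""
        pos = 0
        for r in self.regions:
            if r.start != pos or r.end <= r.start:
                return False
            pos = r.end
        return True


# -- 8-letter family ------------------------------------------------------


def build_switch(k: int, A: int) -> Sequence:
    """The switch ``(G^k U^k)^{A/2} (C^k A^k)^{A/2}`` of length 2kA."""
    _check(k=k, A=A)
    s = ("G" * k + "U" * k) * (A // 2) + ("C" * k + "A" * k) * (A // 2)
    return Sequence(s, "eight")


def build_lock(k: int, B: int) -> Sequence:
    """The lock ``(X^k)^B (C^2k Y^k A^2k Y^k)^{B/2} (P^k U^2k P^k G^2k)^{B/2} (Q^k)^B``."""
    _check(k=k, B=B)
    s = (
        "X" * (k * B)
        + ("C" * (2 * k) + "Y" * k + "A" * (2 * k) + "Y" * k) * (B // 2)
        + ("P" * k + "U" * (2 * k) + "P" * k + "G" * (2 * k)) * (B // 2)
        + "Q" * (k * B)
    )
    return Sequence(s, "eight")


def _check(k: int = 1, A: int = 2, B: int = 2) -> None:
    if k < 1:
        raise ParameterError(f"k must be >= 1, got {k}")
    if A < 2 or A % 2:
        raise ParameterError(f"A must be a positive even integer, got {A}")
    if B < 2 or B % 2:
        raise ParameterError(f"B must be a positive even integer, got {B}")


def _switch_regions(k: int, A: int) -> list[Region]:
    regs = []
    pos = 0
    # left half: L_1 .. L_A, alternating G/U
    for a in range(1, A + 1):
        sym = "G" if a % 2 else "U"
        regs.append(Region("L", a, sym, pos, pos + k))
        pos += k
    # right half: R_A .. R_1 left-to-right, alternating C/A
    for a in range(A, 0, -1):
        sym = "C" if a % 2 == A % 2 else "A"
        # R_A is C^k; parity alternates moving right
        regs.append(Region("R", a, sym, pos, pos + k))
        pos += k
    return regs


def _lock_regions(k: int, B: int, *, prime: bool = False) -> list[Region]:
    """Region layout of the lock; widths differ between the two flavours."""
    wx = k + 1 if prime else k       # x, y, p, q regions
    wl = 2 * k + 1 if prime else 2 * k  # l, r regions
    regs = []
    pos = 0
    for i in range(B, 0, -1):  # x_B .. x_1
        regs.append(Region("x", i, "X", pos, pos + wx))
        pos += wx
    for i in range(1, B + 1):  # l_1 y_1 .. l_B y_B
        lsym = "C" if i % 2 else "A"
        regs.append(Region("l", i, lsym, pos, pos + wl))
        pos += wl
        regs.append(Region("y", i, "Y", pos, pos + wx))
        pos += wx
    for i in range(B, 0, -1):  # p_B r_B .. p_1 r_1
        rsym = "G" if i % 2 else "U"
        regs.append(Region("p", i, "P", pos, pos + wx))
        pos += wx
        regs.append(Region("r", i, rsym, pos, pos + wl))
        pos += wl
    for i in range(1, B + 1):  # q_1 .. q_B
        regs.append(Region("q", i, "Q", pos, pos + wx))
        pos += wx
    return regs


def build_switch_lock(params: DesignParams) -> tuple[Sequence, RegionMap]:
    """Concatenated switch+lock with its region decomposition (8-letter)."""
    if params.alphabet != "eight_letter":
        raise ParameterError("build_switch_lock requires the eight_letter alphabet")
    k, A, B = params.k, params.A, params.B
    seq = Sequence(build_switch(k, A).symbols + build_lock(k, B).symbols, "eight")
    regs = _switch_regions(k, A)
    off = 2 * k * A
    regs += [
        Region(r.kind, r.index, r.symbol, r.start + off, r.end + off)
        for r in _lock_regions(k, B)
    ]
    rmap = RegionMap(tuple(regs))
    assert rmap.length() == params.length
    return seq, rmap


# -- 4-letter prime family ------------------------------------------------

# Realised content of the synthetic lock regions in the prime design: the
# X/Y/P/Q band sequences are alternating dinucleotide runs so that only the
# intended partners can form stable stacks.
_PRIME_FILL = {"X": "CA", "Y": "GU", "P": "AG", "Q": "UC"}


def _alternating(pair: str, width: int) -> str:
    return (pair * width)[:width]


def build_switch_lock_prime(params: DesignParams) -> tuple[Sequence, RegionMap]:
    """The 4-letter design: switch unchanged, lock mapped to ACGU."""
    if params.alphabet != "four_letter_prime":
        raise ParameterError("build_switch_lock_prime requires the four_letter_prime alphabet")
    k, A, B = params.k, params.A, params.B
    regs = _switch_regions(k, A)
    off = 2 * k * A
    regs += [
        Region(r.kind, r.index, r.symbol, r.start + off, r.end + off)
        for r in _lock_regions(k, B, prime=True)
    ]
    chunks = []
    for r in regs:
        if r.symbol in _PRIME_FILL:
            chunks.append(_alternating(_PRIME_FILL[r.symbol], r.width))
        else:
            chunks.append(r.symbol * r.width)
    rmap = RegionMap(tuple(regs))
    seq = Sequence("".join(chunks), "four")
    assert len(seq) == params.length == rmap.length()
    return seq, rmap


def region_map_of(params: DesignParams) -> tuple[Sequence, RegionMap]:
    """Dispatch on the alphabet flavour."""
    if params.alphabet == "four_letter_prime":
        return build_switch_lock_prime(params)
    return build_switch_lock(params)


# -- initial and target structures ----------------------------------------


def band_arcs(u: Region, v: Region, count: int) -> list[Arc]:
    """*count* maximally nested arcs pairing region *u* against region *v*.

    Arc t (1-based, outermost first) joins u's t-th leftmost base to v's t-th
    rightmost base; *u* must lie left of *v*.
    """
    if u.start > v.start:
        u, v = v, u
    if count > min(u.width, v.width):
        raise ValueError(f"band of {count} arcs does not fit {u.label}·{v.label}")
    return [(u.start + t, v.end - 1 - t) for t in range(count)]


def _band_widths(params: DesignParams) -> tuple[int, int]:
    """(center band width, replacement band width)."""
    if params.alphabet == "four_letter_prime":
        return 2 * params.k + 1, params.k + 1
    return 2 * params.k, params.k


def initial_structure(params: DesignParams) -> SecondaryStructure:
    """Switch in the left position; all B center bands of the lock formed."""
    _, rmap = region_map_of(params)
    k, A, B = params.k, params.A, params.B
    wc, _ = _band_widths(params)
    arcs: list[Arc] = []
    for i in range(1, A):
        arcs += band_arcs(rmap[f"L{i}"], rmap[f"R{i + 1}"], k)
    for i in range(1, B + 1):
        arcs += band_arcs(rmap[f"l{i}"], rmap[f"r{i}"], wc)
    return SecondaryStructure(rmap.length(), tuple(arcs))


def target_structure(params: DesignParams) -> SecondaryStructure:
    """Switch in the right position; lock bands replaced by x·y and p·q."""
    _, rmap = region_map_of(params)
    k, A, B = params.k, params.A, params.B
    _, wr = _band_widths(params)
    arcs: list[Arc] = []
    for i in range(1, A):
        arcs += band_arcs(rmap[f"L{i + 1}"], rmap[f"R{i}"], k)
    for i in range(1, B + 1):
        arcs += band_arcs(rmap[f"x{i}"], rmap[f"y{i}"], wr)
        arcs += band_arcs(rmap[f"p{i}"], rmap[f"q{i}"], wr)
    return SecondaryStructure(rmap.length(), tuple(arcs))


# -- FASTA-like I/O --------------------------------------------------------
# The 8-letter symbols P, Q, X, Y are emitted verbatim; the header carries an
# explicit alphabet tag so tooling can tell the flavours apart.


def write_fasta(path, seq: Sequence, name: str = "switchlock") -> None:
    tag = 8 if seq.alphabet == "eight" else 4
    with open(path, "w") as fh:
        fh.write(f">{name} alphabet={tag}\n{seq.symbols}\n")


def read_fasta(path) -> Sequence:
    header, chunks = "", []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                header = line
            else:
                chunks.append(line)
    symbols = "".join(chunks)
    if "alphabet=8" in header or any(c in "PQXY" for c in symbols):
        return Sequence(symbols, "eight")
    return Sequence(symbols, "four")
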