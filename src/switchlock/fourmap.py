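"""The 8->4 letter sequence map, the structure map Map', and eccentricity.

``map_sequence`` widens every region of an 8-letter sequence by one base:
A/C/G/U regions ``u^m`` become ``u^{m+1}``, while the synthetic P/Q/X/Y
regions become alternating runs AG.., UC.., CA.., GU.. of width m+1.  The
mapped X and Y (and P and Q) runs are reverse-complementary over ACGU, so a
whole band of the 8-letter design survives as a stackable helix, but any
*other* pairing involving a synthetic region can only form isolated, poorly
stacking arcs.

An arc of a structure over the mapped sequence is *eccentric* if its two home
regions are not complementary in the 8-letter view.  A stacked arc pair is
eccentric under the

* ``generic`` dialect: if it straddles a region boundary on either side, or
  contains an eccentric arc;
* ``prime`` dialect (default for switch-lock' inputs): only if it contains an
  eccentric arc — boundary-to-boundary stacks inside the switch are the
  design's own helix junctions and are not penalised.

``map_structure`` (Map') converts each non-eccentric stacked pair of a
4-letter structure S' into one arc of an 8-letter structure S, giving the
identity  AC(Map'(S')) = SAC(S') - E,  where E is the number of eccentric
stacked pairs.  At most r - 1 stacked pairs can be eccentric under the
generic dialect (one per region boundary).
"""

from __future__ import annotations

from dataclasses import dataclass

from .alphabet import complementary
from .design import DesignParams, Region, RegionMap, Sequence, \
    build_switch_lock, build_switch_lock_prime
from .structure import Arc, SecondaryStructure

__all__ = [
    "SequenceMapping", "EccentricityReport", "map_sequence",
    "classify_arc", "classify_stack", "map_structure", "eccentricity_report",
]

_ALTERNATING = {"P": "AG", "Q": "UC", "X": "CA", "Y": "GU"}


@dataclass(frozen=True)
class MappedRegion:
    """One region seen in both coordinate systems."""

    symbol: str           # the 8-letter design symbol
    kind: str
    index: int
    start8: int
    end8: int
    start4: int
    end4: int
    in_switch: bool

    @property
    def label(self) -> str:
        return f"{self.kind}{self.index}"


@dataclass(frozen=True)
class SequenceMapping:
    """A mapped sequence with the region correspondence needed by Map'."""

    seq8: Sequence
    seq4: Sequence
    regions: tuple[MappedRegion, ...]
    dialect: str  # default eccentricity dialect for this mapping

    def region_at4(self, pos: int) -> MappedRegion:
        for r in self.regions:  # few regions; linear scan is fine
            if r.start4 <= pos < r.end4:
                return r
        raise IndexError(f"position {pos} outside mapped sequence")

    @property
    def region_count(self) -> int:
        return len(self.regions)


def _regions_of(seq8: Sequence) -> list[Region]:
    """Maximal runs of identical symbols, labeled generically."""
    regs: list[Region] = []
    s = seq8.symbols
    start = 0
    for i in range(1, len(s) + 1):
        if i == len(s) or s[i] != s[start]:
            regs.append(Region("u", len(regs) + 1, s[start], start, i))
            start = i
    return regs


def map_sequence(seq8: Sequence, rmap: RegionMap | None = None) -> SequenceMapping:
    """The generic map(): every region widens by one base (length n + r)."""
    regs = list(rmap) if rmap is not None else _regions_of(seq8)
    mapped: list[MappedRegion] = []
    chunks: list[str] = []
    pos4 = 0
    for r in regs:
        w4 = r.width + 1
        if r.symbol in _ALTERNATING:
            pair = _ALTERNATING[r.symbol]
            chunks.append((pair * w4)[:w4])
        else:
            chunks.append(r.symbol * w4)
        mapped.append(MappedRegion(r.symbol, r.kind, r.index, r.start, r.end,
                                   pos4, pos4 + w4, in_switch=False))
        pos4 += w4
    return SequenceMapping(seq8, Sequence("".join(chunks), "four"),
                           tuple(mapped), dialect="generic")


def prime_mapping(params: DesignParams) -> SequenceMapping:
    """Region correspondence between switch-lock(k,A,B) and switch-lock'.

    The switch is left unchanged (regions keep width k); only the lock
    regions widen by one.
    """
    base = DesignParams(params.k, params.A, params.B, "eight_letter")
    prime = DesignParams(params.k, params.A, params.B, "four_letter_prime")
    seq8, rmap8 = build_switch_lock(base)
    seq4, rmap4 = build_switch_lock_prime(prime)
    mapped = []
    for r8, r4 in zip(rmap8, rmap4):
        assert (r8.kind, r8.index) == (r4.kind, r4.index)
        mapped.append(MappedRegion(r8.symbol, r8.kind, r8.index,
                                   r8.start, r8.end, r4.start, r4.end,
                                   in_switch=r8.kind in ("L", "R")))
    return SequenceMapping(seq8, seq4, tuple(mapped), dialect="prime")


# -- eccentricity ----------------------------------------------------------


def classify_arc(arc: Arc, mapping: SequenceMapping) -> str:
    """``"eccentric"`` iff the home regions are not 8-letter complementary."""
    u = mapping.region_at4(arc[0])
    v = mapping.region_at4(arc[1])
    return "normal" if complementary(u.symbol, v.symbol, "eight") else "eccentric"


def classify_stack(stack: Arc, mapping: SequenceMapping,
                   dialect: str | None = None) -> str:
    """Classify the stacked pair whose outer arc is ``stack = (i, j)``."""
    dialect = dialect or mapping.dialect
    i, j = stack
    outer_ecc = classify_arc((i, j), mapping) == "eccentric"
    inner_ecc = classify_arc((i + 1, j - 1), mapping) == "eccentric"
    if outer_ecc or inner_ecc:
        return "eccentric"
    if dialect == "prime":
        return "normal"
    if dialect != "generic":
        raise ValueError(f"unknown dialect {dialect!r}")
    left_boundary = mapping.region_at4(i) is not mapping.region_at4(i + 1)
    right_boundary = mapping.region_at4(j - 1) is not mapping.region_at4(j)
    return "eccentric" if left_boundary or right_boundary else "normal"


def _stacks(structure: SecondaryStructure) -> list[Arc]:
    """Outer arcs (i, j) such that (i+1, j-1) is also an arc."""
    return [(i, j) for i, j in structure.arcs
            if j - i >= 3 and structure.partner(i + 1) == j - 1]


@dataclass(frozen=True)
class EccentricityReport:
    """Eccentric-stack census of one structure over a mapped sequence."""

    eccentric_stacks: tuple[Arc, ...]
    E: int
    r: int
    dialect: str

    @property
    def bound_holds(self) -> bool:
        """E <= r - 1 (each eccentric stack uses up one region boundary)."""
        return self.E <= self.r - 1


def eccentricity_report(structure: SecondaryStructure, mapping: SequenceMapping,
                        dialect: str | None = None) -> EccentricityReport:
    dialect = dialect or mapping.dialect
    ecc = tuple(s for s in _stacks(structure)
                if classify_stack(s, mapping, dialect) == "eccentric")
    return EccentricityReport(ecc, len(ecc), mapping.region_count, dialect)


# -- Map' ------------------------------------------------------------------


def map_structure(structure4: SecondaryStructure, mapping: SequenceMapping,
                  dialect: str | None = None) -> SecondaryStructure:
    """Map' : each non-eccentric stacked pair becomes one 8-letter arc.

    Let the outer arc of a non-eccentric stack join the i-th position of
    region u to the j-th position of region v (1-based, from the left).  The
    produced arc joins u's i-th base to v's (j-1)-th base; under the prime
    dialect, to v's j-th base when v lies in the (unwidened) switch.
    """
    dialect = dialect or mapping.dialect
    n8 = len(mapping.seq8)
    arcs: list[Arc] = []
    for i, j in _stacks(structure4):
        if classify_stack((i, j), mapping, dialect) == "eccentric":
            continue
        u = mapping.region_at4(i)
        v = mapping.region_at4(j)
        oi = i - u.start4 + 1
        oj = j - v.start4 + 1
        if dialect == "prime" and v.in_switch:
            pos_v = v.start8 + oj - 1  # switch regions are not widened
        else:
            pos_v = v.start8 + oj - 2  # (j-1)-th base of v
        pos_u = u.start8 + oi - 1
        if not (u.start8 <= pos_u < u.end8) or not (v.start8 <= pos_v < v.end8):
            raise ValueError(
                f"stack ({i},{j}) maps outside its 8-letter regions "
                f"{u.label}/{v.label}")
        arcs.append((pos_u, pos_v))
    if len(set(arcs)) != len(arcs):
        raise ValueError("Map' produced duplicate arcs")
    return SecondaryStructure(n8, tuple(arcs))
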