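"""Folding pathways: representation, barrier, and the low-barrier constructors.

A pathway is an ordered list of structures S_1..S_m in which consecutive
structures differ by exactly one arc (one addition or one removal).  Its
*barrier* under an energy functional E (AC or SAC) is

    max_{1 <= i <= j <= m} [ E(S_i) - E(S_j) ],

the biggest drop from an earlier high point to a later low point; for a
pathway starting at an MFE structure this is just E(S_1) minus the minimum
E along the pathway.

The constructors build the designed long low-barrier pathways:

* ``construct_low_barrier_pathway_8``: initial -> target of the 8-letter
  switch-lock, barrier exactly k+1 under the arc-count model, length
  2k(AB + A + 2B - 1);
* ``construct_low_barrier_pathway_4``: initial -> target of the 4-letter
  switch-lock', barrier exactly k+2 under the stacked-pair model, length
  (2k(A-1) + 6k + 3)B + 2k(A-1).

Both are composed of B band-unlocking phases, each embedding one full switch
reconfiguration, plus a final switch reconfiguration.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence as Seq

from .design import DesignParams, RegionMap, Sequence, initial_structure, \
    region_map_of, target_structure
from .energy import ARC, STACK, EnergyModel
from .structure import Arc, SecondaryStructure, validate

__all__ = [
    "Move", "Pathway", "PathwayError", "barrier",
    "reconfigure_switch", "unlock_band",
    "construct_low_barrier_pathway_8", "construct_low_barrier_pathway_4",
    "expected_barrier_8", "expected_barrier_4",
    "read_pathway", "write_pathway",
]


class PathwayError(ValueError):
    """An invalid pathway or a violated construction postcondition."""


@dataclass(frozen=True)
class Move:
    """One pathway step: add or remove a single arc."""

    op: str  # "add" | "remove"
    arc: Arc

    def __post_init__(self) -> None:
        if self.op not in ("add", "remove"):
            raise ValueError(f"bad move op {self.op!r}")

    def inverse(self) -> "Move":
        return Move("remove" if self.op == "add" else "add", self.arc)


def _reverse_moves(moves: Iterable[Move]) -> list[Move]:
    return [m.inverse() for m in reversed(list(moves))]


class Pathway:
    """A sequence of single-arc moves applied to a start structure.

    Structures are materialised lazily; energies along the pathway are
    maintained incrementally (O(1) per move for both AC and SAC).
    """

    def __init__(self, sequence: Sequence, start: SecondaryStructure,
                 moves: Seq[Move], check: bool = True):
        self.sequence = sequence
        self.start = start
        self.moves = list(moves)
        if check:
            self._check_moves()

    def _check_moves(self) -> None:
        if validate(self.start, self.sequence):
            raise PathwayError("start structure is invalid")
        pair: dict[int, int] = dict(self.start._pair)
        arcs = set(self.start.arcs)
        seq, alpha = self.sequence.symbols, self.sequence.alphabet
        from .alphabet import complementary

        for step, mv in enumerate(self.moves):
            i, j = mv.arc
            if mv.op == "remove":
                if pair.get(i) != j:
                    raise PathwayError(f"step {step}: removing absent arc {mv.arc}")
                del pair[i], pair[j]
                arcs.discard((i, j))
            else:
                if i in pair or j in pair:
                    raise PathwayError(f"step {step}: endpoint of {mv.arc} already paired")
                if not complementary(seq[i], seq[j], alpha):
                    raise PathwayError(f"step {step}: arc {mv.arc} not complementary")
                for a, b in arcs:
                    if (a < i < b < j) or (i < a < j < b):
                        raise PathwayError(
                            f"step {step}: arc {mv.arc} crosses ({a},{b})")
                pair[i], pair[j] = j, i
                arcs.add((i, j))

    def __len__(self) -> int:
        """Pathway length: the number of moves (m - 1 structures transitions)."""
        return len(self.moves)

    def structures(self) -> Iterator[SecondaryStructure]:
        s = self.start
        yield s
        for mv in self.moves:
            s = s.with_arc(mv.arc) if mv.op == "add" else s.without_arc(mv.arc)
            yield s

    @property
    def end(self) -> SecondaryStructure:
        s = self.start
        for mv in self.moves:
            s = s.with_arc(mv.arc) if mv.op == "add" else s.without_arc(mv.arc)
        return s

    def energies(self, model: EnergyModel = ARC) -> list[int]:
        """The E-trace (AC or SAC) along the pathway, incrementally."""
        pair: dict[int, int] = dict(self.start._pair)
        if model.kind == "arc_count":
            e = self.start.arc_count()
        else:
            e = self.start.stacked_pair_count()
        trace = [e]
        for mv in self.moves:
            i, j = mv.arc
            if model.kind == "arc_count":
                delta = 1
            else:
                delta = 0
                if j - i >= 3 and pair.get(i + 1) == j - 1:
                    delta += 1
                if i >= 1 and pair.get(i - 1) == j + 1:
                    delta += 1
            if mv.op == "add":
                e += delta
                pair[i], pair[j] = j, i
            else:
                del pair[i], pair[j]
                e -= delta
            trace.append(e)
        return trace

    def barrier(self, model: EnergyModel = ARC) -> int:
        return barrier_of_trace(self.energies(model))

    def reversed(self) -> "Pathway":
        return Pathway(self.sequence, self.end, _reverse_moves(self.moves),
                       check=False)

    def validate_all(self) -> list:
        """Full validator on every structure; [] iff the pathway is valid."""
        out = []
        for idx, s in enumerate(self.structures()):
            for v in validate(s, self.sequence):
                out.append((idx, v))
        return out


def barrier_of_trace(trace: Seq[int]) -> int:
    """max over i<=j of trace[i] - trace[j], in one left-to-right pass."""
    best, running_max = 0, -(10**9)
    for e in trace:
        if e > running_max:
            running_max = e
        if running_max - e > best:
            best = running_max - e
    return best


def barrier(pathway: Pathway, model: EnergyModel = ARC) -> int:
    """The energy barrier of a pathway under the AC or SAC functional."""
    return pathway.barrier(model)


# -- switch reconfiguration --------------------------------------------


def _switch_moves_left_to_right(rmap: RegionMap, k: int, A: int) -> list[Move]:
    """2k(A-1) moves taking a pure left-position switch to the right position.

    Three subphases: barrier-k ascent (remove the L_1·R_2 band), branch
    migration (remove the outermost remaining left arc, immediately add the
    corresponding right-position arc), barrier-k descent (add the innermost
    target band L_A·R_{A-1}).
    """
    moves: list[Move] = []
    # ascent: remove the k L_1·R_2 arcs, outermost first
    L1, R2 = rmap["L1"], rmap["R2"]
    for t in range(k):
        moves.append(Move("remove", (L1.start + t, R2.end - 1 - t)))
    # branch migration over bands sigma = 2 .. A-1
    for s in range(2, A):
        Ls, Rs1, Rm1 = rmap[f"L{s}"], rmap[f"R{s + 1}"], rmap[f"R{s - 1}"]
        for t in range(k):
            moves.append(Move("remove", (Ls.start + t, Rs1.end - 1 - t)))
            moves.append(Move("add", (Ls.start + t, Rm1.end - 1 - t)))
    # descent: add the innermost right-position band
    LA, RA1 = rmap[f"L{A}"], rmap[f"R{A - 1}"]
    for t in range(k):
        moves.append(Move("add", (LA.start + t, RA1.end - 1 - t)))
    return moves


def reconfigure_switch(structure: SecondaryStructure, direction: str,
                       params: DesignParams,
                       rmap: RegionMap | None = None) -> list[Move]:
    """Moves reconfiguring the switch between its two pure positions.

    ``direction`` is ``"left_to_right"`` or ``"right_to_left"``; the latter is
    the exact reverse of the former.  Precondition: every intra-switch arc of
    *structure* forms the full band set of the stated source position, and no
    trans-arc touches the switch regions that the schedule uses.
    """
    if rmap is None:
        _, rmap = region_map_of(params)
    k, A = params.k, params.A
    fwd = _switch_moves_left_to_right(rmap, k, A)
    if direction == "left_to_right":
        moves, removed = fwd, "left"
    elif direction == "right_to_left":
        moves, removed = _reverse_moves(fwd), "right"
    else:
        raise ValueError(f"bad direction {direction!r}")
    _check_switch_position(structure, rmap, k, A, removed)
    return moves


def _switch_band_arcs(rmap: RegionMap, k: int, A: int, position: str) -> set[Arc]:
    arcs: set[Arc] = set()
    for i in range(1, A):
        u = rmap[f"L{i}"] if position == "left" else rmap[f"L{i + 1}"]
        v = rmap[f"R{i + 1}"] if position == "left" else rmap[f"R{i}"]
        arcs |= {(u.start + t, v.end - 1 - t) for t in range(k)}
    return arcs


def _check_switch_position(structure: SecondaryStructure, rmap: RegionMap,
                           k: int, A: int, position: str) -> None:
    lo, hi = rmap["L1"].start, rmap["R1"].end
    present = {a for a in structure.arcs if lo <= a[0] < hi and lo <= a[1] < hi}
    want = _switch_band_arcs(rmap, k, A, position)
    if present != want:
        raise PathwayError(
            f"switch is not purely in the {position} position "
            f"({len(present)} intra-switch arcs, expected the {position}-band set)")


# -- band unlocking --------------------------------------------------------


def _center_band(rmap: RegionMap, i: int, wc: int) -> list[Arc]:
    return [(rmap[f"l{i}"].start + t, rmap[f"r{i}"].end - 1 - t) for t in range(wc)]


def unlock_band(structure: SecondaryStructure, i: int,
                params: DesignParams,
                rmap: RegionMap | None = None) -> list[Move]:
    """Moves removing center band i and forming its x·y / p·q replacements.

    The schedule (for odd i; even i is the mirror image):

    1. reconfigure the switch left -> right (2k(A-1) moves), freeing L_1;
    2. branch migration: k times, remove the outermost l_i·r_i arc and
       immediately add a trans-arc from the freed lock base to the innermost
       free base of L_1 (so trans-arcs nest);
    3. barrier ascent: remove the remaining center arcs;
    4. barrier descent: form the p_i·q_i band;
    5. ascent: remove the k trans-arcs;
    6. descent: form the x_i·y_i band.

    For even i the switch goes right -> left, the trans-arcs connect R_1 to
    r_i, and the x·y band is formed *before* the trans-arcs are removed (the
    mirrored nesting requires it).  Total: 2kA + 4k moves for the 8-letter
    design, 2k(A-1) + 6k + 3 for the 4-letter prime design.

    Precondition (checked): bands 1..i-1 already unlocked, band i complete.
    """
    if rmap is None:
        _, rmap = region_map_of(params)
    k, A, B = params.k, params.A, params.B
    prime = params.alphabet == "four_letter_prime"
    wc = 2 * k + 1 if prime else 2 * k   # center band width
    wr = k + 1 if prime else k           # replacement band width

    if not 1 <= i <= B:
        raise PathwayError(f"band index {i} outside 1..{B}")
    center = _center_band(rmap, i, wc)
    for arc in center:
        if not structure.has_arc(arc):
            raise PathwayError(f"band {i} is not complete: missing center arc {arc}")
    for j in range(1, i):
        for arc in _center_band(rmap, j, wc):
            if structure.has_arc(arc):
                raise PathwayError(
                    f"unlocking band {i} before band {j}: center arcs must be "
                    "removed from the outside in")

    odd = i % 2 == 1
    direction = "left_to_right" if odd else "right_to_left"
    moves = reconfigure_switch(structure, direction, params, rmap)

    li, ri = rmap[f"l{i}"], rmap[f"r{i}"]
    if odd:
        # trans-arcs: freed bases at the left end of l_i against L_1's G's,
        # allocated from L_1's right end inward so the arcs nest
        L1 = rmap["L1"]
        trans = [(L1.end - 1 - t, li.start + t) for t in range(k)]
    else:
        # mirror: freed bases at the right end of r_i against R_1's A's
        R1 = rmap["R1"]
        trans = [(R1.start + t, ri.end - 1 - t) for t in range(k)]
    # 2. branch migration: remove outermost center arc, add trans-arc
    for t in range(k):
        moves.append(Move("remove", center[t]))
        moves.append(Move("add", trans[t]))
    # 3. ascent: remove the remaining center arcs, outermost-first
    for t in range(k, wc):
        moves.append(Move("remove", center[t]))

    xy = [(rmap[f"x{i}"].start + t, rmap[f"y{i}"].end - 1 - t) for t in range(wr)]
    pq = [(rmap[f"p{i}"].start + t, rmap[f"q{i}"].end - 1 - t) for t in range(wr)]
    if odd:
        moves += [Move("add", a) for a in pq]          # 4. descent
        moves += [Move("remove", a) for a in trans]    # 5. ascent
        moves += [Move("add", a) for a in xy]          # 6. descent
    else:
        moves += [Move("add", a) for a in xy]
        moves += [Move("remove", a) for a in trans]
        moves += [Move("add", a) for a in pq]
    return moves


# -- full constructors -----------------------------------------------------


def _apply(structure: SecondaryStructure, moves: Iterable[Move]) -> SecondaryStructure:
    for mv in moves:
        structure = (structure.with_arc(mv.arc) if mv.op == "add"
                     else structure.without_arc(mv.arc))
    return structure


def _construct(params: DesignParams) -> Pathway:
    seq, rmap = region_map_of(params)
    s = initial_structure(params)
    moves: list[Move] = []
    cur = s
    for i in range(1, params.B + 1):
        band = unlock_band(cur, i, params, rmap)
        moves += band
        cur = _apply(cur, band)
    final = reconfigure_switch(cur, "left_to_right", params, rmap)
    moves += final
    cur = _apply(cur, final)
    if cur.arc_set() != target_structure(params).arc_set():
        raise PathwayError("constructed pathway does not end at the target structure")
    return Pathway(seq, s, moves)


def expected_barrier_8(params: DesignParams) -> int:
    """Arc-count barrier of the constructed 8-letter pathway: k + 1.

    Degenerate case A = 2: the switch has a single band pair, the
    branch-migration subphase (whose remove/add interleaving causes the
    extra unit of drop) is empty, and the barrier is exactly k.
    """
    return params.k + 1 if params.A >= 4 else params.k


def expected_barrier_4(params: DesignParams) -> int:
    """Stacked-pair barrier of the constructed prime pathway: k + 2.

    As above, A = 2 removes the branch-migration subphase and the barrier
    drops to k + 1.
    """
    return params.k + 2 if params.A >= 4 else params.k + 1


def construct_low_barrier_pathway_8(params: DesignParams) -> Pathway:
    """The barrier-(k+1) pathway of the 8-letter design.

    Postconditions (checked): length exactly 2k(AB + A + 2B - 1); arc-count
    barrier exactly k + 1 (k when A = 2, see :func:`expected_barrier_8`);
    endpoints are the initial and target structures.
    """
    if params.alphabet != "eight_letter":
        raise PathwayError("construct_low_barrier_pathway_8 needs the eight_letter design")
    p = _construct(params)
    k, A, B = params.k, params.A, params.B
    want_len = 2 * k * (A * B + A + 2 * B - 1)
    if len(p) != want_len:
        raise PathwayError(f"length {len(p)} != predicted {want_len}")
    b = p.barrier(ARC)
    if b != expected_barrier_8(params):
        raise PathwayError(f"arc-count barrier {b} != predicted {expected_barrier_8(params)}")
    return p


def construct_low_barrier_pathway_4(params: DesignParams) -> Pathway:
    """The barrier-(k+2) pathway of the 4-letter prime design.

    Postconditions (checked): length exactly (2k(A-1) + 6k + 3)B + 2k(A-1);
    stacked-pair barrier exactly k + 2.  A mismatch raises: deviation from the
    predicted barrier must be reported, never silently accepted.
    """
    if params.alphabet != "four_letter_prime":
        raise PathwayError("construct_low_barrier_pathway_4 needs the four_letter_prime design")
    p = _construct(params)
    k, A, B = params.k, params.A, params.B
    want_len = (2 * k * (A - 1) + 6 * k + 3) * B + 2 * k * (A - 1)
    if len(p) != want_len:
        raise PathwayError(f"length {len(p)} != predicted {want_len}")
    b = p.barrier(STACK)
    if b != expected_barrier_4(params):
        raise PathwayError(f"stacked-pair barrier {b} != predicted {expected_barrier_4(params)}")
    return p


# -- pathway files ---------------------------------------------------------


def write_pathway(path, pathway: Pathway) -> None:
    """Line 1: sequence; then one dot-bracket line per structure."""
    from .structure import to_dot_bracket
    with open(path, "w") as fh:
        fh.write(pathway.sequence.symbols + "\n")
        for s in pathway.structures():
            fh.write(to_dot_bracket(s) + "\n")


def read_pathway(path) -> Pathway:
    from .design import Sequence as DSeq
    from .structure import read_structure_file
    seq_str, structs = read_structure_file(path)
    alpha = "eight" if any(c in "PQXY" for c in seq_str) else "four"
    seq = DSeq(seq_str, alpha)
    if not structs:
        raise PathwayError(f"{path}: pathway file has no structures")
    moves: list[Move] = []
    for a, b in zip(structs, structs[1:]):
        added = b.arc_set() - a.arc_set()
        removed = a.arc_set() - b.arc_set()
        if len(added) + len(removed) != 1:
            raise PathwayError("consecutive structures must differ by exactly one arc")
        moves.append(Move("add", next(iter(added))) if added
                     else Move("remove", next(iter(removed))))
    return Pathway(seq, structs[0], moves)
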