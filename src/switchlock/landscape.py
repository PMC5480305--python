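"""Brute-force oracles on tiny instances.

Exhaustive enumeration of pseudoknot-free structures, brute-force MAC/MSAC,
random structure sampling, and bounded-barrier flood fill over the
single-arc-move graph.  Everything here is exponential and guarded by
explicit caps: exceeding a cap is an error, never silent truncation — these
oracles must not masquerade as general solvers.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from typing import Iterator

import numpy as np

from .alphabet import complementary
from .energy import ARC, EnergyModel
from .structure import Arc, SecondaryStructure

__all__ = ["enumerate_structures", "count_structures", "brute_force_mfe",
           "bounded_barrier_flood", "random_structure", "FloodResult",
           "LimitExceeded"]

DEFAULT_LENGTH_CAP = 24


class LimitExceeded(RuntimeError):
    """An enumeration or flood limit was hit; the result is unknown."""


def _seq_and_alphabet(sequence) -> tuple[str, str]:
    if hasattr(sequence, "symbols"):
        return sequence.symbols, sequence.alphabet
    return sequence, ("eight" if any(c in "PQXY" for c in sequence) else "four")


def _arc_lists(seq: str, alphabet: str, min_loop: int = 0) -> list[list[int]]:
    """partners[i]: all j > i such that (i, j) is a complementary pair."""
    n = len(seq)
    return [[j for j in range(i + 1 + min_loop, n)
             if complementary(seq[i], seq[j], alphabet)] for i in range(n)]


def enumerate_structures(sequence, model: EnergyModel = ARC,
                         min_count: int = 0,
                         length_cap: int = DEFAULT_LENGTH_CAP
                         ) -> Iterator[SecondaryStructure]:
    """Every valid pseudoknot-free structure with AC (or SAC) >= min_count.

    Each structure is produced exactly once.  Raises :class:`LimitExceeded`
    if the sequence is longer than *length_cap*.
    """
    seq, alphabet = _seq_and_alphabet(sequence)
    n = len(seq)
    if n > length_cap:
        raise LimitExceeded(f"sequence length {n} exceeds enumeration cap {length_cap}")
    partners = _arc_lists(seq, alphabet, model.min_loop)

    def rec(i: int, j: int) -> Iterator[tuple[Arc, ...]]:
        """All arc tuples over the interval [i, j)."""
        if j - i < 2:
            yield ()
            return
        # position i unpaired
        for rest in rec(i + 1, j):
            yield rest
        # position i paired with t
        for t in partners[i]:
            if t >= j:
                break
            for inside in rec(i + 1, t):
                for outside in rec(t + 1, j):
                    yield ((i, t),) + inside + outside

    for arcs in rec(0, n):
        s = SecondaryStructure(n, arcs)
        if model.value(s) >= min_count:
            yield s


def count_structures(sequence, min_loop: int = 0,
                     length_cap: int = DEFAULT_LENGTH_CAP) -> int:
    """Number of valid structures, by an independent interval recursion.

    Counts without materialising structures; used to cross-check the
    enumerator (two independent strategies must agree).
    """
    seq, alphabet = _seq_and_alphabet(sequence)
    n = len(seq)
    if n > length_cap:
        raise LimitExceeded(f"sequence length {n} exceeds enumeration cap {length_cap}")
    partners = _arc_lists(seq, alphabet, min_loop)
    # N[i][j]: structure count on half-open [i, j)
    N = np.ones((n + 2, n + 2), dtype=object)
    for span in range(2, n + 1):
        for i in range(0, n - span + 1):
            j = i + span
            total = N[i + 1][j]
            for t in partners[i]:
                if t >= j:
                    break
                total += N[i + 1][t] * N[t + 1][j]
            N[i][j] = total
    return int(N[0][n])


def brute_force_mfe(sequence, model: EnergyModel = ARC,
                    length_cap: int = DEFAULT_LENGTH_CAP) -> int:
    """max AC (or SAC) over exhaustive enumeration — the DP oracle."""
    return max(model.value(s)
               for s in enumerate_structures(sequence, model, 0, length_cap))


def random_structure(sequence, rng: np.random.Generator,
                     accept: float = 0.6) -> SecondaryStructure:
    """A random valid structure: shuffle all complementary pairs, then add
    each with probability *accept* when it stays compatible."""
    seq, alphabet = _seq_and_alphabet(sequence)
    n = len(seq)
    cand = [(i, j) for i in range(n) for j in range(i + 1, n)
            if complementary(seq[i], seq[j], alphabet)]
    order = rng.permutation(len(cand))
    paired: set[int] = set()
    arcs: list[Arc] = []
    for idx in order:
        i, j = cand[idx]
        if i in paired or j in paired:
            continue
        if rng.random() > accept:
            continue
        if any((a < i < b < j) or (i < a < j < b) for a, b in arcs):
            continue
        arcs.append((i, j))
        paired |= {i, j}
    return SecondaryStructure(n, tuple(arcs))


# -- bounded-barrier flood -------------------------------------------------


@dataclass(frozen=True)
class FloodResult:
    start: SecondaryStructure
    cap: int
    visited: int
    reached: bool
    floor: int
    truncated: bool  # True iff a visit/step limit stopped the search


def _neighbors(s: SecondaryStructure, seq: str, alphabet: str,
               min_loop: int = 0) -> Iterator[SecondaryStructure]:
    for arc in s.arcs:
        yield s.without_arc(arc)
    n = s.n
    for i in range(n):
        if s.is_paired(i):
            continue
        for j in range(i + 1 + min_loop, n):
            if s.is_paired(j) or not complementary(seq[i], seq[j], alphabet):
                continue
            if not s.crosses((i, j)):
                yield s.with_arc((i, j))


def bounded_barrier_flood(sequence, start: SecondaryStructure, cap: int,
                          model: EnergyModel = ARC,
                          target: SecondaryStructure | None = None,
                          max_visited: int = 200_000) -> FloodResult:
    """Explore all structures reachable without the barrier exceeding *cap*.

    Precondition: *start* is an MFE structure (maximum E), so the running
    maximum along any path equals E(start) and the barrier constraint
    reduces to  E(S) >= E(start) - cap  for every visited structure S.
    Raises :class:`LimitExceeded` when *max_visited* is hit before the search
    space is exhausted (reported distinctly from "target not reachable").
    """
    seq, alphabet = _seq_and_alphabet(sequence)
    e_start = model.value(start)
    threshold = e_start - cap
    start_key = start.arc_set()
    target_key = target.arc_set() if target is not None else None
    seen = {start_key}
    queue = deque([start])
    floor = e_start
    reached = target_key == start_key
    while queue:
        s = queue.popleft()
        for nb in _neighbors(s, seq, alphabet, model.min_loop):
            e = model.value(nb)
            if e < threshold:
                continue
            key = nb.arc_set()
            if key in seen:
                continue
            seen.add(key)
            floor = min(floor, e)
            if key == target_key:
                reached = True
            if len(seen) > max_visited:
                raise LimitExceeded(
                    f"flood visited more than {max_visited} structures "
                    f"(cap={cap}); raise max_visited to finish the search")
            queue.append(nb)
    return FloodResult(start, cap, len(seen), reached, floor, truncated=False)
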