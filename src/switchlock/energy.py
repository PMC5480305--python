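"""Maximum arc count (MAC) and maximum stacked-pair count (MSAC) by interval DP.

Two abstract energy functionals are supported:

* ``arc_count``: every base pair contributes energy -1 (E = -AC);
* ``stacked_pair``: every stacked pair of consecutive arcs contributes -1
  (E = -SAC).

``max_arc_count`` is the classic O(n^3) maximum-matching interval recursion;
``max_stack_count`` augments it with a "closed" state so that stacking of an
arc (i, j) on (i+1, j-1) can be scored.  ``min_loop`` (default 0) is the
minimum number of unpaired bases inside an arc: the abstract models impose no
hairpin minimum, so arcs (i, i+1) are allowed by default; set ``min_loop=3``
for physically plausible hairpins.

If numba is installed the DP kernels are jit-compiled; the pure-Python
kernels below are the reference implementation and are always importable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alphabet import complementary, symbols
from .structure import SecondaryStructure

__all__ = ["EnergyModel", "max_arc_count", "max_stack_count", "energy",
           "mfe_structure"]

NEG = -(10**9)


@dataclass(frozen=True)
class EnergyModel:
    """kind: ``arc_count`` or ``stacked_pair``; min_loop: minimum hairpin gap."""

    kind: str = "arc_count"
    min_loop: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("arc_count", "stacked_pair"):
            raise ValueError(f"unknown energy model kind {self.kind!r}")
        if self.min_loop < 0:
            raise ValueError("min_loop must be non-negative")

    def value(self, structure: SecondaryStructure) -> int:
        """The (non-negative) functional: AC or SAC."""
        if self.kind == "arc_count":
            return structure.arc_count()
        return structure.stacked_pair_count()


ARC = EnergyModel("arc_count")
STACK = EnergyModel("stacked_pair")


def energy(structure: SecondaryStructure, model: EnergyModel = ARC) -> int:
    """Total energy: -AC or -SAC."""
    return -model.value(structure)


def _encode(seq: str, alphabet: str) -> tuple[np.ndarray, np.ndarray]:
    """Integer-encode a sequence and build the pair-compatibility matrix."""
    letters = sorted(symbols(alphabet))
    index = {c: i for i, c in enumerate(letters)}
    try:
        enc = np.array([index[c] for c in seq], dtype=np.int8)
    except KeyError as e:
        raise ValueError(f"unsupported symbol {e.args[0]!r} for {alphabet}-letter alphabet")
    m = len(letters)
    compat = np.zeros((m, m), dtype=np.bool_)
    for a in letters:
        for b in letters:
            compat[index[a], index[b]] = complementary(a, b, alphabet)
    return enc, compat


def _mac_kernel(enc, compat, min_loop):
    n = len(enc)
    M = np.zeros((n + 1, n + 1), dtype=np.int64)  # M[i][j]: interval [i, j)
    for span in range(2, n + 1):
        for i in range(0, n - span + 1):
            j = i + span
            best = M[i + 1][j]
            for t in range(i + 1 + min_loop, j):
                if compat[enc[i]][enc[t]]:
                    v = M[i + 1][t] + 1 + M[t + 1][j]
                    if v > best:
                        best = v
            M[i][j] = best
    return M


def _msac_kernel(enc, compat, min_loop):
    """W[i][j]: best SAC on [i, j); V[i][j]: best SAC with arc (i, j-1) forced."""
    n = len(enc)
    W = np.zeros((n + 1, n + 1), dtype=np.int64)
    V = np.full((n + 1, n + 1), NEG, dtype=np.int64)
    for span in range(2, n + 1):
        for i in range(0, n - span + 1):
            j = i + span
            if compat[enc[i]][enc[j - 1]] and span >= min_loop + 2:
                v = W[i + 1][j - 1]
                if V[i + 1][j - 1] + 1 > v:
                    v = V[i + 1][j - 1] + 1
                V[i][j] = v
            best = W[i + 1][j]
            for t in range(i + 1, j):
                if V[i][t + 1] > NEG // 2:
                    cand = V[i][t + 1] + W[t + 1][j]
                    if cand > best:
                        best = cand
            W[i][j] = best
    return W, V


try:  # optional acceleration; the Python kernels above remain authoritative
    from numba import njit as _njit

    _mac_fast = _njit(cache=False)(_mac_kernel)
    _msac_fast = _njit(cache=False)(_msac_kernel)
except Exception:  # pragma: no cover - numba genuinely absent
    _mac_fast = _mac_kernel
    _msac_fast = _msac_kernel


def _seq_and_alphabet(sequence) -> tuple[str, str]:
    if hasattr(sequence, "symbols"):
        return sequence.symbols, sequence.alphabet
    return sequence, ("eight" if any(c in "PQXY" for c in sequence) else "four")


def max_arc_count(sequence, model: EnergyModel = ARC) -> int:
    """MAC(s): the maximum number of arcs over all valid structures."""
    seq, alpha = _seq_and_alphabet(sequence)
    if not seq:
        return 0
    enc, compat = _encode(seq, alpha)
    return int(_mac_fast(enc, compat, model.min_loop)[0][len(seq)])


def max_stack_count(sequence, model: EnergyModel = STACK) -> int:
    """MSAC(s): the maximum number of stacked arc pairs over all structures."""
    seq, alpha = _seq_and_alphabet(sequence)
    if not seq:
        return 0
    enc, compat = _encode(seq, alpha)
    W, _ = _msac_fast(enc, compat, model.min_loop)
    return int(W[0][len(seq)])


def mfe_structure(sequence, model: EnergyModel = ARC) -> SecondaryStructure:
    """One witness structure attaining MAC (or MSAC), by DP traceback."""
    seq, alpha = _seq_and_alphabet(sequence)
    n = len(seq)
    enc, compat = _encode(seq, alpha)
    arcs: list[tuple[int, int]] = []
    if model.kind == "arc_count":
        M = _mac_fast(enc, compat, model.min_loop)

        def trace(i: int, j: int) -> None:
            while j - i >= 2:
                if M[i][j] == M[i + 1][j]:
                    i += 1
                    continue
                for t in range(i + 1 + model.min_loop, j):
                    if compat[enc[i]][enc[t]] and M[i][j] == M[i + 1][t] + 1 + M[t + 1][j]:
                        arcs.append((i, t))
                        trace(i + 1, t)
                        i = t + 1
                        break
                else:  # pragma: no cover - DP is self-consistent
                    raise AssertionError("traceback failed")

        trace(0, n)
    else:
        W, V = _msac_fast(enc, compat, model.min_loop)

        def trace_v(i: int, j: int) -> None:
            # arc (i, j-1) is present
            arcs.append((i, j - 1))
            if j - 1 - i >= 2:
                inner = V[i + 1][j - 1]
                if inner > NEG // 2 and V[i][j] == inner + 1:
                    trace_v(i + 1, j - 1)
                else:
                    trace_w(i + 1, j - 1)

        def trace_w(i: int, j: int) -> None:
            while j - i >= 2:
                if W[i][j] == W[i + 1][j]:
                    i += 1
                    continue
                for t in range(i + 1, j):
                    if V[i][t + 1] > NEG // 2 and W[i][j] == V[i][t + 1] + W[t + 1][j]:
                        trace_v(i, t + 1)
                        i = t + 1
                        break
                else:  # pragma: no cover
                    raise AssertionError("traceback failed")

        trace_w(0, n)
    return SecondaryStructure(n, tuple(arcs))
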