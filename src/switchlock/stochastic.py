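"""Stochastic barrier-ascent simulators.

A *barrier ascent* is the removal, against the energetic gradient, of all k
arcs of an initially complete band.  Four discrete-step models are provided;
in all of them one move (arc addition or removal) takes one time unit, the
chain starts from the complete k-arc state and absorbs at the empty
structure, and the reported quantity is the number of moves until absorption.

* ``distinct_arc`` — bases A_1..A_k pair only with their partners
  Ā_k..Ā_1; adding any missing arc has propensity alpha, removing any
  present arc 1/alpha.  With i arcs removed the probability of an addition is
  i*alpha^2 / (i*alpha^2 + k - i).
* ``distinct_stack`` — same geometry, but propensities depend on stacking:
  adding an arc that forms two/one/zero new stacked pairs has propensity
  alpha^2 / alpha / 1, and removals the reciprocals.
* ``uniform_stack`` — any A_i may pair with any Ā_j as long as no two
  arcs cross; stacking propensities as above.
* ``alternating_stack`` — as uniform, plus i and j must share parity.

The distinct-arc model is a birth-death chain whose exact expected ascent
time is computed in :mod:`switchlock.markov`; simulations here are checked
against it.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field

import numpy as np

from .structure import Arc

__all__ = ["AscentModel", "AscentExperiment", "step_distribution",
           "simulate_ascent", "run_experiment", "write_experiment_csv"]

MODEL_KINDS = ("distinct_arc", "distinct_stack", "uniform_stack",
               "alternating_stack")


@dataclass(frozen=True)
class AscentModel:
    kind: str
    k: int
    alpha: float

    def __post_init__(self) -> None:
        if self.kind not in MODEL_KINDS:
            raise ValueError(f"model kind must be one of {MODEL_KINDS}")
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if not self.alpha > 1:
            raise ValueError("alpha must be > 1")

    def full_state(self) -> frozenset[Arc]:
        """The initial state: arcs (i, i) for i = 1..k, as (A-index, Ā-index)."""
        return frozenset((i, i) for i in range(1, self.k + 1))


# -- state geometry --------------------------------------------------------
# A state is a frozenset of (i, j) meaning A_i paired with Ā_j.  In linear
# coordinates A_i sits at position i and Ā_j at position 2k + 1 - j, so
# (i, j) and (i', j') cross iff exactly one of i' and the mirrored j' falls
# strictly inside the span of (i, j).


def _endpoints(arc: Arc, k: int) -> tuple[int, int]:
    i, j = arc
    return i, 2 * k + 1 - j


def _crosses(a: Arc, b: Arc, k: int) -> bool:
    a1, a2 = _endpoints(a, k)
    b1, b2 = _endpoints(b, k)
    return (a1 < b1 < a2 < b2) or (b1 < a1 < b2 < a2)


def _stack_partners(arc: Arc, state: frozenset[Arc], k: int) -> int:
    """How many stacked pairs *arc* forms with arcs currently in *state*."""
    p, q = _endpoints(arc, k)
    count = 0
    eps = {_endpoints(a, k): a for a in state}
    if (p + 1, q - 1) in eps:
        count += 1
    if (p - 1, q + 1) in eps:
        count += 1
    return count


def _legal_additions(state: frozenset[Arc], model: AscentModel) -> list[Arc]:
    k = model.k
    used_a = {i for i, _ in state}
    used_b = {j for _, j in state}
    if model.kind in ("distinct_arc", "distinct_stack"):
        cand = [(i, i) for i in range(1, k + 1) if i not in used_a]
    else:
        cand = [(i, j) for i in range(1, k + 1) if i not in used_a
                for j in range(1, k + 1) if j not in used_b]
        if model.kind == "alternating_stack":
            cand = [(i, j) for i, j in cand if (i - j) % 2 == 0]
    return [a for a in cand if not any(_crosses(a, b, k) for b in state)]


def step_distribution(state: frozenset[Arc], model: AscentModel) -> list[tuple[tuple[str, Arc], float]]:
    """All legal single-arc moves with their probabilities (sum to 1).

    Each move's probability is proportional to its propensity: alpha (or the
    stack-dependent alpha powers) for additions, the reciprocal for removals.
    """
    for a in state:
        for b in state:
            if a < b and _crosses(a, b, model.k):
                raise ValueError(f"illegal state: arcs {a} and {b} cross")
    alpha = model.alpha
    weights: list[tuple[tuple[str, Arc], float]] = []
    for arc in _legal_additions(state, model):
        if model.kind == "distinct_arc":
            w = alpha
        else:
            w = alpha ** _stack_partners(arc, state, model.k)
        weights.append((("add", arc), w))
    for arc in state:
        if model.kind == "distinct_arc":
            w = 1.0 / alpha
        else:
            rest = state - {arc}
            w = alpha ** (-_stack_partners(arc, rest, model.k))
        weights.append((("remove", arc), w))
    total = sum(w for _, w in weights)
    return [(mv, w / total) for mv, w in weights]


def simulate_ascent(model: AscentModel, rng: np.random.Generator,
                    max_steps: int | None = None) -> int:
    """Steps from the full k-arc state until the structure is empty."""
    if model.kind == "distinct_arc":
        return _simulate_distinct_arc(model.k, model.alpha, rng, max_steps)
    state = model.full_state()
    steps = 0
    while state:
        dist = step_distribution(state, model)
        u = rng.random()
        acc = 0.0
        for (op, arc), p in dist:
            acc += p
            if u < acc:
                state = state | {arc} if op == "add" else state - {arc}
                break
        else:  # numerical corner: take the last move
            op, arc = dist[-1][0]
            state = state | {arc} if op == "add" else state - {arc}
        steps += 1
        if max_steps is not None and steps >= max_steps:
            raise RuntimeError(f"ascent did not absorb within {max_steps} steps")
    return steps


def _simulate_distinct_arc_py(k: int, a2: float, seed: int) -> int:
    """Reference birth-death walk on i = number of removed arcs."""
    rng = np.random.default_rng(seed)
    i, steps = 0, 0
    while i < k:
        p_add = i * a2 / (i * a2 + (k - i))
        if rng.random() < p_add:
            i -= 1
        else:
            i += 1
        steps += 1
    return steps


def _distinct_arc_batch_py(k, a2, seeds):
    return np.array([_simulate_distinct_arc_py(k, a2, int(s)) for s in seeds],
                    dtype=np.int64)


try:  # optional jit for the long ascents at k ~ 8
    from numba import njit as _njit

    @_njit(cache=False)
    def _distinct_arc_batch_jit(k, a2, seeds):  # pragma: no cover - jitted
        out = np.empty(len(seeds), dtype=np.int64)
        for r in range(len(seeds)):
            np.random.seed(seeds[r])
            i = 0
            steps = 0
            while i < k:
                p_add = i * a2 / (i * a2 + (k - i))
                if np.random.random() < p_add:
                    i -= 1
                else:
                    i += 1
                steps += 1
            out[r] = steps
        return out

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False


def _simulate_distinct_arc(k: int, alpha: float, rng: np.random.Generator,
                           max_steps: int | None = None) -> int:
    a2 = alpha * alpha
    i, steps = 0, 0
    while i < k:
        p_add = i * a2 / (i * a2 + (k - i))
        if rng.random() < p_add:
            i -= 1
        else:
            i += 1
        steps += 1
        if max_steps is not None and steps >= max_steps:
            raise RuntimeError(f"ascent did not absorb within {max_steps} steps")
    return steps


# -- experiments -----------------------------------------------------------


@dataclass
class AscentExperiment:
    """One simulation cell: per-run step counts plus summary statistics."""

    model: AscentModel
    runs: int
    seed: int
    results: list[int] = field(default_factory=list)

    @property
    def mean(self) -> float:
        return float(np.mean(self.results))

    @property
    def stderr(self) -> float:
        if len(self.results) < 2:
            return float("nan")
        return float(np.std(self.results, ddof=1) / math.sqrt(len(self.results)))


def run_experiment(model: AscentModel, runs: int = 1000,
                   seed: int = 0) -> AscentExperiment:
    """Simulate *runs* independent ascents.

    Reproducibility: run r uses the child seed ``seed + r`` (recorded in CSV
    output), so individual runs can be replayed in isolation.
    """
    exp = AscentExperiment(model, runs, seed)
    if model.kind == "distinct_arc" and _HAVE_NUMBA and runs >= 16:
        seeds = np.arange(seed, seed + runs, dtype=np.int64) % (2**32)
        exp.results = [int(x) for x in
                       _distinct_arc_batch_jit(model.k, model.alpha ** 2, seeds)]
        return exp
    for r in range(runs):
        rng = np.random.default_rng(seed + r)
        exp.results.append(simulate_ascent(model, rng))
    return exp


def run_grid(kind: str, ks, alphas, runs: int = 1000, seed: int = 0):
    """Experiments over a (k, alpha) grid; returns a list of AscentExperiment."""
    out = []
    for k in ks:
        for alpha in alphas:
            out.append(run_experiment(AscentModel(kind, k, alpha), runs, seed))
            seed += runs  # disjoint child-seed ranges per cell
    return out


def write_experiment_csv(path, experiments) -> None:
    """CSV columns: model, k, alpha, seed, run, child_seed, steps."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["model", "k", "alpha", "seed", "run", "child_seed", "steps"])
        for e in experiments:
            m = e.model
            for r, steps in enumerate(e.results):
                w.writerow([m.kind, m.k, m.alpha, e.seed, r, e.seed + r, steps])
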