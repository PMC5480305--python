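# switchlock

Design and verification of single-stranded nucleic-acid molecules whose
folding pathway from a designed initial structure to a designed target
structure is provably *long* — superlinear in the strand length — while its
energy barrier stays low, and every substantially shorter pathway must climb
a much higher barrier.

The package is for people studying molecular computation and folding
kinetics with abstract energy models: it generates the switch-lock sequence
families, builds and verifies their low-barrier pathways move by move,
computes maximum arc / stacked-pair counts by dynamic programming, maps the
designs from an 8-letter to the standard 4-letter alphabet, and quantifies
how long a molecule is expected to take to climb an energy barrier, both
exactly (Markov-chain hitting times) and by stochastic simulation.

## The designs in one paragraph

A molecule `switch-lock(k, A, B)` (length 2kA + 8kB) is a **switch** — A
bands of k base pairs that can sit in a "left" or "right" position — joined
to a **lock** — B wide center bands that must be replaced by twice as many
narrow bands to reach the target.  Removing a center band outright costs an
energy barrier of 2k.  Borrowing the free end of the switch via *trans-arcs*
halves that cost to k+1, but odd bands need the left end and even bands the
right end, so the switch must fully reconfigure (Θ(kA) moves) between
consecutive band removals.  The pathway therefore makes

    2k(AB + A + 2B − 1)

moves — Θ(kAB) for a molecule of length Θ(k(A+B)) — while never dropping
more than k+1 pairs below the minimum free energy (the barrier is exactly
k+1 under the arc-count model for A ≥ 4; see `docs/methods.md` for the
degenerate A = 2 case).  A 4-letter variant `switch-lock'(k, A, B)` achieves
length (2k(A−1) + 6k + 3)B + 2k(A−1) with barrier k+2 under the
stacked-pair model.  Climbing a barrier of size k against a pairing bias α
takes expected time between 2(α²+1)^{k−1} − 2 + k and 2k(α²+1)^{k−1} − k,
so the designed low-barrier route is exponentially favoured over shortcuts.

## Worked example

```pycon
>>> from switchlock import (DesignParams, build_switch_lock, max_arc_count,
...     initial_structure, construct_low_barrier_pathway_8)
>>> from switchlock.energy import ARC
>>> params = DesignParams(k=3, A=6, B=4)
>>> seq, regions = build_switch_lock(params)
>>> len(seq), max_arc_count(seq), initial_structure(params).arc_count()
(132, 39, 39)
>>> path = construct_low_barrier_pathway_8(params)
>>> len(path), path.barrier(ARC)
(222, 4)
>>> trace = path.energies(ARC)
>>> min(trace), max(trace)
(35, 39)
```

The 132-nt molecule has 39 base pairs in its (MFE) initial structure, and
the constructed pathway to the target makes 222 single-pair moves — exactly
2k(AB + A + 2B − 1) — while the arc count never falls below 35 = 39 − (k+1):
the molecule pays only a (k+1)-barrier, here 4, to traverse all 223
structures.  Exact ascent analytics:

```pycon
>>> from switchlock import hitting_time_recurrence
>>> r = hitting_time_recurrence(k=8, alpha=2.0)
>>> round(r.T0, 1), r.bounds
(162384.8, (156256.0, 1249992.0))
```

so climbing even one band's 8-pair barrier takes ≈ 1.6·10⁵ moves in
expectation — against 222 moves for the whole designed pathway.

Each script in `examples/` demonstrates one capability end to end
(`python examples/low_barrier_pathway.py`, …), and the `switchlock` console
command exposes the same operations from a shell
(`switchlock design --k 2 --A 4 --B 2 --out seq.fa`,
`switchlock pathway …`, `switchlock verify …`, `switchlock hitting-time …`,
`switchlock ascend …`).

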