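# Methods

## The model

A molecule is a string over either an abstract 8-letter alphabet
{A, C, G, U, P, Q, X, Y} with complementary pairs (A·U), (C·G), (P·Q),
(X·Y), or the standard 4-letter alphabet with (A·U), (C·G).  A secondary
structure is a set of non-crossing arcs (base pairs) between complementary
positions, each position in at most one arc; pseudoknots are excluded by
construction.  Two energy functionals are used, both abstract:

* **arc count** — every arc contributes −1 (E = −AC);
* **stacked pairs** — every pair of consecutive arcs (i, j), (i+1, j−1)
  contributes −1 (E = −SAC).

Neither model has loop penalties, wobble pairs, sequence-dependent stack
energies, or any other Turner-style parameter.  This is deliberate: the
package's claims are exact combinatorial statements (lengths, barriers,
counts), which are provable and machine-checkable in the abstract models and
would be hopeless under a many-parameter thermodynamic model.  Minimum-
free-energy (MFE) structures are those attaining the maximum arc count
(MAC) or maximum stacked-pair count (MSAC).

A folding pathway is a sequence of structures each differing from its
predecessor by one arc.  Its **barrier** is
max over positions i ≤ j of E(S_i) − E(S_j) — the largest climb the
molecule must make out of an energy valley it has already reached.  When the
pathway starts at an MFE structure the barrier is simply the start level
minus the minimum level along the pathway.

## The switch-lock designs

`switch-lock(k, A, B)` (8-letter, length 2kA + 8kB) concatenates

* a **switch** (G^k U^k)^{A/2} (C^k A^k)^{A/2} whose A−1 bands of k arcs can
  sit in a *left* or a *right* position (the two positions share no arcs and
  mutually cross), and
* a **lock** (X^k)^B (C^{2k} Y^k A^{2k} Y^k)^{B/2} (P^k U^{2k} P^k
  G^{2k})^{B/2} (Q^k)^B whose B initial *center bands* (l_i·r_i, 2k arcs
  each) must be replaced by x_i·y_i and p_i·q_i bands (k arcs each) to reach
  the target.

Arc-for-arc, a center band is worth its two replacement bands, so the
initial and target structures have equal arc count, and both attain MAC =
(A−1)k + 2kB.  Removing a center band outright costs a 2k-barrier.  The
switch exists to cut this cost: after reconfiguring the switch, its freed
outermost region can accept k *trans-arcs* from a half-removed center band
(branch migration at nearly constant energy), halving the exposed barrier to
k+1.  Crucially, odd bands borrow the left end of the switch and even bands
the right end, so the switch must fully reconfigure between consecutive
band removals — B+1 reconfigurations of Θ(kA) moves each, giving total
pathway length 2k(AB + A + 2B − 1) for a molecule of length Θ(k(A+B)).

`switch-lock'(k, A, B)` (4-letter, k even, length 2kA + (8k+6)B) keeps the
switch and realises the synthetic lock regions as alternating dinucleotide
runs of width k+1 — (CA)^{k/2}C for X, (GU)^{k/2}G for Y, (AG)^{k/2}A for P,
(UC)^{k/2}U for Q — and widens center regions to 2k+1.  Alternating runs of
odd width are reverse-complementary exactly in intended partner pairs
(X with Y, P with Q); this is why k must be even.  Under the stacked-pair
functional the same unlocking schedule has length (2k(A−1) + 6k + 3)B +
2k(A−1) and barrier k+2.

### The explicit pathway schedules

`reconfigure_switch` performs, for left→right: (1) remove the k arcs of the
outermost left band; (2) branch migration — for each remaining left band,
outermost first, alternately remove its outermost arc and immediately add
the corresponding right-position arc; (3) add the k arcs of the innermost
right band.  Right→left is the exact reversal.  `unlock_band(i)` embeds one
reconfiguration, then: branch-migrate k center arcs into trans-arcs, remove
the remaining center arcs, form one replacement band, remove the trans-arcs,
form the other replacement band.  For odd bands the trans-arcs join the
freed left end of l_i to the switch's L_1 region and the p·q band is formed
before the x·y band; for even bands everything mirrors (trans-arcs from R_1
to r_i) and the x·y band must come first — the other order would cross the
trans-arcs.

Two move-ordering details matter and are fixed deterministically:

* "outermost first" everywhere (smallest left endpoint among candidates);
  removing from the end of a helix costs one stacked pair per move, removing
  from the middle would cost two and push the stacked-pair barrier to k+3.
* during branch migration the switch-side bases for trans-arcs are allocated
  from the innermost free base outward.  Allocating them outermost-first
  (the naive reading of "leftmost free base") would cross the arcs.

Both constructors verify their postconditions (exact length, exact barrier,
exact endpoints, validity of every intermediate structure) and raise rather
than return a deviating pathway.

### The A = 2 boundary case

The "+1" in the k+1 (and the "+2" in the k+2) barrier comes from the
branch-migration subphase of switch reconfiguration, which interleaves a
removal and an addition one unit below the running level.  With A = 2 the
switch has a single band pair and this subphase is empty: reconfiguration is
k removals followed by k additions, a clean drop of exactly k.  The
constructed pathway's barrier is therefore exactly k (8-letter) or k+1
(4-letter) when A = 2, and exactly k+1 / k+2 for every A ≥ 4.
`expected_barrier_8` / `expected_barrier_4` encode this piecewise value and
the tests assert it exactly; the flood-fill example confirms empirically
that at A = 2 the target is already reachable under a barrier cap of k.

## MFE dynamic programs

`max_arc_count` is the classic O(n³) maximum-matching interval recursion.
`max_stack_count` adds a "closed" table V[i][j] (best SAC with the arc
(i, j−1) forced) beside the free table W, with V[i][j] =
max(W[i+1][j−1], V[i+1][j−1] + 1): the +1 route scores a stack exactly when
the inner arc is also present.  Both kernels are plain Python/numpy and are
jit-compiled by numba when it is importable; the Python kernels are the
reference and the only semantics.  `min_loop` (default 0) sets the minimum
unpaired span inside an arc.  The default allows adjacent arcs (i, i+1):
the abstract models impose no hairpin minimum and the closed-form band
arithmetic assumes unrestricted non-crossing pairing.  Setting
`min_loop=3` recovers physically plausible hairpins for exploratory use.
Witness structures come from a standard traceback.

Correctness is established against `landscape.enumerate_structures`, an
exhaustive generator of all pseudoknot-free structures (checked in turn
against an independent interval-recursion counter), on hundreds of random
short sequences and on the smallest full design.

## The 8↔4-letter maps and eccentricity

`map_sequence` widens every region (maximal single-symbol run) by one base;
P/Q/X/Y regions become alternating runs as above.  An arc of a structure
over the mapped sequence is *eccentric* when its two home regions are not
complementary in the 8-letter view.  A stacked pair is eccentric under the
**generic** dialect when it straddles a region boundary on either side or
contains an eccentric arc; under the **prime** dialect (the default for
switch-lock' inputs) only when it contains an eccentric arc, since the
prime design's switch legitimately stacks across band junctions.

`map_structure` (Map′) sends each non-eccentric stacked pair, via its outer
arc's within-region coordinates, to one arc of the 8-letter sequence,
giving AC(Map′(S′)) = SAC(S′) − E with E the eccentric-stack count, and
E ≤ r − 1 (one boundary per eccentric stack, r regions).  Positions are
1-based from the left within each region; the right endpoint maps to the
(j−1)-st base of its region — j-th for unwidened switch regions under the
prime dialect.  One consequence worth stating: Map′ of the prime *initial*
structure is the 8-letter initial structure minus the single innermost
intra-switch arc, because a helix of m arcs has only m−1 stacks.  The
identity AC = SAC − E still holds exactly, and the lock bands map
arc-for-arc.  Map′ is defined on structures, not pathways: consecutive
pathway steps can collapse under the map, so no step-wise image is claimed.

## Barrier-ascent stochastics

The ascent of a barrier of size k (removing a complete k-arc band) is
modelled by four discrete chains over bases A_1..A_k / Ā_k..Ā_1, absorbing
at the empty structure, one move per time unit:

* **distinct-arc**: only partner arcs (A_i, Ā_i); adding has propensity α,
  removing 1/α, so with i arcs removed P(re-add) = iα²/(iα² + k − i).
* **distinct-stack**: same geometry; propensity α^s for an addition forming
  s new stacked pairs (s ∈ {0,1,2}), α^{−s} for removals.
* **uniform-stack**: any A_i may pair any Ā_j without crossings.
* **alternating-stack**: as uniform plus parity i ≡ j (mod 2); implemented
  for completeness and exercised by invariant tests.

α > 1 is the propensity rate favouring pairing; the package default in the
examples is 1.5–2, the range where ascent times are measurable yet strongly
exponential in k.  The distinct-arc chain reduces to a birth-death walk on
the number of removed arcs; the exact expected absorption time T_0 is
computed three independent ways in `markov` (forward d-recurrence,
falling-factorial closed form for each d_j, tridiagonal elimination of the
hitting-time system) and bracketed by 2(α²+1)^{k−1} − 2 + k ≤ T_0 ≤
2k(α²+1)^{k−1} − k.  Simulated means over 1000-run experiments (the
experiment size used throughout) agree with T_0 to within a few standard
errors for k ≤ 8.

Numerical note: the hitting-time linear system has condition number of
order T_0 itself — about (α²+1)^{k−1} — so beyond k ≈ 10 *no* double-
precision solve can reach 1e−9 relative accuracy regardless of pivoting or
sweep direction (we measured ~4e−3 relative error at k = 15, α = 3 for a
double-precision Thomas sweep).  The tridiagonal elimination therefore runs
in exact rational arithmetic by default (a float α converts exactly), with
a float mode retained for timing comparison.  The d-recurrence, by
contrast, is all positive multiply-adds and is accurate to O(k·ε) in
floats.

Reproducibility: experiment run r uses child seed `seed + r`, recorded per
row in CSV output, so any single run can be replayed.  When numba is
available the distinct-arc batch simulator is jit-compiled with its own
(legacy np.random) generator; the per-run Python path uses
`numpy.random.default_rng`.  Within one installation both are exactly
reproducible from the seed; the two paths are not bit-identical to each
other.

## Brute-force oracles and flood fill

`landscape` holds the deliberately exponential machinery: structure
enumeration (length cap 24 by default), brute-force MAC/MSAC, a random
structure sampler (shuffled candidate arcs, acceptance probability 0.6 —
chosen to yield a broad mix of sparse and dense structures), and
`bounded_barrier_flood`, a BFS over single-arc moves restricted to
structures with E ≥ E(start) − cap.  The flood presumes the start is MFE so
the running maximum along any path is E(start); it reports visited count,
energy floor, and target reachability.  Exceeding a visit limit raises an
error distinct from "not reachable" — truncated searches never masquerade
as exhaustive ones.

## Synthetic inputs and what the tests do and do not show

Every fixture is generated by the design module or sampled with seeded
generators; there are no external datasets.  Test grids run k ≤ 5, A ≤ 8,
B ≤ 6 (pathway constructors), sequences ≤ 14 nt (enumeration oracles), and
k ≤ 8 with 1000 runs per cell (simulations) — sizes at which exact
enumeration and exact analytics exist, chosen so the whole suite verifies
closed-form claims rather than sampling large instances.  Passing tests
certify the combinatorial claims of the abstract models.  They say nothing
about real RNA: pseudoknots, inter-molecular binding, loop penalties and
sequence-dependent stack energies are all outside the models, and the
designs are known to be fragile under them (e.g. initial and target lock
bands could pseudoknot with each other).  The package is a verification and
exploration tool for the abstract designs, not a predictor of wet-lab
behaviour.

## Known limitations

* `four_letter_mapped` parameters are accepted by `DesignParams` for
  completeness of the flavour tag, but the mapped-design pathway (barrier
  k+3) has no constructor; the prime design supersedes it and the generic
  map is available for arbitrary sequences via `map_sequence`.
* No general minimum-barrier pathway search is provided at scale; the flood
  fill is exact but exponential and capped.
* The stack-based ascent models are simulation-only; no closed-form hitting
  times are known for them.
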