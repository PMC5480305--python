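"""Build a switch-lock molecule and inspect its designed structures.

The design has a switch (A bands of k base pairs that can sit in a "left"
or "right" position) followed by a lock (B wide center bands).  The initial
and target structures share no intra-switch arcs yet have the same arc
count, which equals the maximum arc count of the sequence: both are
minimum-free-energy structures under the arc-count model.
"""

from switchlock import (DesignParams, build_switch_lock, initial_structure,
                        max_arc_count, target_structure, to_dot_bracket)

params = DesignParams(k=2, A=4, B=2)
seq, regions = build_switch_lock(params)

print(f"switch-lock(k={params.k}, A={params.A}, B={params.B})")
print(f"sequence ({len(seq)} nt):")
print(" ", seq.symbols)
print("regions:", " ".join(f"{r.label}:{r.symbol}^{r.width}" for r in regions))

init, target = initial_structure(params), target_structure(params)
print("initial :", to_dot_bracket(init))
print("target  :", to_dot_bracket(target))

mac = max_arc_count(seq)
print(f"MAC = {mac}; AC(initial) = {init.arc_count()}; "
      f"AC(target) = {target.arc_count()}")
print("-> both designed structures attain the maximum arc count:"
      " they are MFE, so any pathway between them must climb a barrier.")
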