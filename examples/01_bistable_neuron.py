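"""A single neuron with an excitatory chemical self-loop.

Sweeps the self-synapse weight and shows the fold from one fixed point (a
quiescent cell) to three (quiescent / unstable intermediate / depolarized
plateau): the minimal circuit that can hold a bistable membrane state.
"""

import numpy as np

from wormcircuit import CircuitModel, bifurcation_sweep, find_fixed_points


def self_loop(w: float) -> CircuitModel:
    return CircuitModel(names=("N",), W=[[w]], G=[[0.0]], tau=1.0, theta=0.5, k=20.0)


trace = bifurcation_sweep(self_loop, np.linspace(0.0, 3.0, 16), box=(-1.0, 3.0),
                          n_starts=40, seed=0)
print("self-weight w -> number of fixed points")
for w, c in zip(trace.values, trace.counts):
    print(f"  w = {w:4.1f}   {c}")
lo, hi = trace.transition_intervals()[0]
print(f"the 1 -> 3 fold happens between w = {lo:.1f} and w = {hi:.1f}")

fps = find_fixed_points(self_loop(2.0), box=(-1.0, 3.0), n_starts=40, seed=0)
print("\nfixed points at w = 2 (x, stability):")
for p in sorted(fps.points, key=lambda p: p.x[0]):
    print(f"  x = {p.x[0]:8.5f}   {p.stability}")
print(
    "\nThe two stable roots are the quiescent and plateau potentials; the\n"
    "intermediate root is the separatrix between their attraction domains."
)
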