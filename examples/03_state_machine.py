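"""The attractor-based finite state machine of the command circuit.

Each stimulus protocol sets one left/right neuron pair to 1 (everything else
at the starting state) and lets the circuit relax; the attraction domain in
which the perturbed state lands decides the next state.  Activating AVB or
PVC drives the circuit to the forward state, activating AVA, AVD or AVE to
the backward state.
"""

from wormcircuit import (
    StimulusProtocol,
    build_state_machine,
    command_circuit_fixture,
    find_fixed_points,
)
from wormcircuit.connectome import command_state_index

model = command_circuit_fixture()
fps = find_fixed_points(model, box=(-3.0, 3.0), n_starts=500, seed=0)
protocols = [
    StimulusProtocol(cls, (cls + "L", cls + "R"), amplitude=1.0)
    for cls in ("AVB", "PVC", "AVA", "AVD", "AVE")
]
sm = build_state_machine(model, fps, protocols)

names = {1: "forward", 2: "backward", 3: "quiescent"}
pretty = {
    lab: names[command_state_index(p.x, model)]
    for lab, p in zip(sm.states, fps.stable_points)
}
print("from state    activate    next state")
for (state, proto), target in sorted(sm.transitions.items()):
    print(f"{pretty[state]:12s}  {proto:8s}    {pretty[target]}")
print(
    "\nFrom the quiescent state, AVB/PVC activation ends forward and\n"
    "AVA/AVD/AVE activation ends backward; an established moving state is\n"
    "hysteretic -- a single-pair nudge cannot flip it.  PVC and AVD never\n"
    "appear in a fixed point themselves; they act by steering the circuit\n"
    "into the attraction domain of their section's state."
)
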