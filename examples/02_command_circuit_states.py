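"""The three activity states of the forward/backward command circuit.

Solves the packaged 10-neuron circuit (AVB, PVC, AVA, AVD, AVE pairs) and
prints its stable fixed points: the forward state (AVB active), the backward
state (AVA/AVE active, AVD mildly depolarized) and the quiescent state.
"""

from wormcircuit import command_circuit_fixture, find_fixed_points
from wormcircuit.connectome import command_state_index

model = command_circuit_fixture()
fps = find_fixed_points(model, box=(-3.0, 3.0), n_starts=500, seed=0)

print(f"{len(fps)} roots found, {len(fps.stable_points)} of them stable attractors\n")
names = {1: "forward", 2: "backward", 3: "quiescent"}
cols = sorted(fps.stable_points, key=lambda p: command_state_index(p.x, model))
header = "neuron   " + "".join(
    f"{names[command_state_index(p.x, model)]:>11s}" for p in cols
)
print(header)
for i, nm in enumerate(model.names):
    print(f"{nm:8s}" + "".join(f"{p.rounded[i]:11.1f}" for p in cols))
print(
    "\nValues are relative membrane potentials (model units, threshold 0.5):\n"
    "a state is 'active' for a neuron when its value exceeds the threshold."
)
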