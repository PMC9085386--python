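# wormcircuit

Fixed-point-attractor analysis of small neuronal circuits, built around the
*C. elegans* forward/backward command circuit.

Many *C. elegans* interneurons (AVA, AVB, AVE, RIM, ...) hold bistable
membrane states, and the animal's locomotion switches between a long-lived
forward state and brief reversals. `wormcircuit` links that behavior to
circuit wiring through the attractor structure of a nonlinear rate model: it
finds all fixed points of a signed, weighted circuit, classifies their
stability, estimates attraction domains, assembles an attractor-based finite
state machine driven by stimulus protocols, screens connectomes for the
recurrent motifs that make multistability possible, performs in-silico
ablations, and analyses locomotion speed traces (segmentation, event
statistics, bimodal speed fit) with a matching synthetic-trace generator.

It is a library first (see `examples/`), with a thin `wormcircuit` CLI for
the common pipelines.

## Model

Membrane potentials **x** (relative to rest, dimensionless) of an *n*-neuron
circuit evolve as

```
τ ẋ = (G − L − E) x + W σ(x − θ) + B u
```

where `W` is the signed chemical-synapse matrix (entry *(i, j)* = weight of
the synapse from neuron *j* onto neuron *i*; excitatory > 0, inhibitory < 0),
`G` the symmetric nonnegative gap-junction conductances with diagonal
column-sum matrix `L` (so `(G − L) x` is the electrical coupling
`Σ_l g_li (x_l − x_i)`), `E` the identity, `σ(v) = 1/(1 + e^{−kv})` the
synaptic sigmoid, and `B u` an external stimulus. All neurons share
`τ = 1`, threshold `θ = 0.5` and slope `k = 20` by default. Fixed points are
the solutions of

```
(G − L − E) x + W σ(x − θ) = 0
```

found by seeded multi-start root finding and classified by the eigenvalues of
the analytic Jacobian. Because `σ(−kθ) ≈ 0` at these parameters, a
near-zero (quiescent) fixed point always exists; multistability additionally
requires a positive feedback loop of excitatory chemical synapses
(`wormcircuit.check_sufficiency` tests exactly this predicate).

The packaged command-circuit fixture (`command_circuit_fixture()`) is a
10-neuron model of the AVBL/R, PVCL/R, AVAL/R, AVDL/R, AVEL/R circuit whose
weights follow the connectome's edge list and sign rules (excitatory within
the forward and backward sections, inhibitory between them); see
`docs/methods.md` for how the magnitudes were chosen.

## Worked example

```python
from wormcircuit import command_circuit_fixture, find_fixed_points

model = command_circuit_fixture()
fps = find_fixed_points(model, box=(-3, 3), n_starts=500, seed=0)
print(len(fps), "roots,", len(fps.stable_points), "stable")
```

Running `python examples/02_command_circuit_states.py` prints

```
5 roots found, 3 of them stable attractors

neuron       forward   backward  quiescent
AVBL            0.9       -1.2        0.0
AVBR            0.9       -1.2        0.0
PVCL           -0.2       -0.4       -0.0
PVCR           -0.2       -0.4       -0.0
AVAL           -0.8        1.4        0.0
AVAR           -0.8        1.4        0.0
AVDL           -0.3        0.3        0.0
AVDR           -0.3        0.3        0.0
AVEL           -0.6        1.1        0.0
AVER           -0.6        1.0        0.0
```

The three attractors are the circuit's behavioral states: *forward* (AVB pair
above the 0.5 threshold, everything else suppressed), *backward* (AVA and AVE
pairs active, AVD mildly depolarized below threshold) and *quiescent* (all
near zero — the pause/sleep state). The two extra roots are the saddles on
the basin boundaries between them. `examples/03_state_machine.py` then shows
that activating the AVB or PVC pair from rest drives the circuit into the
forward state while AVA, AVD or AVE activation drives it backward, and
`examples/04_ablation_screen.py` that deleting AVB destroys the forward
state, deleting AVA or AVE destroys the backward state, and AVD, PVC or all
gap junctions can be removed with all three states intact.

`examples/06_locomotion_analysis.py` runs the behavior pipeline on a
synthetic trace (100 000 frames at 10 Hz):

```
forward  : 93.30% of time, 377 events, mean duration 24.7 s
backward :  6.70% of time, 376 events, mean duration 1.8 s
fitted speed modes: forward +259.9 um/s (sd 77.4), backward -306.2 um/s (sd 66.8)
```

i.e. segmentation and the two-component Gaussian fit recover the generator's
speed modes and the strong forward-time bias.

## CLI

```
wormcircuit --fixture command --out out/ fixed-points
wormcircuit --fixture command --out out/ ablate --remove AVDL,AVDR
wormcircuit --out out/ --seed 1 behavior-sim
wormcircuit --out out/ behavior-fit out/speed_trace.csv
```

Subcommands: `fixed-points`, `motifs`, `basins`, `state-machine`, `ablate`,
`behavior-sim`, `behavior-fit`; all accept `--config` (YAML/JSON, validated,
unknown keys rejected), `--seed` and `--out`. Reports embed the seed and a
configuration hash, so identical invocations are byte-identical.

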