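# Methods

## The dynamical model

Each neuron is a graded-potential unit: `τ ẋ = (G − L − E) x + W σ(x − θ) + B u`,
with `σ(v) = 1/(1 + e^{−kv})`. The state `x` is the membrane potential
relative to rest in dimensionless model units; no millivolt scale is attached
because none is fixed by the available data. Chemical synapses act through
the presynaptic sigmoid (signed weights, |w| ≤ 1 in rule-built circuits);
gap junctions act as linear diffusive coupling `g_li (x_l − x_i)` with
symmetric nonnegative conductances. All neurons share `τ`, `θ` and `k`
(per-neuron overrides are rejected rather than silently ignored): the
circuits analysed here are homogeneous command-interneuron populations, and
the shared-parameter simplification is part of the model's definition, not a
numerical convenience. Defaults `τ = 1`, `θ = 0.5`, `k = 20`. Self gap
junctions are mathematically inert (`x_i − x_i = 0`) and are dropped from
dynamical models with a warning, but retained in `Connectome` objects because
the motif census counts them.

With `θ = 0.5` and `k = 20`, `σ(−kθ) = σ(−10) ≈ 4.5·10⁻⁵`, so a root of the
fixed-point equation always exists within `O(‖W‖·10⁻⁴)` of the origin — the
quiescent state — and it is linearly stable because `G − L` is negative
semidefinite and the sigmoid slope at `−θ` is negligible.

## Fixed-point solving

Fixed points solve `(G − L − E) x + W σ(x − θ) = 0` (τ cancels). The solver
runs Powell-hybrid root finding (scipy) with the analytic Jacobian from a
deterministic start set: a seeded Latin-hypercube sample of the search box
(default 500 starts, box `[−3, 3]ⁿ` — all observed coordinates lie well
inside) plus the origin and the box corners (all `2ⁿ` corners for `n ≤ 10`,
the `2n` single-axis extremes above that). Roots are kept when the residual
infinity norm is below `1e−9` and they lie in the box; roots closer than
`1e−3` (infinity norm) are merged keeping the smallest residual. The start
set is seeded, so a `FixedPointSet` is bit-reproducible per platform.

Stability is read off the Jacobian eigenvalues: *stable* (all real parts
negative), *unstable* (all positive), *saddle* (mixed). Real parts within
`1e−9` of zero are flagged marginal and resolved by perturb-and-relax
simulation. Reported coordinates are rounded to one decimal in tables; raw
values are always retained.

**Counting convention.** `find_fixed_points` returns every distinct root.
For one- and two-neuron motifs "number of fixed points" means exactly that
(e.g. three for a strong excitatory self-loop, including the unstable
intermediate root). Table-style screens and state reports for larger
circuits count *stable* fixed points (attractors): any smooth system with
three attractors necessarily carries additional saddles on its basin
boundaries, so "three fixed points" for the command circuit is a statement
about attractors — the solver indeed finds five roots there, two of them
saddles, and reports three. The quiescent point is included since it is
linearly stable in this model.

## Integration, basins, protocols

Trajectories are integrated with LSODA at `rtol = atol = 1e−8` (`k = 20`
makes the dynamics stiff near threshold); equilibration means
`‖ẋ‖∞ < 1e−7`. Basin estimation samples initial conditions uniformly in the
search box (seeded), relaxes each, and labels it by the stable fixed point
within 0.05 (infinity norm) of the terminal state — the radius is half the
one-decimal reporting resolution; non-convergent or unmatched samples are
counted as unresolved, so fractions plus unresolved sum to one exactly.

Stimulus protocols default to initial-condition mode: targeted neurons are
set to amplitude 1.0, all others to the starting state, and the circuit
relaxes with no input (the 0/1 activation-pattern convention; no stimulus
physics is specified beyond that). Sustained-input mode instead holds `B u`
on the targets for a fixed duration and then releases. Protocol runs are
deterministic — no noise is injected; stochastic switching is out of scope.
The state machine runs every (state, protocol) pair; unresolved outcomes
become flagged self-loops so the machine stays total and deterministic.

## Motifs and the positive-feedback predicate

The census counts four recurrent classes: chemical self-loops, self-loops
with both chemical and electrical edges, reciprocally connected pairs, and
reciprocal pairs sharing a gap junction. Classes are nested (the chem+gap
hits are a subset of the chem hits); exclusive counts are derivable by
subtraction.

The multistability predicate asks for a positive feedback loop dominated by
excitatory chemical synapses. Cycles are enumerated over the signed directed
graph (networkx, length-bounded); each gap junction contributes two opposed
positive arcs, but the degenerate 2-cycle made of one gap junction's own two
arcs is excluded — diffusive coupling alone cannot create multistability.
"Dominated by excitatory synapses" is read strictly: every chemical edge in
the witness loop must be excitatory. A lenient mode (`strict=False`) accepts
any positive sign product, which admits mutual inhibition
(`(−1)·(−1) = +1`); whether that configuration should count is genuinely
ambiguous, so both modes are exposed and the strict one is the default (all
worked examples of multistability here — self-loops, the AVA/AVB pairs — use
all-excitatory loops). The companion condition that weights can be adjusted
suitably is a statement about adjustability, reported as a note rather than
checked numerically.

## Ablation screens

Ablation deletes rows and columns of `W`, `G`, `B` (structural removal, as
in laser ablation), never clamps. Baseline attractors are matched across
conditions by supra-threshold activation pattern rather than coordinates —
coordinates drift when neurons are removed, activation patterns are the
state's identity. A baseline state whose active neurons are all ablated is
impaired by construction; the quiescent state survives every condition
because `x ≈ 0` remains a stable root of any reduced model.

## The command-circuit fixture

The fixture wires the ten command interneurons with the forward section
{AVBL/R, PVCL/R} and backward section {AVAL/R, AVDL/R, AVEL/R}. Edge
existence and direction follow the connectome (e.g. the only intra-pair AVE
chemical synapse runs AVER→AVEL; PVCL carries a chemical self-loop; AVA and
PVC share gap junctions); signs follow the section rule; intra-pair gap
conductances lie in [1, 2] and cross-section gaps are weaker.

Magnitudes were adjusted by hand within those constraints. The mechanical
count→weight map used by `build_circuit` (counts ≤ 2 → 0.1, linear to
saturation at 1.0 for counts ≥ 7) cannot by itself produce the observed
state structure — most starkly, the single AVBR→AVBL synapse would get
weight 0.1 and the AVB-active forward state could not sustain itself — so
the fixture treats the map as a guideline and the qualitative state
structure as the constraint, exactly the role weight adjustment plays in
this framework (condition (ii) of the multistability predicate). The
adjustment never creates, deletes, re-signs or re-types an edge. Load-bearing
choices: the AVB pair sustains itself (0.9 mutual); the AVA pair alone is
deliberately sub-threshold (0.45 mutual) so that the backward state requires
the AVE loop — this is what makes AVE ablation impair the backward state;
AVD and PVC cannot self-sustain (0.3-level recurrence) and instead funnel
activation into their section's state (AVD→AVA 0.45 each, PVC→AVB 0.5 each,
with PVC→AVB taken excitatory); cross-section inhibition is mutual and
asymmetric in the strengths observed to reproduce the sign structure of the
three states. The fixture ships as packaged JSON
(`wormcircuit/data/command_circuit.json`); `_build_command_circuit()` is the
readable edge-table source of that file, and a test asserts they agree.

Per-entry decimals of the resulting states are properties of these
hand-adjusted weights; analyses built on the fixture therefore assert
counts, signs and activation patterns, not specific decimals.

## Behavior generator and analysis

The generator emits a semi-Markov state sequence with exponential dwell
times and i.i.d. Gaussian per-frame speed noise around each state's mean.
Defaults are the reported local-search statistics: forward `N(+259.8,
77.79²)` μm/s occupying 93.36% of time, backward `N(−308.03, 62.79²)` at
6.64%. The backward mean dwell is 2 s (backward events last seconds); the
forward dwell follows from the occupancy ratio (≈ 28.1 s); frame rate 10 Hz
(a typical tracker rate; no rate is fixed by the data). With a target
occupancy the embedded chain switches into state *j* with probability
∝ `occupancy_j / dwell_j`, which for two states is strict alternation with
stationary time fractions equal to the target. Exponential dwells are the
simplest renewal process consistent with mean durations — a modeling choice;
real dwell distributions are heavier-tailed.

Segmentation classifies frames by sign with a configurable dead band
(default 0: pure sign classification; the pause mass is too small to
separate by default). The speed fit is sign-split by default — independent
Gaussian maximum likelihood on the positive and negative samples, matching
the convention of reporting separate forward/backward parameters; an EM
mixture mode (scikit-learn) is available and doubles as an independent
cross-check in the tests. Sign-splitting truncates each component at zero,
which biases the forward center by ≈ `σ_f φ(μ_f/σ_f)` ≈ 0.1 μm/s here —
negligible at these separations, and the reason the two methods agree.

What passing tests show, and don't: the pipeline provably recovers the
parameters of data generated by its own model (occupancy to ±1 point,
centers to ±10 μm/s at 10⁵ frames); real traces add autocorrelation, smooth
reversal kinematics and tracking noise the generator deliberately omits.

## Problem sizes and tolerances used in shipped analyses

Fixed-point solving uses 500 multi-starts for the 10-neuron circuit (plus
1024 corners) and 40–200 for the 1–2-neuron motifs; basin estimates use
300–4000 Monte-Carlo samples depending on dimension; behavior analyses use
10⁵-frame traces. These sizes give sampling errors several times smaller
than every tolerance asserted on them (e.g. forward-occupancy SE ≈ 0.35
points vs the ±1-point check; forward-center SE ≈ 0.25 μm/s vs ±10 μm/s).

## Known limitations

- Limit cycles and other non-fixed-point attractors are out of scope; the
  solver characterizes equilibria only.
- Basin geometry is summarized as Monte-Carlo fractions, not boundaries.
- The fixture's weight magnitudes are one admissible assignment, not an
  estimate of synaptic strengths; only its qualitative structure is meant.
- The sufficiency predicate is a structural screen: it is necessary-ish in
  practice but its converse is not checked (a satisfied predicate does not
  guarantee multistability at the given weights).
- Stimulus amplitudes/units are conventions (0/1 activation patterns), since
  no physical stimulus scale is specified for the protocols.
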