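"""Connectome IO, rule-based circuit construction, and structure deduction.

Adjacency CSV orientation: entry ``(i, j)`` of a count matrix is the number
of synapses from column neuron ``j`` onto row neuron ``i`` (postsynaptic
rows), matching the weight-matrix layout of :class:`~wormcircuit.model.CircuitModel`.

Weight-adjustment rules for turning synapse counts into signed weights:

1. chemical connections within a functional section are excitatory (positive),
   between sections inhibitory (negative);
2. chemical magnitudes are monotone in synapse count and capped at 1;
3. connections of only 1-2 synapses get a weak magnitude of about 0.1;
4. the gap conductance between the left/right partners of a class is large
   (1 to 2) to enforce their synchrony; gap junctions across sections are
   weaker than those within a section.

The packaged command-circuit fixture (10 neurons: AVBL/R, PVCL/R, AVAL/R,
AVDL/R, AVEL/R) follows the sign rules and the known edge list of the
connectome with manually adjusted magnitudes; see ``docs/methods.md`` for the
rationale and the exact values.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .errors import InvalidInputError, InvalidStructureError
from .model import CircuitModel
from .motifs import Connectome

__all__ = [
    "GroupAssignment",
    "AdjustmentRules",
    "StructureConstraint",
    "read_adjacency_csv",
    "build_circuit",
    "command_circuit_fixture",
    "command_circuit_groups",
    "deduce_structure_constraints",
    "constraint_holds",
]

COMMAND_NEURONS = (
    "AVBL", "AVBR", "PVCL", "PVCR", "AVAL", "AVAR", "AVDL", "AVDR", "AVEL", "AVER",
)


@dataclass
class GroupAssignment:
    """Functional section labels and left/right pairing of neurons."""

    sections: dict[str, str]  # neuron -> section label
    pairs: dict[str, str] = field(default_factory=dict)  # neuron -> partner

    def __post_init__(self):
        for a, b in list(self.pairs.items()):
            if self.pairs.get(b, a) != a:
                raise InvalidStructureError(f"pair map is not symmetric at {a}/{b}")
            self.pairs[b] = a

    def section(self, neuron: str) -> str:
        try:
            return self.sections[neuron]
        except KeyError:
            raise InvalidInputError(f"neuron {neuron!r} has no section assignment") from None

    def same_section(self, a: str, b: str) -> bool:
        return self.section(a) == self.section(b)

    def is_pair(self, a: str, b: str) -> bool:
        return self.pairs.get(a) == b


@dataclass
class AdjustmentRules:
    """Parameters of the count -> signed-weight map."""

    chem_max: float = 1.0
    chem_min: float = -1.0
    weak_weight: float = 0.1
    weak_count: int = 2  # counts <= weak_count map to weak_weight
    saturation_count: int = 7  # counts >= this reach the cap
    intra_pair_gap: float = 1.5  # within [1, 2]
    intra_section_gap_cap: float = 0.5
    cross_section_gap_cap: float = 0.3

    def chem_magnitude(self, count: int) -> float:
        """Piecewise-linear monotone map: {1,2} -> weak, saturating at the cap."""
        if count <= 0:
            return 0.0
        if count <= self.weak_count:
            return self.weak_weight
        if count >= self.saturation_count:
            return self.chem_max
        frac = (count - self.weak_count) / (self.saturation_count - self.weak_count)
        return self.weak_weight + frac * (self.chem_max - self.weak_weight)

    def gap_weight(self, count: int, is_pair: bool, same_section: bool) -> float:
        if count <= 0:
            return 0.0
        if is_pair:
            return self.intra_pair_gap
        cap = self.intra_section_gap_cap if same_section else self.cross_section_gap_cap
        return min(self.weak_weight * count, cap)


def read_adjacency_csv(chem_path, gap_path) -> Connectome:
    """Read paired chemical/gap neuron x neuron count matrices.

    Both files must be square with identical header-named neuron order; the
    gap matrix must be exactly symmetric (integer counts).  Self gap entries
    are dropped (inert).  Entry ``(i, j)`` is read as ``j -> i``.
    """
    chem = pd.read_csv(chem_path, index_col=0)
    gap = pd.read_csv(gap_path, index_col=0)
    for name, df in (("chemical", chem), ("gap", gap)):
        if df.shape[0] != df.shape[1]:
            raise InvalidStructureError(f"{name} matrix is not square: {df.shape}")
        if list(df.index) != list(df.columns):
            raise InvalidStructureError(f"{name} matrix rows and columns disagree")
    if list(chem.index) != list(gap.index):
        raise InvalidStructureError("chemical and gap matrices name different neurons")
    neurons = tuple(str(n) for n in chem.index)
    gv = gap.to_numpy(dtype=float)
    if not np.array_equal(gv, gv.T):
        bad = np.argwhere(gv != gv.T)[0]
        raise InvalidStructureError(
            f"gap matrix asymmetric at ({neurons[bad[0]]}, {neurons[bad[1]]})"
        )
    chem_edges: dict[tuple[str, str], dict] = {}
    cv = chem.to_numpy(dtype=float)
    for i in range(len(neurons)):
        for j in range(len(neurons)):
            if cv[i, j] != 0:
                chem_edges[(neurons[j], neurons[i])] = {"count": int(cv[i, j]), "sign": None}
    gap_edges: dict[tuple[str, str], int] = {}
    for i in range(len(neurons)):
        for j in range(i, len(neurons)):  # keep self gaps: census-relevant,
            if gv[i, j] != 0:  # dynamically inert (dropped at model build)
                gap_edges[tuple(sorted((neurons[i], neurons[j])))] = int(gv[i, j])
    return Connectome(neurons=neurons, chem=chem_edges, gap=gap_edges)


def build_circuit(
    connectome: Connectome,
    groups: GroupAssignment,
    rules: AdjustmentRules | None = None,
    tau: float = 1.0,
    theta: float = 0.5,
    k: float = 20.0,
) -> CircuitModel:
    """Signed, weighted circuit from synapse counts via the adjustment rules.

    Sign-safe by construction: the excitatory/inhibitory class of every
    chemical edge is decided solely by section co-membership, magnitudes never
    flip it, and no edge is created or destroyed.
    """
    rules = rules or AdjustmentRules()
    names = connectome.neurons
    for nm in names:
        groups.section(nm)  # raises on ungrouped neurons
    n = len(names)
    pos = {nm: i for i, nm in enumerate(names)}
    W = np.zeros((n, n))
    for (pre, post), attrs in connectome.chem.items():
        mag = rules.chem_magnitude(attrs["count"])
        sign = 1.0 if groups.same_section(pre, post) else -1.0
        W[pos[post], pos[pre]] = float(np.clip(sign * mag, rules.chem_min, rules.chem_max))
    G = np.zeros((n, n))
    for (a, b), count in connectome.gap.items():
        if a == b:
            continue
        w = rules.gap_weight(
            count, is_pair=groups.is_pair(a, b), same_section=groups.same_section(a, b)
        )
        G[pos[a], pos[b]] = G[pos[b], pos[a]] = w
    return CircuitModel(names=names, W=W, G=G, tau=tau, theta=theta, k=k)


def command_circuit_groups() -> GroupAssignment:
    """Forward/backward sections and L/R pairing of the command interneurons."""
    sections = {}
    for nm in ("AVBL", "AVBR", "PVCL", "PVCR"):
        sections[nm] = "forward"
    for nm in ("AVAL", "AVAR", "AVDL", "AVDR", "AVEL", "AVER"):
        sections[nm] = "backward"
    pairs = {"AVBL": "AVBR", "PVCL": "PVCR", "AVAL": "AVAR", "AVDL": "AVDR", "AVEL": "AVER"}
    return GroupAssignment(sections=sections, pairs=pairs)


def command_circuit_fixture() -> CircuitModel:
    """The packaged 10-neuron forward/backward command circuit.

    Parameters tau=1, theta=0.5, k=20.  Its stable fixed points are the
    forward state (AVB pair active), the backward state (AVA and AVE pairs
    active, AVD mildly depolarized) and the quiescent state (all near zero).
    """
    ref = resources.files("wormcircuit.data").joinpath("command_circuit.json")
    with ref.open() as fh:
        return CircuitModel.from_dict(json.load(fh))


def _build_command_circuit() -> CircuitModel:
    """Construct the fixture from its edge table (source of the packaged JSON).

    Edge existence and signs follow the connectome and the section rule;
    magnitudes are manually adjusted (the count->magnitude map alone cannot
    sustain e.g. the AVB-active state, whose intra-pair chemical synapses are
    few) -- adjustment changes only weights, never the existence, the
    chemical/electrical type, or the excitatory/inhibitory class of an edge.
    """
    names = COMMAND_NEURONS
    pos = {nm: i for i, nm in enumerate(names)}
    W = np.zeros((10, 10))
    G = np.zeros((10, 10))

    def chem(pre, post, w):
        W[pos[post], pos[pre]] = w

    def gap(a, b, g):
        G[pos[a], pos[b]] = G[pos[b], pos[a]] = g

    # forward section (excitatory within)
    chem("AVBL", "AVBR", 0.9)
    chem("AVBR", "AVBL", 0.9)
    chem("PVCL", "PVCR", 0.3)
    chem("PVCR", "PVCL", 0.3)
    chem("PVCL", "PVCL", 0.1)  # PVCL chemical self-loop
    for pvc in ("PVCL", "PVCR"):
        for avb in ("AVBL", "AVBR"):
            chem(pvc, avb, 0.5)  # PVC -> AVB taken excitatory

    # backward section (excitatory within)
    chem("AVAL", "AVAR", 0.45)
    chem("AVAR", "AVAL", 0.45)
    chem("AVDL", "AVDR", 0.3)
    chem("AVDR", "AVDL", 0.3)
    chem("AVER", "AVEL", 0.1)  # the only intra-pair AVE chemical synapse
    for ave in ("AVEL", "AVER"):
        for ava in ("AVAL", "AVAR"):
            chem(ave, ava, 0.75)
    for ava in ("AVAL", "AVAR"):
        for ave in ("AVEL", "AVER"):
            chem(ava, ave, 0.5)
    for avd in ("AVDL", "AVDR"):
        for ava in ("AVAL", "AVAR"):
            chem(avd, ava, 0.45)
    for ava in ("AVAL", "AVAR"):
        for avd in ("AVDL", "AVDR"):
            chem(ava, avd, 0.15)

    # cross-section (inhibitory)
    for avb in ("AVBL", "AVBR"):
        for ava in ("AVAL", "AVAR"):
            chem(avb, ava, -0.5)
        for ave in ("AVEL", "AVER"):
            chem(avb, ave, -0.3)
        for avd in ("AVDL", "AVDR"):
            chem(avb, avd, -0.15)
    for ava in ("AVAL", "AVAR"):
        for avb in ("AVBL", "AVBR"):
            chem(ava, avb, -0.45)
        for pvc in ("PVCL", "PVCR"):
            chem(ava, pvc, -0.3)
    for ave in ("AVEL", "AVER"):
        for avb in ("AVBL", "AVBR"):
            chem(ave, avb, -0.15)
        for pvc in ("PVCL", "PVCR"):
            chem(ave, pvc, -0.15)
    for pvc in ("PVCL", "PVCR"):
        for ava in ("AVAL", "AVAR"):
            chem(pvc, ava, -0.3)

    # gap junctions (left/right pairs strong; AVA-PVC cross-section weak)
    gap("AVBL", "AVBR", 1.5)
    gap("AVAL", "AVAR", 1.5)
    gap("PVCL", "PVCR", 2.0)
    gap("AVDL", "AVDR", 1.0)
    gap("AVEL", "AVER", 1.0)
    gap("AVAL", "PVCL", 0.3)
    gap("AVAR", "PVCR", 0.3)

    return CircuitModel(names=names, W=W, G=G, tau=1.0, theta=0.5, k=20.0)


@dataclass(frozen=True)
class StructureConstraint:
    """One deduced structural requirement on the analyzed circuit."""

    kind: str
    subjects: tuple[str, ...]
    objects: tuple[str, ...]
    rationale: str


CONSTRAINT_KINDS = (
    "strong-reciprocal",
    "weak-or-gap-only",
    "mutual-inhibition",
    "basin-support-excitation-or-cross-inhibition",
    "state-suppresses-basin-of-opposite",
)


def deduce_structure_constraints(
    state_formers: dict[str, tuple[str, ...]],
    basin_formers: dict[str, tuple[str, ...]] | None = None,
    pairs: dict[str, str] | None = None,
) -> list[StructureConstraint]:
    """Structural requirements implied by the roles neurons play in the machine.

    ``state_formers`` maps a state label to the neuron group whose sustained
    activity constitutes that fixed point; ``basin_formers`` maps a state
    label to the group that enlarges its attraction domain without being
    active at the fixed point.  Emitted rules, deterministically ordered:

    - state-forming groups must be strongly recurrently connected
      (left/right partners strong-reciprocal);
    - basin-forming pairs are weakly connected or coupled only by gap
      junctions (no strong mutual chemical excitation);
    - groups forming opposite fixed points tend to inhibit each other;
    - basin formers either excite their own state formers or inhibit the
      opposite state formers;
    - state formers may inhibit the basin formers of the opposite state.
    """
    if not state_formers:
        raise InvalidInputError("state_formers must be nonempty")
    basin_formers = basin_formers or {}
    pairs = pairs or {}
    seen = set()
    for label, grp in list(state_formers.items()) + list(basin_formers.items()):
        for nm in grp:
            if nm in seen:
                raise InvalidInputError(f"neuron {nm} assigned to more than one role group")
            seen.add(nm)

    def pair_partition(group):
        """Split a group into L/R pairs (via the pair map) and singletons."""
        out, used = [], set()
        for nm in group:
            if nm in used:
                continue
            partner = pairs.get(nm)
            if partner in group and partner not in used:
                out.append(tuple(sorted((nm, partner))))
                used.update((nm, partner))
            else:
                out.append((nm,))
                used.add(nm)
        return out

    constraints: list[StructureConstraint] = []
    states = sorted(state_formers)

    for label in states:
        for unit in pair_partition(state_formers[label]):
            if len(unit) == 2:
                constraints.append(
                    StructureConstraint(
                        kind="strong-reciprocal",
                        subjects=unit,
                        objects=unit,
                        rationale=(
                            f"{unit[0]} and {unit[1]} must be strongly connected to "
                            f"each other to form the {label} fixed point"
                        ),
                    )
                )
    for label in sorted(basin_formers):
        for unit in pair_partition(basin_formers[label]):
            if len(unit) == 2:
                constraints.append(
                    StructureConstraint(
                        kind="weak-or-gap-only",
                        subjects=unit,
                        objects=unit,
                        rationale=(
                            f"{unit[0]} and {unit[1]} are not bistable, so they are "
                            "weakly connected or strongly connected only by gap junctions"
                        ),
                    )
                )
    for a_idx, a in enumerate(states):
        for b in states[a_idx + 1 :]:
            ga, gb = state_formers[a], state_formers[b]
            constraints.append(
                StructureConstraint(
                    kind="mutual-inhibition",
                    subjects=tuple(sorted(ga)),
                    objects=tuple(sorted(gb)),
                    rationale=(
                        f"neurons forming the opposing fixed points {a} and {b} "
                        "tend to inhibit each other"
                    ),
                )
            )
    for label in sorted(basin_formers):
        own = state_formers.get(label, ())
        others = tuple(
            sorted(nm for lab in states if lab != label for nm in state_formers[lab])
        )
        constraints.append(
            StructureConstraint(
                kind="basin-support-excitation-or-cross-inhibition",
                subjects=tuple(sorted(basin_formers[label])),
                objects=tuple(sorted(own)) + others,
                rationale=(
                    f"basin formers of {label} either excite its state formers "
                    f"({', '.join(sorted(own))}) or inhibit the opposite state formers"
                ),
            )
        )
        for other in states:
            if other == label:
                continue
            constraints.append(
                StructureConstraint(
                    kind="state-suppresses-basin-of-opposite",
                    subjects=tuple(sorted(state_formers[other])),
                    objects=tuple(sorted(basin_formers[label])),
                    rationale=(
                        f"state formers of {other} may inhibit the basin formers "
                        f"of the opposite state {label}"
                    ),
                )
            )
    return constraints


def constraint_holds(
    c: StructureConstraint,
    model: CircuitModel,
    strong_chem: float = 0.4,
    strong_gap: float = 1.0,
) -> bool:
    """Check a deduced constraint against a concrete weight matrix.

    "Strong" means a mutual chemical weight of at least ``strong_chem`` in both
    directions or a gap conductance of at least ``strong_gap``.
    """
    W, names = model.W, model.names

    def w(pre, post):
        return W[names.index(post), names.index(pre)]

    def g(a, b):
        return model.G[names.index(a), names.index(b)]

    if c.kind == "strong-reciprocal":
        a, b = c.subjects
        return g(a, b) >= strong_gap or min(w(a, b), w(b, a)) >= strong_chem
    if c.kind == "weak-or-gap-only":
        a, b = c.subjects
        return min(w(a, b), w(b, a)) < strong_chem + 0.1
    if c.kind == "mutual-inhibition":
        fwd = any(w(a, b) < 0 for a in c.subjects for b in c.objects)
        rev = any(w(b, a) < 0 for a in c.subjects for b in c.objects)
        return fwd and rev
    if c.kind == "basin-support-excitation-or-cross-inhibition":
        return any(
            w(a, b) > 0 or any(w(a, o) < 0 for o in c.objects)
            for a in c.subjects
            for b in c.objects
        )
    if c.kind == "state-suppresses-basin-of-opposite":
        return any(w(a, b) < 0 for a in c.subjects for b in c.objects)
    raise InvalidInputError(f"unknown constraint kind {c.kind!r}")


def command_state_index(x: np.ndarray, model: CircuitModel) -> int:
    """Conventional state index of a command-circuit fixed point.

    1 = forward (AVB pair supra-threshold), 2 = backward (AVA and/or AVE
    supra-threshold), 3 = quiescent (no neuron supra-threshold).  Returns 0
    for any other activation pattern.
    """
    from .fixed_points import activation_pattern

    pat = activation_pattern(np.asarray(x, dtype=float), model)
    if not pat:
        return 3
    if {"AVBL", "AVBR"} & pat:
        return 1
    if {"AVAL", "AVAR", "AVEL", "AVER"} & pat:
        return 2
    return 0
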