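"""Motif census and positive-feedback screening of connectomes.

Recurrent micro-structures — chemical self-loops and reciprocally connected
pairs, with or without an accompanying gap junction — are the candidate
substrates of bistability.  A sufficiency condition for a signed motif to
admit multiple fixed points is (i) the presence of at least one positive
feedback loop dominated by excitatory chemical synapses and (ii) suitably
adjusted weights; this module checks condition (i) as a graph predicate and
reports condition (ii) as a note only (it is a statement about adjustability,
not about a given weight assignment).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .errors import InvalidInputError
from .model import CircuitModel

__all__ = [
    "Connectome",
    "MotifCensus",
    "FeedbackLoop",
    "scan_bistability_motifs",
    "enumerate_feedback_loops",
    "check_sufficiency",
]


@dataclass
class Connectome:
    """Directed chemical edges and undirected gap edges with synapse counts.

    ``chem`` maps ``(pre, post)`` to ``{"count": int, "sign": +1/-1 or None}``;
    ``gap`` maps an unordered pair (stored as a sorted tuple) to a count.
    """

    neurons: tuple[str, ...]
    chem: dict[tuple[str, str], dict]
    gap: dict[tuple[str, str], int]

    def __post_init__(self):
        self.neurons = tuple(self.neurons)
        known = set(self.neurons)
        for (a, b), attrs in self.chem.items():
            if a not in known or b not in known:
                raise InvalidInputError(f"chemical edge ({a}, {b}) names unknown neuron")
            if attrs.get("count", 1) < 1:
                raise InvalidInputError(f"chemical edge ({a}, {b}) has count < 1")
        fixed = {}
        for pair, count in self.gap.items():
            a, b = sorted(pair)
            if a not in known or b not in known:
                raise InvalidInputError(f"gap edge ({a}, {b}) names unknown neuron")
            if count < 1:
                raise InvalidInputError(f"gap edge ({a}, {b}) has count < 1")
            fixed[(a, b)] = fixed.get((a, b), 0) + count
        self.gap = fixed

    def has_gap(self, a: str, b: str) -> bool:
        return tuple(sorted((a, b))) in self.gap


@dataclass
class MotifCensus:
    """Counts of the four bistability-capable motif classes.

    Classes are *nested*: every chem+gap self-loop neuron is also counted in
    the plain chemical self-loop class, and likewise for pairs (exclusive
    counts are derivable by subtraction).
    """

    self_chem: list[str]
    self_chem_gap: list[str]
    pair_chem: list[tuple[str, str]]
    pair_chem_gap: list[tuple[str, str]]

    @property
    def counts(self) -> dict[str, int]:
        return {
            "self_chem": len(self.self_chem),
            "self_chem_gap": len(self.self_chem_gap),
            "pair_chem": len(self.pair_chem),
            "pair_chem_gap": len(self.pair_chem_gap),
        }

    def to_table(self) -> str:
        c = self.counts
        lines = [
            "motif class\tcount",
            f"chemical self-loop\t{c['self_chem']}",
            f"chemical+gap self-loop\t{c['self_chem_gap']}",
            f"reciprocal chemical pair\t{c['pair_chem']}",
            f"reciprocal chemical pair + gap\t{c['pair_chem_gap']}",
        ]
        return "\n".join(lines) + "\n"


def scan_bistability_motifs(connectome: Connectome) -> MotifCensus:
    """Census the four recurrent motif classes of a connectome.

    self_chem: neurons with >= 1 chemical self-loop; self_chem_gap: those that
    also carry a gap self-edge; pair_chem: unordered pairs with chemical edges
    in both directions; pair_chem_gap: such pairs that also share a gap edge.
    """
    self_chem = sorted(a for (a, b) in connectome.chem if a == b)
    self_chem_gap = [a for a in self_chem if connectome.has_gap(a, a)]
    directed = set(connectome.chem)
    pair_chem = sorted(
        {
            tuple(sorted((a, b)))
            for (a, b) in directed
            if a != b and (b, a) in directed
        }
    )
    pair_chem_gap = [p for p in pair_chem if connectome.has_gap(*p)]
    return MotifCensus(
        self_chem=self_chem,
        self_chem_gap=self_chem_gap,
        pair_chem=pair_chem,
        pair_chem_gap=pair_chem_gap,
    )


@dataclass
class FeedbackLoop:
    """A simple directed cycle with edge types and signs."""

    nodes: tuple[str, ...]
    edges: list[dict]  # {"pre", "post", "type": "chem"|"gap", "sign": +1/-1}
    sign_product: int
    excitatory_only: bool

    def __len__(self):
        return len(self.nodes)


def _signed_digraph(circuit) -> nx.MultiDiGraph:
    """Signed directed graph of a circuit; gap edges expand to two opposed +1 arcs."""
    g = nx.MultiDiGraph()
    if isinstance(circuit, CircuitModel):
        g.add_nodes_from(circuit.names)
        for i in range(circuit.n):
            for j in range(circuit.n):
                w = circuit.W[i, j]
                if w != 0.0:
                    g.add_edge(
                        circuit.names[j],
                        circuit.names[i],
                        type="chem",
                        sign=1 if w > 0 else -1,
                    )
        for i in range(circuit.n):
            for j in range(i + 1, circuit.n):
                if circuit.G[i, j] != 0.0:
                    a, b = circuit.names[i], circuit.names[j]
                    g.add_edge(a, b, type="gap", sign=1)
                    g.add_edge(b, a, type="gap", sign=1)
        return g
    if isinstance(circuit, Connectome):
        g.add_nodes_from(circuit.neurons)
        for (a, b), attrs in circuit.chem.items():
            sign = attrs.get("sign")
            if sign not in (1, -1):
                raise InvalidInputError(
                    f"chemical edge ({a}, {b}) carries no sign; feedback-loop "
                    "analysis requires signed edges"
                )
            g.add_edge(a, b, type="chem", sign=sign)
        for (a, b) in circuit.gap:
            if a == b:
                continue
            g.add_edge(a, b, type="gap", sign=1)
            g.add_edge(b, a, type="gap", sign=1)
        return g
    raise InvalidInputError(f"unsupported circuit type {type(circuit)!r}")


def enumerate_feedback_loops(circuit, max_len: int) -> list[FeedbackLoop]:
    """All simple directed cycles of length <= ``max_len`` in the signed graph.

    Accepts a signed :class:`Connectome` or a :class:`CircuitModel` (signs
    from the weight matrix).  Gap junctions contribute a pair of opposed
    positive directed edges each.  The sign product multiplies chemical signs
    only (gap arcs count +1); ``excitatory_only`` is True when every chemical
    edge in the cycle is excitatory.
    """
    if max_len < 1:
        raise InvalidInputError("max_len must be >= 1")
    g = _signed_digraph(circuit)
    loops: list[FeedbackLoop] = []
    seen: set[tuple] = set()
    for cycle in nx.simple_cycles(g, length_bound=max_len):
        # expand parallel-edge choices along the node cycle
        steps = []
        ok = True
        for idx, a in enumerate(cycle):
            b = cycle[(idx + 1) % len(cycle)]
            data = g.get_edge_data(a, b)
            if not data:
                ok = False
                break
            steps.append([(a, b, d) for d in data.values()])
        if not ok:
            continue
        for combo in itertools.product(*steps):
            # a 2-cycle made of the two arcs of ONE gap junction is not a
            # feedback loop through chemistry-or-coupling, it is the same
            # physical edge traversed twice; keep it only if types differ or
            # the circuit genuinely has reciprocal arcs -- both arcs being
            # 'gap' between the same pair is the degenerate case we drop.
            if (
                len(cycle) == 2
                and all(step[2]["type"] == "gap" for step in combo)
            ):
                continue
            key = (tuple(cycle), tuple(s[2]["type"] for s in combo), tuple(s[2]["sign"] for s in combo))
            if key in seen:
                continue
            seen.add(key)
            edges = [
                {"pre": a, "post": b, "type": d["type"], "sign": d["sign"]}
                for (a, b, d) in combo
            ]
            chem_signs = [e["sign"] for e in edges if e["type"] == "chem"]
            sign_product = int(np.prod(chem_signs)) if chem_signs else 1
            excitatory_only = all(s > 0 for s in chem_signs) and bool(chem_signs)
            loops.append(
                FeedbackLoop(
                    nodes=tuple(cycle),
                    edges=edges,
                    sign_product=sign_product,
                    excitatory_only=excitatory_only,
                )
            )
    loops.sort(key=lambda l: (len(l), l.nodes))
    return loops


def check_sufficiency(
    circuit, max_len: int | None = None, strict: bool = True
) -> dict:
    """Check the positive-feedback condition for multistability.

    strict mode (default): satisfied iff some cycle has a positive sign product
    AND is composed exclusively of excitatory chemical synapses (plus possibly
    gap arcs).  Lenient mode accepts any positive-sign-product loop (e.g.
    mutual inhibition, whose 2-cycle has sign (+1) = (-1)(-1)).  The shortest
    witness is returned.  The companion weight-adjustability condition is not
    checked numerically; it is reported as a note.
    """
    if max_len is None:
        n = circuit.n if isinstance(circuit, CircuitModel) else len(circuit.neurons)
        max_len = n
    loops = enumerate_feedback_loops(circuit, max_len=max_len)
    if strict:
        hits = [l for l in loops if l.sign_product > 0 and l.excitatory_only]
    else:
        hits = [l for l in loops if l.sign_product > 0]
    witness = min(hits, key=len) if hits else None
    return {
        "satisfied": witness is not None,
        "witness": witness,
        "mode": "strict" if strict else "lenient",
        "note": (
            "weight-adjustability condition (ii) is assumed, not checked: "
            "it concerns the existence of admissible weights, not this assignment"
        ),
    }
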