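"""In-silico ablation and gap-junction removal screens.

Ablation is structural: the neuron's rows and columns are deleted from W, G
and B (a laser-ablated cell is gone, and per-condition reports are over the
surviving neurons only).  Gap removal zeroes symmetric conductance entries
and leaves W untouched.  The screen re-solves fixed points per condition and
matches surviving attractors to the baseline ones by supra-threshold
activation pattern — coordinates drift under ablation, activation patterns do
not.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidInputError
from .fixed_points import (
    FixedPointSet,
    activation_pattern,
    find_fixed_points,
)
from .model import CircuitModel

__all__ = [
    "AblationSpec",
    "AblationReport",
    "ablate_neurons",
    "remove_gap_junctions",
    "ablation_screen",
]


@dataclass(frozen=True)
class AblationSpec:
    """One perturbation condition; specs compose (neurons + gaps)."""

    label: str
    remove_neurons: frozenset[str] = frozenset()
    remove_gap_all: bool = False
    remove_gap_pairs: frozenset[tuple[str, str]] = frozenset()

    def __init__(
        self,
        label: str,
        remove_neurons=(),
        remove_gap_all: bool = False,
        remove_gap_pairs=(),
    ):
        object.__setattr__(self, "label", label)
        object.__setattr__(self, "remove_neurons", frozenset(remove_neurons))
        object.__setattr__(self, "remove_gap_all", bool(remove_gap_all))
        object.__setattr__(
            self,
            "remove_gap_pairs",
            frozenset(tuple(sorted(p)) for p in remove_gap_pairs),
        )

    def apply(self, model: CircuitModel) -> CircuitModel:
        out = model
        if self.remove_gap_all:
            out = remove_gap_junctions(out, all_gaps=True)
        if self.remove_gap_pairs:
            out = remove_gap_junctions(out, pairs=self.remove_gap_pairs)
        if self.remove_neurons:
            out = ablate_neurons(out, self.remove_neurons)
        return out


def ablate_neurons(model: CircuitModel, names) -> CircuitModel:
    """Delete neurons structurally; remaining neuron order is preserved."""
    names = set(names)
    if not names:
        raise InvalidInputError("ablation set is empty")
    unknown = sorted(names - set(model.names))
    if unknown:
        raise InvalidInputError(f"unknown neurons: {', '.join(unknown)}")
    keep = [i for i, nm in enumerate(model.names) if nm not in names]
    if not keep:
        raise InvalidInputError("ablating every neuron leaves an empty circuit")
    idx = np.asarray(keep)
    return CircuitModel(
        names=tuple(model.names[i] for i in keep),
        W=model.W[np.ix_(idx, idx)],
        G=model.G[np.ix_(idx, idx)],
        tau=model.tau,
        theta=model.theta,
        k=model.k,
        B=np.eye(len(keep)),
    )


def remove_gap_junctions(
    model: CircuitModel, pairs=None, all_gaps: bool = False
) -> CircuitModel:
    """Zero the named symmetric gap entries (or the whole of G)."""
    G = model.G.copy()
    if all_gaps:
        G[:] = 0.0
    elif pairs:
        for a, b in pairs:
            i, j = model.index(a), model.index(b)
            if G[i, j] == 0.0:
                raise InvalidInputError(f"no gap junction between {a} and {b}")
            G[i, j] = G[j, i] = 0.0
    else:
        raise InvalidInputError("specify pairs or all_gaps=True")
    return model.with_params(G=G)


@dataclass
class ConditionResult:
    spec: AblationSpec
    model: CircuitModel | None
    fps: FixedPointSet | None
    survival: dict[str, bool]  # baseline state label -> survives?
    patterns: dict[str, frozenset[str]]  # condition fp label -> supra-threshold set
    error: str | None = None


@dataclass
class AblationReport:
    """Per-condition fixed-point sets with baseline-state survival flags."""

    baseline: FixedPointSet
    baseline_patterns: dict[str, frozenset[str]]
    results: list[ConditionResult]

    def survival_matrix(self) -> dict[str, dict[str, bool]]:
        return {r.spec.label: dict(r.survival) for r in self.results}

    def to_dict(self) -> dict:
        return {
            "baseline_states": {
                lab: sorted(pat) for lab, pat in self.baseline_patterns.items()
            },
            "conditions": [
                {
                    "label": r.spec.label,
                    "error": r.error,
                    "n_stable": len(r.fps.stable_points) if r.fps else None,
                    "survival": dict(r.survival),
                }
                for r in self.results
            ],
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    def to_table(self) -> str:
        """Table-1-style TSV: neurons x (condition, fixed point), one decimal."""
        lines = []
        header = ["neuron"]
        cols = []  # (condition label, fp label, values-by-name dict)
        for r in self.results:
            if r.fps is None:
                continue
            for i, p in enumerate(r.fps.stable_points):
                vals = dict(zip(r.model.names, p.rounded))
                cols.append((r.spec.label, f"fp{i + 1}", vals))
                header.append(f"{r.spec.label}:fp{i + 1}")
        lines.append("\t".join(header))
        for nm in self.baseline_names:
            row = [nm]
            for _, _, vals in cols:
                row.append(f"{vals[nm]:.1f}" if nm in vals else "none")
            lines.append("\t".join(row))
        return "\n".join(lines) + "\n"

    @property
    def baseline_names(self) -> tuple[str, ...]:
        return self._names

    _names: tuple[str, ...] = ()


def _label_stable(fps: FixedPointSet, model: CircuitModel) -> dict[str, frozenset[str]]:
    return {
        f"fp{i + 1}": activation_pattern(p.x, model)
        for i, p in enumerate(fps.stable_points)
    }


def ablation_screen(
    model: CircuitModel,
    conditions: list[AblationSpec],
    box=(-3.0, 3.0),
    n_starts: int = 500,
    seed: int = 0,
) -> AblationReport:
    """Re-solve fixed points under each condition and flag impaired baseline states.

    A baseline attractor survives a condition when some stable fixed point of
    the perturbed circuit reproduces its supra-threshold activation pattern
    restricted to the surviving neurons; a baseline pattern that loses all of
    its active neurons to ablation is impaired by construction.  The quiescent
    state (empty pattern) is matched by the near-zero attractor, which exists
    under every condition.  Per-condition solver failures are recorded and the
    screen continues.
    """
    if not conditions:
        raise InvalidInputError("conditions list is empty")
    baseline_fps = find_fixed_points(model, box=box, n_starts=n_starts, seed=seed)
    baseline_patterns = _label_stable(baseline_fps, model)

    results = []
    for spec in conditions:
        try:
            sub = spec.apply(model)
            fps = find_fixed_points(sub, box=box, n_starts=n_starts, seed=seed)
            patterns = _label_stable(fps, sub)
            survival = {}
            for lab, pat in baseline_patterns.items():
                restricted = pat & set(sub.names)
                if pat and not restricted:
                    survival[lab] = False  # every active neuron was ablated
                else:
                    survival[lab] = restricted in patterns.values()
            results.append(
                ConditionResult(
                    spec=spec, model=sub, fps=fps, survival=survival, patterns=patterns
                )
            )
        except InvalidInputError:
            raise
        except Exception as exc:  # noqa: BLE001 - per-condition fault isolation
            results.append(
                ConditionResult(
                    spec=spec,
                    model=None,
                    fps=None,
                    survival={lab: False for lab in baseline_patterns},
                    patterns={},
                    error=str(exc),
                )
            )
    report = AblationReport(
        baseline=baseline_fps, baseline_patterns=baseline_patterns, results=results
    )
    report._names = model.names
    return report
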