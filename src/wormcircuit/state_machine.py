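"""Attraction domains and the attractor-based finite state machine.

Stable fixed points are the machine's states; a stimulus protocol (an
initial-condition "activation pattern" or a sustained input) is a transition
trigger: it displaces the circuit, the circuit relaxes, and the basin in which
the displaced state landed determines the next state.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidInputError, InvalidParameterError
from .fixed_points import FixedPointSet
from .model import CircuitModel, equilibrate, simulate

__all__ = [
    "StimulusProtocol",
    "BasinEstimate",
    "StateMachine",
    "estimate_attraction_domains",
    "run_protocol",
    "build_state_machine",
    "match_fixed_point",
]

#: infinity-norm radius within which a terminal state is identified with a fixed point
MATCH_RADIUS = 0.05
UNRESOLVED = "unresolved"


@dataclass
class StimulusProtocol:
    """A stimulus applied to named target neurons.

    mode "initial-condition": targets are set to ``amplitude`` and the rest of
    the state to the baseline, then the circuit relaxes with no input (the
    0/1 activation-pattern convention).  mode "sustained-input": ``B u`` is
    held at ``amplitude`` on the targets for ``duration`` time units, then
    released and the circuit relaxes.
    """

    name: str
    targets: tuple[str, ...]
    mode: str = "initial-condition"
    amplitude: float = 1.0
    duration: float | None = None

    def __post_init__(self):
        self.targets = tuple(self.targets)
        if self.mode not in ("initial-condition", "sustained-input"):
            raise InvalidParameterError(f"unknown protocol mode {self.mode!r}")
        if not np.isfinite(self.amplitude):
            raise InvalidParameterError("amplitude must be finite")
        if self.mode == "sustained-input" and not (self.duration and self.duration > 0):
            raise InvalidParameterError("sustained-input mode requires duration > 0")


def _stable_labels(fps: FixedPointSet) -> dict[str, np.ndarray]:
    return {f"fp{i + 1}": p.x for i, p in enumerate(fps.stable_points)}


def match_fixed_point(
    x: np.ndarray, fps: FixedPointSet, radius: float = MATCH_RADIUS
) -> str:
    """Label of the stable fixed point within ``radius`` (inf-norm) of ``x``."""
    for label, ref in _stable_labels(fps).items():
        if np.max(np.abs(x - ref)) < radius:
            return label
    return UNRESOLVED


@dataclass
class BasinEstimate:
    """Monte-Carlo attraction-domain fractions for the stable fixed points."""

    labels: list[str]
    samples: np.ndarray  # (n_samples, n) initial conditions
    assignments: list[str]  # per-sample terminal label (may be "unresolved")
    box: np.ndarray
    seed: int

    @property
    def counts(self) -> dict[str, int]:
        out = {lab: 0 for lab in self.labels + [UNRESOLVED]}
        for a in self.assignments:
            out[a] += 1
        return out

    @property
    def fractions(self) -> dict[str, float]:
        n = len(self.assignments)
        return {lab: c / n for lab, c in self.counts.items()}

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            n = self.samples.shape[1]
            fh.write(",".join(f"x{i}" for i in range(n)) + ",label\n")
            for row, lab in zip(self.samples, self.assignments):
                fh.write(",".join(f"{v:.6g}" for v in row) + f",{lab}\n")


def estimate_attraction_domains(
    model: CircuitModel,
    fps: FixedPointSet,
    box=None,
    n_samples: int = 1000,
    seed: int = 0,
    match_radius: float = MATCH_RADIUS,
    max_time: float = 200.0,
) -> BasinEstimate:
    """Sample initial conditions uniformly in ``box`` and label their attractor.

    Non-convergent or unmatched samples are counted as unresolved, never
    raised.  The box defaults to the fixed-point search box.
    """
    if not fps.stable_points:
        raise InvalidInputError("need at least one stable fixed point")
    if n_samples < 1:
        raise InvalidParameterError("n_samples must be >= 1")
    box = np.asarray(box, dtype=float) if box is not None else fps.box
    if box.shape == (2,):
        box = np.tile(box, (model.n, 1))
    rng = np.random.default_rng(seed)
    samples = rng.uniform(box[:, 0], box[:, 1], size=(n_samples, model.n))
    assignments = []
    for x0 in samples:
        try:
            traj = equilibrate(model, x0, max_time=max_time)
            lab = (
                match_fixed_point(traj.terminal_state, fps, match_radius)
                if traj.converged
                else UNRESOLVED
            )
        except Exception:  # noqa: BLE001 - non-convergence is data, not failure
            lab = UNRESOLVED
        assignments.append(lab)
    return BasinEstimate(
        labels=list(_stable_labels(fps)),
        samples=samples,
        assignments=assignments,
        box=box,
        seed=seed,
    )


def run_protocol(
    model: CircuitModel,
    start: str,
    protocol: StimulusProtocol,
    fps: FixedPointSet,
    match_radius: float = MATCH_RADIUS,
    max_time: float = 200.0,
) -> str:
    """Apply a protocol from the basin of ``start`` and report where the circuit lands.

    ``start`` may be a stable-fixed-point label ("fp1", ...) or "zero" for the
    origin.  Returns the matched terminal label, or "unresolved" (with a
    warning) if the terminal state matches no stable fixed point.
    """
    labels = _stable_labels(fps)
    if start == "zero":
        baseline = np.zeros(model.n)
    elif start in labels:
        baseline = labels[start].copy()
    else:
        raise InvalidInputError(f"unknown start state {start!r}")

    idx = [model.index(nm) for nm in protocol.targets]
    if protocol.mode == "initial-condition":
        x0 = baseline.copy()
        x0[idx] = protocol.amplitude
        traj = equilibrate(model, x0, max_time=max_time)
    else:
        u_on = np.zeros(model.B.shape[1])
        if model.B.shape != (model.n, model.n) or not np.allclose(
            model.B, np.eye(model.n)
        ):
            raise InvalidInputError(
                "sustained-input protocols require the identity input matrix B"
            )
        u_on[idx] = protocol.amplitude
        dur = float(protocol.duration)

        def input_fn(t):
            return u_on if t < dur else np.zeros_like(u_on)

        traj = simulate(model, baseline, input_fn=input_fn, t_end=dur + max_time, dt=1.0)

    lab = match_fixed_point(traj.terminal_state, fps, match_radius)
    if lab == UNRESOLVED:
        warnings.warn(
            f"protocol {protocol.name!r} from {start!r} ended at an unmatched "
            f"state (max|x|={np.max(np.abs(traj.terminal_state)):.3g})",
            stacklevel=2,
        )
    return lab


@dataclass
class StateMachine:
    """Deterministic transition table over stable fixed-point states."""

    states: list[str]
    transitions: dict[tuple[str, str], str]  # (state, protocol name) -> state
    protocols: dict[str, StimulusProtocol]
    warnings: list[tuple[str, str]] = field(default_factory=list)

    def next_state(self, state: str, protocol: str) -> str:
        return self.transitions[(state, protocol)]

    def to_dict(self) -> dict:
        return {
            "states": self.states,
            "protocols": {
                name: {
                    "targets": list(p.targets),
                    "mode": p.mode,
                    "amplitude": p.amplitude,
                    "duration": p.duration,
                }
                for name, p in self.protocols.items()
            },
            "transitions": [
                {"from": s, "protocol": p, "to": t}
                for (s, p), t in sorted(self.transitions.items())
            ],
            "unresolved_self_loops": [list(w) for w in self.warnings],
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    def to_dot(self) -> str:
        lines = ["digraph state_machine {"]
        for s in self.states:
            lines.append(f'  "{s}";')
        for (s, p), t in sorted(self.transitions.items()):
            style = ' style=dashed' if (s, p) in self.warnings else ""
            lines.append(f'  "{s}" -> "{t}" [label="{p}"{style}];')
        lines.append("}")
        return "\n".join(lines) + "\n"


def build_state_machine(
    model: CircuitModel,
    fps: FixedPointSet,
    protocols: list[StimulusProtocol],
    match_radius: float = MATCH_RADIUS,
    max_time: float = 200.0,
) -> StateMachine:
    """Run every (state, protocol) pair and assemble the transition table.

    Unresolved outcomes become self-loops flagged in ``warnings`` (the machine
    stays deterministic and total).
    """
    if not fps.stable_points:
        raise InvalidInputError("need at least one stable fixed point")
    states = list(_stable_labels(fps))
    registry = {p.name: p for p in protocols}
    transitions = {}
    warn: list[tuple[str, str]] = []
    for s in states:
        for name, proto in registry.items():
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                target = run_protocol(
                    model, s, proto, fps, match_radius=match_radius, max_time=max_time
                )
            if target == UNRESOLVED:
                target = s
                warn.append((s, name))
            transitions[(s, name)] = target
    return StateMachine(
        states=states, transitions=transitions, protocols=registry, warnings=warn
    )
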