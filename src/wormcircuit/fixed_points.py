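"""Fixed-point location and stability analysis.

A fixed point is a solution of ``(G - L - E) x + W sigma(x - theta) = 0``
(the time constant drops out).  Because the sigmoid is steep (``k = 20`` by
default) the equation can have several isolated roots; they are located by
multi-start Newton-type root finding from a seeded low-discrepancy start set
plus canonical starts (the origin and the search-box corners), deduplicated,
and classified by the eigenvalues of the analytic Jacobian.

Stability vocabulary: *stable* = all eigenvalue real parts negative,
*unstable* = all positive, *saddle* = mixed signs.  Eigenvalues with
``|Re| < 1e-9`` are flagged marginal and resolved by a simulation probe.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import optimize
from scipy.stats import qmc

from .errors import InvalidInputError, InvalidParameterError
from .model import CircuitModel, equilibrate, jacobian, sigmoid

__all__ = [
    "FixedPoint",
    "FixedPointSet",
    "BifurcationTrace",
    "find_fixed_points",
    "classify_stability",
    "bifurcation_sweep",
    "activation_pattern",
]

log = logging.getLogger(__name__)

DEFAULT_BOX_HALFWIDTH = 3.0
DEFAULT_N_STARTS = 500
DEFAULT_SOLVER_TOL = 1e-9
DEFAULT_DEDUP_TOL = 1e-3
MARGINAL_TOL = 1e-9


@dataclass
class FixedPoint:
    """A single root of the fixed-point equation with its local analysis."""

    x: np.ndarray
    residual: float
    eigenvalues: np.ndarray
    stability: str  # "stable" | "unstable" | "saddle"
    marginal: bool = False

    @property
    def rounded(self) -> np.ndarray:
        """Coordinates rounded to one decimal (reporting convention)."""
        return np.round(self.x, 1)

    def __repr__(self):  # pragma: no cover - cosmetic
        return f"FixedPoint({np.round(self.x, 3)}, {self.stability})"


@dataclass
class FixedPointSet:
    """Deduplicated fixed points of one model under one solver configuration."""

    points: list[FixedPoint]
    box: np.ndarray  # shape (n, 2)
    n_starts: int
    solver_tol: float
    dedup_tol: float
    seed: int

    def __len__(self):
        return len(self.points)

    def __iter__(self):
        return iter(self.points)

    @property
    def stable_points(self) -> list[FixedPoint]:
        """The attractors: linearly stable fixed points only."""
        return [p for p in self.points if p.stability == "stable"]

    def to_dict(self) -> dict:
        return {
            "n_points": len(self.points),
            "n_stable": len(self.stable_points),
            "seed": self.seed,
            "points": [
                {
                    "x": p.x.tolist(),
                    "rounded": p.rounded.tolist(),
                    "residual": p.residual,
                    "stability": p.stability,
                    "eigenvalues_real": np.real(p.eigenvalues).tolist(),
                }
                for p in self.points
            ],
        }

    def to_table(self, names: Sequence[str]) -> str:
        """Neurons x fixed-points TSV, one decimal, stable points first."""
        pts = sorted(self.points, key=lambda p: p.stability != "stable")
        header = "neuron\t" + "\t".join(
            f"fp{i + 1}({p.stability})" for i, p in enumerate(pts)
        )
        rows = [header]
        for i, name in enumerate(names):
            rows.append(name + "\t" + "\t".join(f"{p.rounded[i]:.1f}" for p in pts))
        return "\n".join(rows) + "\n"


def _residual_fn(model: CircuitModel):
    lin = model.G - model.L - np.eye(model.n)

    def fun(x):
        return lin @ x + model.W @ sigmoid(x - model.theta, model.k)

    def jac(x):
        s = sigmoid(x - model.theta, model.k)
        return lin + model.W * (model.k * s * (1.0 - s))[np.newaxis, :]

    return fun, jac


def _normalize_box(box, n: int) -> np.ndarray:
    box = np.asarray(box, dtype=float)
    if box.shape == (2,):
        box = np.tile(box, (n, 1))
    if box.shape != (n, 2):
        raise InvalidParameterError(f"box must have shape ({n}, 2), got {box.shape}")
    if not np.all(np.isfinite(box)) or not np.all(box[:, 0] < box[:, 1]):
        raise InvalidParameterError("box bounds must be finite with low < high")
    return box


def _start_points(box: np.ndarray, n_starts: int, seed: int) -> np.ndarray:
    """Seeded Latin-hypercube starts plus the origin and the box corners."""
    n = box.shape[0]
    sampler = qmc.LatinHypercube(d=n, seed=seed)
    starts = qmc.scale(sampler.random(n_starts), box[:, 0], box[:, 1])
    canon = [np.zeros(n)]
    if n <= 10:
        corners = np.array(
            np.meshgrid(*[box[i] for i in range(n)], indexing="ij")
        ).reshape(n, -1).T
    else:  # too many corners to enumerate: take the 2n single-axis extremes
        corners = np.vstack([np.diag(box[:, 0]), np.diag(box[:, 1])])
    return np.vstack([starts, canon, corners])


def classify_stability(model: CircuitModel, x: np.ndarray) -> tuple[str, np.ndarray, bool]:
    """Label a fixed point by the Jacobian eigenvalue real parts.

    Returns ``(label, eigenvalues, marginal)``.  Marginal eigenvalues
    (``|Re| < 1e-9``) trigger a simulation probe: the point is perturbed and
    relaxed, and counted stable only if the trajectory returns to it.
    """
    eig = np.linalg.eigvals(jacobian(model, x))
    re = np.real(eig)
    marginal = bool(np.any(np.abs(re) < MARGINAL_TOL))
    if marginal:
        rng = np.random.default_rng(0)
        probe = x + 1e-3 * rng.standard_normal(model.n)
        back = equilibrate(model, probe, max_time=100.0).terminal_state
        label = "stable" if np.max(np.abs(back - x)) < 1e-2 else "saddle"
        return label, eig, True
    if np.all(re < 0):
        return "stable", eig, False
    if np.all(re > 0):
        return "unstable", eig, False
    return "saddle", eig, False


def find_fixed_points(
    model: CircuitModel,
    box=( -DEFAULT_BOX_HALFWIDTH, DEFAULT_BOX_HALFWIDTH),
    n_starts: int = DEFAULT_N_STARTS,
    solver_tol: float = DEFAULT_SOLVER_TOL,
    dedup_tol: float = DEFAULT_DEDUP_TOL,
    seed: int = 0,
) -> FixedPointSet:
    """Locate all fixed points inside ``box`` by multi-start root finding.

    Starts are a seeded Latin-hypercube set of size ``n_starts`` plus the
    origin and the box corners, so the result is deterministic for a given
    ``(model, box, n_starts, seed)``.  Converged roots are kept if their
    infinity-norm residual is below ``solver_tol`` and they lie inside the box
    (small margin); roots closer than ``dedup_tol`` are merged, keeping the
    smallest residual.  Finding no root is not an error (empty set, logged).
    """
    if not np.all(np.isfinite(model.W)):
        raise InvalidInputError("model contains non-finite weights")
    if n_starts < 1:
        raise InvalidParameterError("n_starts must be >= 1")
    box = _normalize_box(box, model.n)
    fun, jac = _residual_fn(model)

    roots: list[tuple[np.ndarray, float]] = []
    for x0 in _start_points(box, n_starts, seed):
        sol = optimize.root(fun, x0, jac=jac, method="hybr", tol=1e-12)
        if not sol.success:
            continue
        res = float(np.max(np.abs(fun(sol.x))))
        if res >= solver_tol:
            continue
        margin = 1e-6 * (1.0 + np.abs(box).max())
        if np.any(sol.x < box[:, 0] - margin) or np.any(sol.x > box[:, 1] + margin):
            continue
        roots.append((sol.x, res))

    # greedy dedup, best residual first
    roots.sort(key=lambda t: t[1])
    kept: list[tuple[np.ndarray, float]] = []
    for x, res in roots:
        if all(np.max(np.abs(x - y)) >= dedup_tol for y, _ in kept):
            kept.append((x, res))
    kept.sort(key=lambda t: tuple(np.round(t[0], 6)))

    points = []
    for x, res in kept:
        label, eig, marginal = classify_stability(model, x)
        points.append(
            FixedPoint(x=x, residual=res, eigenvalues=eig, stability=label, marginal=marginal)
        )
    if not points:
        log.warning(
            "no fixed point converged inside the box (n=%d, n_starts=%d)",
            model.n,
            n_starts,
        )
    return FixedPointSet(
        points=points,
        box=box,
        n_starts=n_starts,
        solver_tol=solver_tol,
        dedup_tol=dedup_tol,
        seed=seed,
    )


def activation_pattern(x: np.ndarray, model: CircuitModel) -> frozenset[str]:
    """Names of neurons whose potential exceeds the chemical threshold."""
    return frozenset(model.names[i] for i in np.where(x > model.theta)[0])


@dataclass
class BifurcationTrace:
    """Fixed-point counts and coordinates along a one-parameter sweep."""

    parameter: str
    values: np.ndarray
    counts: list[int | None]  # None where the builder failed
    branches: list[list[np.ndarray]]
    errors: dict[int, str] = field(default_factory=dict)

    def transition_intervals(self) -> list[tuple[float, float]]:
        """Parameter intervals across which the fixed-point count changes."""
        out = []
        for i in range(len(self.values) - 1):
            a, b = self.counts[i], self.counts[i + 1]
            if a is not None and b is not None and a != b:
                out.append((float(self.values[i]), float(self.values[i + 1])))
        return out


def bifurcation_sweep(
    builder: Callable[[float], CircuitModel],
    values,
    box=(-DEFAULT_BOX_HALFWIDTH, DEFAULT_BOX_HALFWIDTH),
    n_starts: int = DEFAULT_N_STARTS,
    seed: int = 0,
    parameter: str = "w",
) -> BifurcationTrace:
    """Sweep a model-builder over a parameter grid, solving fixed points at each value.

    Builder failures are recorded per value and the sweep continues.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise InvalidParameterError("need at least two grid values")
    counts: list[int | None] = []
    branches: list[list[np.ndarray]] = []
    errors: dict[int, str] = {}
    for i, v in enumerate(values):
        try:
            model = builder(float(v))
            fps = find_fixed_points(model, box=box, n_starts=n_starts, seed=seed)
        except Exception as exc:  # noqa: BLE001 - per-value fault isolation
            errors[i] = str(exc)
            counts.append(None)
            branches.append([])
            continue
        counts.append(len(fps))
        branches.append([p.x for p in fps])
    return BifurcationTrace(
        parameter=parameter, values=values, counts=counts, branches=branches, errors=errors
    )
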