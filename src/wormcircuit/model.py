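"""Non-linear rate model of a neuronal microcircuit.

The membrane potential :math:`x_i` of each neuron (relative to rest,
dimensionless model units) evolves as

.. math::

    \\tau \\dot x = (G - L - E)\\,x + W\\,\\sigma(x - \\theta) + B\\,u

where ``W`` is the signed chemical-synapse weight matrix (entry ``(i, j)`` is
the weight of the synapse from presynaptic neuron ``j`` onto postsynaptic
neuron ``i``; positive = excitatory, negative = inhibitory), ``G`` is the
symmetric nonnegative gap-junction conductance matrix, ``L`` the diagonal
matrix of gap-conductance column sums (so that ``(G - L)x`` implements the
electrical coupling ``sum_l g_li (x_l - x_i)``), ``E`` the identity,
``sigma(v) = 1/(1 + exp(-k v))`` the synaptic activation sigmoid, and ``B u``
an external stimulus.  All neurons share the time constant ``tau``, threshold
``theta`` and sigmoid slope ``k``.

No physical voltage scale is attached to ``x``; the model operates entirely in
relative units.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.special import expit

from .errors import (
    IntegrationDivergedError,
    InvalidInputError,
    InvalidParameterError,
    InvalidStructureError,
)

__all__ = [
    "CircuitModel",
    "Trajectory",
    "sigmoid",
    "gap_laplacian",
    "dynamics_rhs",
    "jacobian",
    "simulate",
    "equilibrate",
]

#: default equilibration tolerance on the infinity norm of the right-hand side
CONVERGENCE_TOL = 1e-7


def sigmoid(v, k: float):
    """Synaptic activation ``sigma(v) = 1 / (1 + exp(-k v))``.

    Numerically stable for arbitrarily large ``|k*v|`` (delegates to
    :func:`scipy.special.expit`).  ``k`` must be strictly positive.
    """
    if k <= 0:
        raise InvalidParameterError(f"sigmoid slope k must be > 0, got {k}")
    return expit(k * np.asarray(v, dtype=float))


def gap_laplacian(G: np.ndarray) -> np.ndarray:
    """Diagonal matrix ``L = diag(sum_k g_k1, ..., sum_k g_kn)`` of column sums of ``G``.

    ``(G - L) x`` then equals the gap-junction current vector with components
    ``sum_l g_li (x_l - x_i)``; it vanishes identically on uniform states.
    """
    G = np.asarray(G, dtype=float)
    if G.ndim != 2 or G.shape[0] != G.shape[1]:
        raise InvalidStructureError(f"gap matrix must be square, got shape {G.shape}")
    if not np.allclose(G, G.T, rtol=0.0, atol=1e-12):
        raise InvalidStructureError("gap matrix must be symmetric")
    return np.diag(G.sum(axis=0))


@dataclass
class CircuitModel:
    """A signed, weighted neuronal circuit with shared dynamical parameters.

    Parameters
    ----------
    names
        Ordered neuron identifiers (length ``n``).
    W
        ``n x n`` chemical weight matrix; entry ``(i, j)`` is the synapse from
        ``j`` onto ``i``.
    G
        ``n x n`` symmetric nonnegative gap-junction conductances.  Diagonal
        entries (self gap junctions) are mathematically inert and dropped with
        a warning.
    tau, theta, k
        Shared time constant (> 0), chemical threshold, and sigmoid slope (> 0).
    B
        ``n x m`` input matrix mapping stimuli ``u`` onto neurons.  Defaults to
        the identity (each neuron independently drivable).
    """

    names: tuple[str, ...]
    W: np.ndarray
    G: np.ndarray
    tau: float = 1.0
    theta: float = 0.5
    k: float = 20.0
    B: np.ndarray | None = None

    def __post_init__(self):
        self.names = tuple(str(s) for s in self.names)
        n = len(self.names)
        if len(set(self.names)) != n:
            raise InvalidStructureError("neuron names must be unique")
        self.W = np.array(self.W, dtype=float)
        self.G = np.array(self.G, dtype=float)
        if self.W.shape != (n, n):
            raise InvalidStructureError(f"W must be {n}x{n}, got {self.W.shape}")
        if self.G.shape != (n, n):
            raise InvalidStructureError(f"G must be {n}x{n}, got {self.G.shape}")
        if not np.all(np.isfinite(self.W)) or not np.all(np.isfinite(self.G)):
            raise InvalidInputError("W and G must be finite")
        if not np.allclose(self.G, self.G.T, rtol=0.0, atol=1e-12):
            raise InvalidStructureError("G must be symmetric")
        if np.any(self.G < 0):
            raise InvalidStructureError("gap conductances must be nonnegative")
        if np.any(np.diag(self.G) != 0):
            warnings.warn(
                "self gap junctions are inert (x_l - x_i = 0) and were dropped",
                stacklevel=2,
            )
            self.G = self.G.copy()
            np.fill_diagonal(self.G, 0.0)
        if not self.tau > 0:
            raise InvalidParameterError(f"tau must be > 0, got {self.tau}")
        if not self.k > 0:
            raise InvalidParameterError(f"k must be > 0, got {self.k}")
        if self.B is None:
            self.B = np.eye(n)
        else:
            self.B = np.array(self.B, dtype=float)
            if self.B.ndim != 2 or self.B.shape[0] != n:
                raise InvalidStructureError(
                    f"B must have {n} rows, got shape {self.B.shape}"
                )

    # -- derived quantities -------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.names)

    @property
    def L(self) -> np.ndarray:
        return gap_laplacian(self.G)

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise InvalidInputError(f"unknown neuron {name!r}") from None

    def with_params(self, **kwargs) -> "CircuitModel":
        """Copy of the model with selected fields replaced."""
        return replace(self, **kwargs)

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "names": list(self.names),
            "W": self.W.tolist(),
            "G": self.G.tolist(),
            "tau": self.tau,
            "theta": self.theta,
            "k": self.k,
            "B": self.B.tolist(),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_dict(cls, d: dict) -> "CircuitModel":
        return cls(
            names=tuple(d["names"]),
            W=np.array(d["W"], dtype=float),
            G=np.array(d["G"], dtype=float),
            tau=float(d["tau"]),
            theta=float(d["theta"]),
            k=float(d["k"]),
            B=np.array(d["B"], dtype=float) if d.get("B") is not None else None,
        )

    @classmethod
    def from_json(cls, path) -> "CircuitModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class Trajectory:
    """Sampled solution of the network ODE."""

    times: np.ndarray
    states: np.ndarray  # shape (len(times), n)
    converged: bool

    @property
    def terminal_state(self) -> np.ndarray:
        return self.states[-1]


def _check_state(model: CircuitModel, x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.shape != (model.n,):
        raise InvalidInputError(
            f"state has shape {x.shape}, expected ({model.n},)"
        )
    return x


def dynamics_rhs(
    model: CircuitModel, x, u: np.ndarray | None = None
) -> np.ndarray:
    """Time derivative ``(1/tau)[(G - L - E)x + W sigma(x - theta) + B u]``."""
    x = _check_state(model, x)
    coupling = (model.G - model.L - np.eye(model.n)) @ x
    chem = model.W @ sigmoid(x - model.theta, model.k)
    drive = np.zeros(model.n)
    if u is not None:
        u = np.asarray(u, dtype=float)
        if u.shape != (model.B.shape[1],):
            raise InvalidInputError(
                f"input has shape {u.shape}, expected ({model.B.shape[1]},)"
            )
        drive = model.B @ u
    return (coupling + chem + drive) / model.tau


def jacobian(model: CircuitModel, x) -> np.ndarray:
    """Analytic Jacobian of :func:`dynamics_rhs` with respect to ``x``.

    ``J = (1/tau)[(G - L - E) + W diag(k sigma_j (1 - sigma_j))]`` with
    ``sigma_j = sigma(x_j - theta)``.
    """
    x = _check_state(model, x)
    s = sigmoid(x - model.theta, model.k)
    lin = model.G - model.L - np.eye(model.n)
    return (lin + model.W * (model.k * s * (1.0 - s))[np.newaxis, :]) / model.tau


def simulate(
    model: CircuitModel,
    x0,
    input_fn: Callable[[float], Sequence[float]] | None = None,
    t_end: float = 50.0,
    dt: float = 0.1,
    conv_tol: float = CONVERGENCE_TOL,
    rtol: float = 1e-8,
    atol: float = 1e-8,
) -> Trajectory:
    """Integrate the network ODE from ``x0``.

    Uses an adaptive stiff-capable integrator (LSODA); with slope ``k = 20``
    the sigmoid makes the system stiff near threshold.  Integration stops
    early once ``||rhs||_inf < conv_tol`` (equilibration), in which case
    ``converged`` is True.

    Raises
    ------
    IntegrationDivergedError
        If the state becomes non-finite; the failure time is reported.
    """
    if t_end <= 0 or dt <= 0:
        raise InvalidParameterError("t_end and dt must be > 0")
    x0 = _check_state(model, x0)

    def rhs(t, x):
        u = np.asarray(input_fn(t), dtype=float) if input_fn is not None else None
        return dynamics_rhs(model, x, u)

    def settled(t, x):
        return float(np.max(np.abs(rhs(t, x)))) - conv_tol

    settled.terminal = True
    settled.direction = -1

    t_eval = np.arange(0.0, t_end + 0.5 * dt, dt)
    sol = solve_ivp(
        rhs,
        (0.0, t_end),
        x0,
        method="LSODA",
        t_eval=t_eval,
        events=settled,
        rtol=rtol,
        atol=atol,
    )
    times = sol.t
    states = sol.y.T
    if sol.t_events[0].size:  # append the event point itself
        te = sol.t_events[0][0]
        if times.size == 0 or te > times[-1]:
            times = np.append(times, te)
            states = np.vstack([states, sol.y_events[0][0]])
    if not np.all(np.isfinite(states)):
        bad = np.where(~np.all(np.isfinite(states), axis=1))[0][0]
        raise IntegrationDivergedError(times[bad] if bad < times.size else t_end)
    if sol.status == -1:
        raise IntegrationDivergedError(times[-1] if times.size else 0.0)
    converged = bool(sol.t_events[0].size) or (
        float(np.max(np.abs(rhs(times[-1], states[-1])))) < conv_tol
    )
    return Trajectory(times=times, states=states, converged=converged)


def equilibrate(
    model: CircuitModel,
    x0,
    max_time: float = 200.0,
    conv_tol: float = CONVERGENCE_TOL,
) -> Trajectory:
    """Simulate with zero input until the state settles (or ``max_time``)."""
    return simulate(model, x0, input_fn=None, t_end=max_time, dt=1.0, conv_tol=conv_tol)
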