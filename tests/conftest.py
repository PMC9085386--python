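"""Shared fixtures: toy circuits, the command-circuit fixture, and oracles."""

import numpy as np
import pytest

from wormcircuit import CircuitModel, command_circuit_fixture, find_fixed_points


def one_neuron(w: float, theta: float = 0.5, k: float = 20.0, tau: float = 1.0) -> CircuitModel:
    """Single neuron with a chemical self-loop of weight w."""
    return CircuitModel(names=("N",), W=[[w]], G=[[0.0]], tau=tau, theta=theta, k=k)


def mutual_pair(w: float, g: float = 0.0) -> CircuitModel:
    """Two neurons coupled only by mutual chemical synapses of weight w."""
    return CircuitModel(names=("A", "B"), W=[[0.0, w], [w, 0.0]], G=[[0.0, g], [g, 0.0]])


def grid_scan_roots(f, lo: float, hi: float, step: float = 1e-3, refine: int = 60):
    """Independent 1-D root oracle: dense sign-change scan plus bisection."""
    xs = np.arange(lo, hi + step, step)
    vals = np.array([f(x) for x in xs])
    roots = []
    for i in range(len(xs) - 1):
        a, b = vals[i], vals[i + 1]
        if a == 0.0:
            roots.append(xs[i])
        elif a * b < 0:
            x0, x1 = xs[i], xs[i + 1]
            f0 = a
            for _ in range(refine):
                mid = 0.5 * (x0 + x1)
                fm = f(mid)
                if f0 * fm <= 0:
                    x1 = mid
                else:
                    x0, f0 = mid, fm
            roots.append(0.5 * (x0 + x1))
    if vals[-1] == 0.0:
        roots.append(xs[-1])
    return roots


@pytest.fixture(scope="session")
def command_model():
    return command_circuit_fixture()


@pytest.fixture(scope="session")
def command_fps(command_model):
    return find_fixed_points(command_model, box=(-3.0, 3.0), n_starts=500, seed=0)
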