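"""Exception hierarchy shared by all wormcircuit modules."""


class CircuitError(ValueError):
    """Base class for invalid circuit definitions or inputs."""


class InvalidParameterError(CircuitError):
    """A scalar model parameter is out of its admissible range."""


class InvalidStructureError(CircuitError):
    """A connection matrix violates a structural invariant (e.g. asymmetric gap matrix)."""


class InvalidInputError(CircuitError):
    """Runtime input (state, stimulus, neuron name, ...) is inconsistent with the model."""


class IntegrationDivergedError(RuntimeError):
    """Numerical integration produced a non-finite state."""

    def __init__(self, time: float):
        self.time = float(time)
        super().__init__(f"integration diverged (non-finite state) near t={time:g}")
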