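"""Exception hierarchy for the five-element Windkessel package."""


class ParameterError(ValueError):
    """A circuit, drive, or geometry parameter is outside its domain."""


class DegenerateParameterError(ParameterError):
    """A parameter combination needs the degenerate branch.

    Raised when C2*L2 = 0 is passed to a code path that divides by it;
    callers should use the algebraic L2 = 0 branch instead
    (:func:`windkessel5.integrate.simulate_degenerate_L2_zero`).
    """


class WrongBranchError(ParameterError):
    """The degenerate branch was requested with non-degenerate parameters."""


class ResonanceError(ValueError):
    """Drive and natural frequency coincide; the two-tone closed form
    (and the two-tone least-squares fit) is singular there because the
    secular, linearly growing resonant response is not modelled."""


class NumericalBlowupError(RuntimeError):
    """The time-stepper produced a non-finite value."""

    def __init__(self, node: int, time: float):
        self.node = node
        self.time = time
        super().__init__(
            f"non-finite value at node {node} (t = {time:g} s); "
            "the explicit scheme is unstable for this dt / natural frequency"
        )


class ConfigError(ValueError):
    """A run configuration key or value failed validation."""


class GeometryDomainWarning(UserWarning):
    """The aspect-ratio formula was evaluated outside its calibrated
    size-ratio domain [0, 1]."""
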