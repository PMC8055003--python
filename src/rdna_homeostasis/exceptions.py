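"""Package-specific exception types.

All domain-validation failures raise subclasses of :class:`ValueError`
so that callers can catch them generically; runtime failures (integration,
simulation, unconverged fits) subclass :class:`RuntimeError`.
"""


class ParameterError(ValueError):
    """Model parameters violate an invariant or admit no homeostatic state."""


class CalibrationError(ValueError):
    """The requested set point cannot be realised by any UAF concentration."""


class IntegrationError(RuntimeError):
    """ODE integration failed; the message names the time of failure."""


class SimulationError(RuntimeError):
    """Stochastic simulation failed (e.g. population extinct)."""

    def __init__(self, message: str, generation: int | None = None):
        super().__init__(message)
        self.generation = generation


class InsufficientDataError(ValueError):
    """Too few observations to attempt a fit."""


class IdentifiabilityError(ValueError):
    """The requested free-parameter set is not identifiable."""


class UnconvergedFitError(RuntimeError):
    """A prediction was requested from a fit that did not converge."""


class UnitMismatchError(ValueError):
    """Records mix incompatible measurement units."""


class ConfigError(ValueError):
    """Configuration file contains unknown sections or keys."""
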