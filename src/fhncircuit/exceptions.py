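"""Exception hierarchy for fhncircuit."""


class FHNCircuitError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(FHNCircuitError, ValueError):
    """A model parameter violates its validity constraints."""


class ConfigError(FHNCircuitError, ValueError):
    """A configuration file or preset name could not be interpreted."""


class ContractViolationError(FHNCircuitError, ValueError):
    """An operation was called with arguments outside its contract,
    e.g. a stability report requested at a voltage that is not a fixed
    point of the supplied drive current."""


class IntegrationError(FHNCircuitError, RuntimeError):
    """The ODE solver failed before reaching the requested end time.

    Attributes
    ----------
    last_time : float
        The last time the solver reached before failing.
    """

    def __init__(self, message: str, last_time: float):
        super().__init__(message)
        self.last_time = last_time


class InconclusiveOscillationError(FHNCircuitError, RuntimeError):
    """A trajectory matched none of the recognised oscillation patterns;
    usually fixed by integrating for a longer time span."""
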