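"""Exception types shared across the package."""


class OscperturbError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(OscperturbError, ValueError):
    """Invalid user input (bad state vector, parameter, or config value)."""


class UnknownTopologyError(OscperturbError, KeyError):
    """Requested 3-node topology id is not in the built-in registry."""


class UnknownModelError(OscperturbError, KeyError):
    """Requested catalog model id is not in the built-in catalog."""


class StructuralLinkError(OscperturbError, ValueError):
    """A link label does not address a structurally nonzero Jacobian element."""


class IntegrationError(OscperturbError, RuntimeError):
    """The ODE solver failed (stiffness breakdown, NaN state, ...)."""

    def __init__(self, message, parameter_set_id=None):
        super().__init__(message)
        self.parameter_set_id = parameter_set_id


class InsufficientCyclesError(OscperturbError, ValueError):
    """A trajectory contains too few oscillation peaks to measure."""


class NoOscillationError(OscperturbError, ValueError):
    """A trajectory is flat (no oscillation to measure)."""


class EmptySummaryError(OscperturbError, ValueError):
    """A pattern summary was requested over zero sustained results."""


class BudgetExhaustedError(OscperturbError, RuntimeError):
    """A sampling/search attempt budget ran out before the goal was met."""
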