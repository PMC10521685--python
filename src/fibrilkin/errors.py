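"""Exception hierarchy for fibrilkin.

All domain-level failures derive from :class:`FibrilkinError` so callers can
catch package errors without masking programming mistakes.
"""


class FibrilkinError(Exception):
    """Base class for all fibrilkin errors."""


class DomainError(FibrilkinError, ValueError):
    """An input value is outside the physically meaningful domain."""


class ConfigurationError(FibrilkinError, ValueError):
    """An option (e.g. a model-variant tag) is not recognised."""


class IntegrationError(FibrilkinError, RuntimeError):
    """The ODE solver failed to produce a trajectory."""


class FitConvergenceError(FibrilkinError, RuntimeError):
    """No optimisation start converged; carries the best partial result."""

    def __init__(self, message, partial_result=None):
        super().__init__(message)
        self.partial_result = partial_result


class NotSaturatedError(FibrilkinError, ValueError):
    """A kinetic curve has no detectable plateau, so sigmoid analysis is undefined."""


class NoFibrilsError(FibrilkinError, ValueError):
    """A fibril population is empty where per-fibril statistics were requested."""
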