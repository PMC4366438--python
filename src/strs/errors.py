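"""Exception hierarchy for the STRS model library."""

from __future__ import annotations


class STRSError(Exception):
    """Base class for all library-specific errors."""


class InvalidParameterError(STRSError, ValueError):
    """A rate, population size, proportion, or range violates its constraints."""


class InvalidForcingError(InvalidParameterError):
    """A repentance-rate forcing would be negative somewhere over its period."""


class IntegrationFailureError(STRSError, RuntimeError):
    """The ODE solver failed (e.g. step-size underflow).

    Carries ``last_good_time``, the last time the solver reached successfully.
    """

    def __init__(self, message: str, last_good_time: float | None = None):
        super().__init__(message)
        self.last_good_time = last_good_time


class InsufficientSpanError(STRSError, ValueError):
    """A requested averaging window is longer than the trajectory."""


class NoEndemicEquilibriumError(STRSError, ValueError):
    """Endemic equilibrium requested where it does not exist (Sabbath number > 1)."""


class BracketError(STRSError, ValueError):
    """A root-finding bracket does not contain a sign change."""


class ConvergenceError(STRSError, RuntimeError):
    """An iteration failed to reach its tolerance within the allotted cycles."""


class UnknownScenarioError(STRSError, KeyError):
    """A scenario name is not in the registry; the message lists valid names."""


class NotReachedError(STRSError, ValueError):
    """A trajectory never crosses the requested level within its horizon."""
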