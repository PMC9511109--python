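"""Exception hierarchy for model-contract violations.

All exceptions derive from :class:`PSMCEAError` so callers can catch the
package's failures in one clause; the subclasses distinguish domain errors
(bad parameter values), fitting failures and configuration problems.
"""


class PSMCEAError(Exception):
    """Base class for all errors raised by this package."""


class DomainError(PSMCEAError, ValueError):
    """A value is outside the mathematical domain of an operation.

    The message names the offending field.
    """


class NoMedianError(PSMCEAError):
    """The survival function never reaches 0.5 on the search bracket."""


class InsufficientEventsError(PSMCEAError):
    """Too few observed events to fit a parametric survival model."""


class ConvergenceError(PSMCEAError):
    """The likelihood optimizer failed to converge; carries diagnostics."""

    def __init__(self, message: str, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics


class FlatCurveError(PSMCEAError):
    """Digitized points are degenerate (all survival equal to one)."""


class IncomparableFitsError(PSMCEAError):
    """Model-selection candidates were fitted on different data."""


class ConfigurationError(PSMCEAError, ValueError):
    """A configuration key is unknown, unresolvable or invalid."""


class GridMismatchError(PSMCEAError):
    """A trace and a strategy were built on different cycle grids."""


class UndefinedICERError(PSMCEAError):
    """Incremental QALYs are numerically zero; the ICER is undefined."""
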