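"""Exception hierarchy for the taglobal package.

All errors raised by the library derive from :class:`TaglobalError` so that
callers (and the CLI) can catch everything from one base class.
"""


class TaglobalError(Exception):
    """Base class for all taglobal errors."""


class FormatError(TaglobalError):
    """A file does not conform to the expected layout (names the offender)."""


class DuplicateAxisError(TaglobalError):
    """An axis contains duplicate values after sorting."""


class AxisMismatchError(TaglobalError):
    """Two objects that must share an axis do not (no implicit interpolation)."""


class EmptySliceError(TaglobalError):
    """A spectral slice selects no wavelengths."""


class EmptyWindowError(TaglobalError):
    """A time or lifetime window contains no grid points."""


class InsufficientBaselineError(TaglobalError):
    """Not enough pre-time-zero delays for baseline/chirp estimation."""


class ParameterError(TaglobalError):
    """An argument violates its precondition."""


class ConvergenceError(TaglobalError):
    """An iterative fit did not converge; carries solver diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class DegenerateRatesError(TaglobalError):
    """Duplicate (or nearly duplicate) rate constants in a sequential scheme."""


class NoComponentError(TaglobalError):
    """No dynamical-content peak found above the analysis floor."""


class DegenerateDataError(TaglobalError):
    """Data carry no usable signal (e.g. all-zero fluorescence counts)."""


class OverfitWarning(UserWarning):
    """More exponentials requested than the data support."""


class DegeneracyWarning(UserWarning):
    """Fitted lifetimes collapsed onto each other; model order reduced."""


class MonotonicityWarning(UserWarning):
    """A regularization scan violated expected chi^2/penalty monotonicity."""
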