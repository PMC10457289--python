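"""Exception hierarchy for pulsecount.

All domain errors derive from :class:`PulseCountError` so callers can catch
one base class at the CLI boundary.
"""


class PulseCountError(Exception):
    """Base class for all pulsecount errors."""


class InvalidParameterError(PulseCountError, ValueError):
    """A parameter violates its documented precondition."""


class DegenerateInputError(PulseCountError, ValueError):
    """Input is structurally valid but carries no information for the
    requested operation (e.g. constant samples passed to a decay fit)."""


class FitError(PulseCountError, RuntimeError):
    """Nonlinear fit failed to converge.

    Attributes
    ----------
    last_params : tuple or None
        The last parameter iterate the optimizer reached, if available.
    """

    def __init__(self, message, last_params=None):
        super().__init__(message)
        self.last_params = last_params


class OutOfRangeError(PulseCountError, ValueError):
    """An event or sample falls outside the window it must lie in."""


class NoHoleError(PulseCountError, ValueError):
    """Detector mask has no enclosed inner opening; ellipticity undefined."""


class InsufficientAnnulusError(PulseCountError, ValueError):
    """Fewer than three valid radial bins; profile metrics undefined."""


class UndefinedEfficiencyError(PulseCountError, ZeroDivisionError):
    """Detection efficiency requested against an empty truth stream."""


class UndefinedRatioError(PulseCountError, ValueError):
    """Directional spectrum ratio undefined (e.g. constant image)."""


class FormatError(PulseCountError, ValueError):
    """A file does not conform to the expected on-disk dialect."""


class DataError(PulseCountError, ValueError):
    """File parsed but its payload is unusable (NaNs, empty, out of bounds)."""
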