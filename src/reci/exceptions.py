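"""Exception hierarchy for reci.

All package-specific errors derive from :class:`ReciError` so callers can
catch everything the library raises with a single clause.
"""


class ReciError(Exception):
    """Base class for all errors raised by reci."""


class DegenerateInputError(ReciError):
    """A vector is constant (zero range / zero variance) where spread is required."""


class InsufficientDataError(ReciError):
    """Too few observations for the requested operation."""


class EmptyResultError(ReciError):
    """An operation removed every data point."""


class FitFailureError(ReciError):
    """A regression fit failed to converge after all restarts."""


class UndefinedConfidenceError(ReciError):
    """Both directional errors are zero; the error ratio is undefined."""


class UndefinedRatioError(ReciError):
    """A conditional-variance ratio has a zero denominator."""


class NonIntegrableMechanismError(ReciError):
    """Quadrature of the limiting variance ratio diverges under grid refinement."""


class PairFormatError(ReciError):
    """A pair or metadata file violates the expected two-column layout."""


class ConfigurationError(ReciError):
    """An invalid specification, menu entry, or empty candidate list."""
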