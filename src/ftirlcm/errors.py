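"""Exception hierarchy shared across the package.

Every error a caller may want to catch programmatically derives from
:class:`FtirLcmError`.  The CLI maps :class:`ValidationError` (and subclasses)
to exit code 2 and :class:`ConditioningError` to exit code 3.
"""


class FtirLcmError(Exception):
    """Base class for all package errors."""


class ValidationError(FtirLcmError):
    """Input data or parameters violate a documented contract."""


class FormatError(ValidationError):
    """A file is missing required metadata or carries contradictory fields."""


class StructuralError(ValidationError):
    """Array shapes / axis lengths are mutually inconsistent."""


class WindowError(ValidationError):
    """A requested wavenumber window falls outside the spectral axis."""


class ParameterError(ValidationError):
    """A numeric parameter is out of its admissible range."""


class ConditioningError(FtirLcmError):
    """A numerical fit is degenerate (collinear points, rank deficiency)."""


class InfeasibleError(ValidationError):
    """A combinatorial target (e.g. pooling integral) cannot be met."""
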