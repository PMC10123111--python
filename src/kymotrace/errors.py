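"""Exception hierarchy.

All public errors derive from :class:`KymotraceError` so callers can catch the
package's failures with a single except clause.
"""


class KymotraceError(Exception):
    """Base class for all kymotrace errors."""


class InvalidParameterError(KymotraceError, ValueError):
    """A parameter violates its documented domain (e.g. non-positive lifetime)."""


class InvalidInputError(KymotraceError, ValueError):
    """Input data violates a precondition (e.g. empty duration list)."""


class InvalidGeometryError(KymotraceError, ValueError):
    """Imaging geometry is unusable (e.g. tether shorter than the PSF support)."""


class MetadataError(KymotraceError):
    """A kymograph container lacks required physical calibration metadata."""


class ParseError(KymotraceError):
    """A file could not be parsed; carries the offending line number if known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class FitFailureError(KymotraceError):
    """A nonlinear fit failed to converge; carries the best residual seen."""

    def __init__(self, message: str, best_residual: float | None = None):
        self.best_residual = best_residual
        super().__init__(message)


class InvalidCorrectionError(KymotraceError, ValueError):
    """Photobleaching correction is undefined (bleaching-dominated data)."""


class OutOfRangeError(KymotraceError, ValueError):
    """A physical position falls outside the tether span."""
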