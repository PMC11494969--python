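"""Exception hierarchy shared across the package."""


class DynomicsError(Exception):
    """Base class for all package-specific errors."""


class InvalidLagError(DynomicsError, ValueError):
    """An edge lag outside {0, 1} was supplied to a two-slice operation."""


class NetworkFormatError(DynomicsError, ValueError):
    """An edge-list file could not be parsed.

    Carries the 1-based line number of the offending row when known.
    """

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class DegenerateGroupError(DynomicsError, ValueError):
    """A normalization group contained no positive values."""


class UndefinedMetricError(DynomicsError, ValueError):
    """A summary metric has an empty denominator (no eligible edges)."""


class AlignmentError(DynomicsError, ValueError):
    """Temporal alignment is impossible (no shared entities / no overlap)."""
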