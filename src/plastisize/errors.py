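"""Exception hierarchy shared across the package."""


class PlastisizeError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(PlastisizeError, ValueError):
    """A scalar argument or configuration value is out of its valid domain."""


class InvalidRecordError(PlastisizeError, ValueError):
    """A taxon record violates its invariants (e.g. non-positive length)."""


class InsufficientDataError(PlastisizeError, ValueError):
    """Too few usable records for the requested computation."""


class IntervalsUnavailableError(PlastisizeError, ValueError):
    """Intervals were requested from a fit that carries no interval statistics.

    The point prediction is still computed and attached as ``point_mm``.
    """

    def __init__(self, message: str, point_mm: float | None = None):
        super().__init__(message)
        self.point_mm = point_mm


class InvalidGridError(PlastisizeError, ValueError):
    """A grid violates its invariants (shape, class range, units)."""


class NoClassError(PlastisizeError, ValueError):
    """No size class can contain the predicted ingestible plastic length."""
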