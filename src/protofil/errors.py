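"""Exception hierarchy.

Everything raised on bad user input derives from :class:`ProtofilError` so
callers can catch one base class; each subclass also derives from the
closest builtin (ValueError/KeyError/OSError) for idiomatic handling.
"""


class ProtofilError(Exception):
    """Base class for all package errors."""


class InvalidSpecificationError(ProtofilError, ValueError):
    """A template, trajectory spec, or config violates its invariants."""


class FormatError(ProtofilError, ValueError):
    """A structure/trajectory file is malformed or internally inconsistent."""


class SelectionError(ProtofilError, KeyError):
    """An unknown subunit/domain label or an empty selection."""


class InsufficientDataError(ProtofilError, ValueError):
    """Too few points/frames for the requested operation."""


class GeometryError(ProtofilError, ValueError):
    """Degenerate geometry (collinear points, zero-length axes, ...)."""


class DegeneratePredictorError(ProtofilError, ValueError):
    """Regression predictor is constant."""
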