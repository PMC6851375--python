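"""Exception hierarchy for locodist.

All errors raised by the library derive from :class:`LocodistError` so that
callers (and the CLI) can catch everything from one base class.
"""


class LocodistError(Exception):
    """Base class for all locodist errors."""


class FormatError(LocodistError):
    """A file or table does not match the expected format (e.g. missing column)."""


class DataError(LocodistError):
    """The data itself is unusable (too short, non-monotone, empty slice...)."""


class ArgumentError(LocodistError, ValueError):
    """An argument violates a precondition."""


class GeometryError(LocodistError):
    """A geometric construction failed (collinear points, non-disk topology...)."""


class NumericError(LocodistError):
    """An iterative numerical procedure failed to converge."""
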