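"""Exception hierarchy shared across the pipeline.

Every stage raises a subclass of :class:`SoiltoxError`, so callers can
distinguish bad input files (:class:`SchemaError`, :class:`ParseError`,
:class:`ValidationError`) from mathematically undefined results
(:class:`UndefinedIndexError`, :class:`DegenerateDataError`).
"""


class SoiltoxError(Exception):
    """Base class for all errors raised by this package."""


class SchemaError(SoiltoxError):
    """An input table is missing a required column or has a malformed header."""


class ParseError(SoiltoxError):
    """A cell could not be converted to the expected type; message names the row."""


class ValidationError(SoiltoxError):
    """Structurally parsed data violates a domain invariant (negative count, duplicate id, ...)."""


class UndefinedIndexError(SoiltoxError):
    """An index (CD, EP, percent change, IF cell) is undefined for this input.

    Raised instead of silently returning 0 or +/-inf, e.g. when a colony
    series has no colonies at all or a percent-change control mean is zero.
    """


class DegenerateDataError(SoiltoxError):
    """A statistic is undefined because the data are degenerate (constant vector, rank-0 matrix)."""


class InsufficientReplicationError(SoiltoxError):
    """A variance-based procedure was asked to run on groups with fewer than 2 replicates."""
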