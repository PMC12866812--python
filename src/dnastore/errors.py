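"""Exception hierarchy shared across the package.

Every error raised by dnastore derives from :class:`DnastoreError`, which in
turn derives from ``ValueError`` so callers who do not care about the fine
distinctions can catch a single builtin type.
"""


class DnastoreError(ValueError):
    """Base class for all dnastore errors."""


class InvalidRadixError(DnastoreError):
    """Radix outside the supported range (must be >= 2)."""


class AlphabetError(DnastoreError):
    """Input contains characters outside the expected alphabet."""


class InvalidTableError(DnastoreError):
    """A rule table violates bijectivity or its run-length constraint."""


class CorruptSequenceError(DnastoreError):
    """A sequence cannot be decoded under the given rule table."""


class FormatError(DnastoreError):
    """Structural problem: wrong initiator, bad length, malformed file."""


class PaddingError(DnastoreError):
    """Odd-length bit string passed to the 2-bit positional mapping."""


class IndexOverflowError(DnastoreError):
    """More strand ordinals requested than the 16-bit index can address."""


class UndefinedMetricError(DnastoreError):
    """Metric requested on an empty input where it has no value."""


class InsufficientDataError(DnastoreError):
    """Sequence or matrix too small for the requested analysis window."""
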