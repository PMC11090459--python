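"""Exception hierarchy for hegp.

All errors raised deliberately by this package derive from :class:`HEGPError`
so callers can catch one base class at a pipeline boundary.
"""


class HEGPError(Exception):
    """Base class for all hegp errors."""


class InvalidArgumentError(HEGPError, ValueError):
    """A caller-supplied argument violates a precondition (bad shape, size, range)."""


class MissingDataError(HEGPError, ValueError):
    """Input contains missing (NaN) values; the rotation scheme requires complete data."""


class DataError(HEGPError, ValueError):
    """Input contains non-finite or otherwise unusable values."""


class InvalidKeyError(HEGPError, ValueError):
    """A key matrix fails the orthogonality contract."""


class CorruptKeyError(HEGPError, IOError):
    """A key file failed its checksum on load."""


class UnsupportedFormatError(HEGPError, IOError):
    """A key file has an unknown format version."""


class HarmonizationError(HEGPError, ValueError):
    """Contributions cannot be merged because their marker panels differ."""


class EmptyResultError(HEGPError, ValueError):
    """An operation dropped every marker (e.g. all monomorphic)."""
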