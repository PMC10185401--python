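"""Exception hierarchy shared by the BUS reader/writer and the BUSZ codecs."""


class BuszError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(BuszError):
    """The input does not look like the expected file format (bad magic, bad header)."""


class TruncatedStreamError(BuszError):
    """A bit stream or file ended before a complete codeword/record was read."""


class NotSortedError(BuszError):
    """Records violate the required (barcode, umi, ec) sort order."""

    def __init__(self, message: str, index: int | None = None):
        super().__init__(message)
        self.index = index


class CorruptionError(BuszError):
    """A compressed payload is internally inconsistent."""


class IntegrityError(BuszError):
    """The barcode index disagrees with the BUSZ file it claims to describe."""
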