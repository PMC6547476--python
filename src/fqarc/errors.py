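"""Exception hierarchy for fqarc.

All errors raised by the library derive from :class:`FqarcError` so callers
(and the CLI) can distinguish library failures from programming errors.
"""


class FqarcError(Exception):
    """Base class for all fqarc errors."""


class FastqFormatError(FqarcError):
    """The input is not valid strict 4-line FASTQ.

    Parameters
    ----------
    message:
        Human-readable description.
    byte_offset:
        Offset into the input stream where the problem was detected, when
        known.
    record_index:
        0-based index of the offending record, when known.
    """

    def __init__(self, message, byte_offset=None, record_index=None):
        super().__init__(message)
        self.byte_offset = byte_offset
        self.record_index = record_index


class CodingError(FqarcError):
    """An entropy-coding model was asked to do something impossible
    (zero-probability symbol, symbol outside the alphabet, ...)."""


class CorruptPayloadError(FqarcError):
    """A compressed payload ended prematurely or is internally inconsistent."""


class ArchiveError(FqarcError):
    """Base class for container-level failures."""


class ArchiveFormatError(ArchiveError):
    """The byte stream is not an fqarc archive (bad magic) or is structurally
    malformed."""


class ArchiveVersionError(ArchiveError):
    """The archive declares a format version this build does not support."""


class TruncatedArchiveError(ArchiveError):
    """The archive is shorter than its header declares."""

    def __init__(self, expected, actual):
        super().__init__(
            f"archive truncated: expected {expected} bytes, got {actual}"
        )
        self.expected = expected
        self.actual = actual


class StreamIntegrityError(ArchiveError):
    """A per-stream checksum failed: the named stream is corrupt."""

    def __init__(self, stream_name, message=None):
        super().__init__(
            message or f"integrity check failed for stream '{stream_name}'"
        )
        self.stream_name = stream_name
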