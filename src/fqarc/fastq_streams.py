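"""FASTQ parsing, field decoupling, and byte-exact reassembly.

A FASTQ file is a flat concatenation of 4-line records: identifier line
(``@``-prefixed), nucleotide sequence, plus-line (``+`` with optional
comment), and a quality string of the same length as the sequence.  The
compressor splits these into four homogeneous streams so each can be coded
with a model suited to its statistics; this module owns that split and its
exact inverse.

Only strict 4-line FASTQ with a single consistent newline convention (LF or
CRLF) is accepted — both restrictions exist so that
``reassemble(decouple(parse(x))) == x`` holds byte-for-byte, which is the
whole point of a lossless archiver.
"""

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterator, List

from .errors import FastqFormatError

__all__ = [
    "FastqRecord",
    "StreamBundle",
    "PlusMode",
    "NewlineStyle",
    "parse_fastq",
    "iter_records",
    "classify_plus_lines",
    "decouple",
    "reassemble",
]


class PlusMode(Enum):
    """How the third (plus) line of every record can be regenerated.

    BARE:     every plus-line was exactly "+"; nothing is stored.
    MIRROR:   every plus-line was "+" followed by that record's identifier;
              regenerated from the identifier stream.
    VERBATIM: anything else; plus-line comments are stored literally so the
              lossless contract holds on arbitrary input.
    """

    BARE = 0
    MIRROR = 1
    VERBATIM = 2


class NewlineStyle(Enum):
    LF = 0
    CRLF = 1

    @property
    def bytes(self):
        return b"\n" if self is NewlineStyle.LF else b"\r\n"


@dataclass
class FastqRecord:
    """One 4-line record with the '@'/'+' markers stripped.

    ``plus_line`` holds only the comment after '+' (empty for a bare plus).
    """

    identifier: str
    sequence: str
    plus_line: str
    quality: str

    def validate(self, index=None):
        if not self.identifier:
            raise FastqFormatError("empty identifier", record_index=index)
        if len(self.quality) != len(self.sequence):
            raise FastqFormatError(
                f"quality length {len(self.quality)} != sequence length "
                f"{len(self.sequence)} at record {index}",
                record_index=index,
            )
        for name in ("identifier", "sequence", "plus_line", "quality"):
            if "\n" in getattr(self, name) or "\r" in getattr(self, name):
                raise FastqFormatError(
                    f"newline byte inside {name} at record {index}",
                    record_index=index,
                )


@dataclass
class StreamBundle:
    """The four decoupled streams plus the metadata needed to invert."""

    identifiers: List[str]
    sequences: List[str]
    qualities: List[str]
    plus_mode: PlusMode
    plus_payload: List[str] = field(default_factory=list)
    newline_style: NewlineStyle = NewlineStyle.LF

    @property
    def record_count(self):
        return len(self.identifiers)

    def validate(self):
        n = self.record_count
        if not (len(self.sequences) == len(self.qualities) == n):
            raise FastqFormatError("stream lengths disagree")
        if self.plus_mode is PlusMode.VERBATIM:
            if len(self.plus_payload) != n:
                raise FastqFormatError("VERBATIM plus payload length mismatch")
        elif self.plus_payload:
            raise FastqFormatError(
                f"plus payload must be empty for {self.plus_mode.name}"
            )
        for i, (s, q) in enumerate(zip(self.sequences, self.qualities)):
            if len(s) != len(q):
                raise FastqFormatError(
                    f"quality/sequence length mismatch at record {i}",
                    record_index=i,
                )


def _detect_newline(data: bytes) -> NewlineStyle:
    """Sniff the newline convention and reject mixed conventions."""
    has_crlf = b"\r\n" in data
    # any LF not preceded by CR?
    stripped = data.replace(b"\r\n", b"")
    has_bare_lf = b"\n" in stripped
    if b"\r" in stripped:
        raise FastqFormatError("bare CR byte: unsupported newline convention")
    if has_crlf and has_bare_lf:
        raise FastqFormatError(
            "mixed LF/CRLF newline conventions; lossless round trip "
            "cannot be guaranteed"
        )
    return NewlineStyle.CRLF if has_crlf else NewlineStyle.LF


def iter_records(data: bytes, newline_style: NewlineStyle) -> Iterator[FastqRecord]:
    """Yield validated records from ``data`` lazily.

    Works line-by-line over a memoryview so multi-gigabyte inputs never need
    four copies in flight; callers that want batching wrap this iterator.
    """
    nl = newline_style.bytes
    step = len(nl)
    pos = 0
    n = len(data)
    index = 0
    while pos < n:
        lines = []
        start_offset = pos
        for k in range(4):
            end = data.find(nl, pos)
            if end < 0:
                raise FastqFormatError(
                    f"truncated record {index}: line {k + 1} of 4 has no "
                    f"newline terminator",
                    byte_offset=start_offset,
                    record_index=index,
                )
            lines.append(data[pos:end])
            pos = end + step
        ident, seq, plus, qual = lines
        if not ident.startswith(b"@"):
            raise FastqFormatError(
                f"record {index} does not start with '@'",
                byte_offset=start_offset,
                record_index=index,
            )
        if not plus.startswith(b"+"):
            raise FastqFormatError(
                f"record {index}: third line does not start with '+' "
                "(wrapped multi-line FASTQ is not supported)",
                byte_offset=start_offset,
                record_index=index,
            )
        rec = FastqRecord(
            identifier=ident[1:].decode("latin-1"),
            sequence=seq.decode("latin-1"),
            plus_line=plus[1:].decode("latin-1"),
            quality=qual.decode("latin-1"),
        )
        rec.validate(index)
        yield rec
        index += 1


def parse_fastq(data: bytes):
    """Parse a complete FASTQ byte stream.

    Returns ``(records, newline_style)``.  Raises
    :class:`~fqarc.errors.FastqFormatError` on truncated records, quality /
    sequence length mismatches, or mixed newline conventions.
    """
    if not data:
        return [], NewlineStyle.LF
    style = _detect_newline(data)
    if not data.endswith(style.bytes):
        raise FastqFormatError(
            "input does not end with a newline: truncated trailing record",
            byte_offset=len(data),
        )
    records = list(iter_records(data, style))
    return records, style


def classify_plus_lines(records) -> PlusMode:
    """Pick the cheapest plus-line representation that stays lossless."""
    bare = True
    mirror = True
    for rec in records:
        if rec.plus_line != "":
            bare = False
        if rec.plus_line != rec.identifier:
            mirror = False
        if not bare and not mirror:
            return PlusMode.VERBATIM
    if bare:
        return PlusMode.BARE
    return PlusMode.MIRROR


def decouple(records, newline_style=NewlineStyle.LF) -> StreamBundle:
    """Split records into the four streams.

    The plus stream is classified first; unless it must be stored verbatim,
    its payload is dropped entirely and regenerated at reassembly.
    """
    records = list(records)
    if not records:
        return StreamBundle([], [], [], PlusMode.BARE, [], newline_style)
    mode = classify_plus_lines(records)
    bundle = StreamBundle(
        identifiers=[r.identifier for r in records],
        sequences=[r.sequence for r in records],
        qualities=[r.quality for r in records],
        plus_mode=mode,
        plus_payload=[r.plus_line for r in records]
        if mode is PlusMode.VERBATIM
        else [],
        newline_style=newline_style,
    )
    return bundle


def reassemble(bundle: StreamBundle) -> bytes:
    """Exact inverse of ``decouple(parse_fastq(x))``: rebuild the file."""
    bundle.validate()
    nl = bundle.newline_style.bytes.decode("latin-1")
    parts = []
    mode = bundle.plus_mode
    for i in range(bundle.record_count):
        ident = bundle.identifiers[i]
        if mode is PlusMode.BARE:
            plus = "+"
        elif mode is PlusMode.MIRROR:
            plus = "+" + ident
        else:
            plus = "+" + bundle.plus_payload[i]
        parts.append(
            f"@{ident}{nl}{bundle.sequences[i]}{nl}{plus}{nl}"
            f"{bundle.qualities[i]}{nl}"
        )
    return "".join(parts).encode("latin-1")
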