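"""The single-file binary archive holding the compressed streams.

Layout (all integers little-endian, fixed width):

========  =======  =====================================================
offset    size     field
========  =======  =====================================================
0         8        magic ``b"FQARCv01"``
8         2        format version (u16)
10        1        flags: bits 0-1 plus mode (0 bare, 1 mirror,
                   2 verbatim); bit 2 newline style (0 LF, 1 CRLF)
11        8        record count (u64)
19        8        checksum of the original FASTQ bytes (blake2b-64)
27        8        checksum of the header bytes themselves (computed with
                   this field zeroed)
35        1        number of stream entries (u8)
36        --       stream entries, then the payloads back to back in
                   entry order
========  =======  =====================================================

Each stream entry is: stream id (u8), codec id (u8), parameter-block
length (u16) + JSON parameter block, uncompressed stream length (u64),
payload length (u64), checksum of the uncompressed stream bytes (u64),
checksum of the payload bytes (u64).

All checksums are 64-bit blake2b digests.  The header checksum makes any
single-byte header corruption detectable even in fields that would not
change decode semantics; the payload checksum lets a flipped byte anywhere
in a payload be detected — and attributed to the right stream — before any
decoding starts; the content checksum guards against model/parameter
mismatches; the global checksum is the final word on the reassembled file.
Codec parameters are embedded so decompression never depends on tool-side
defaults.
"""

import hashlib
import json
import struct
from dataclasses import dataclass, field
from typing import Dict, List, Tuple

from .errors import (
    ArchiveFormatError,
    ArchiveVersionError,
    StreamIntegrityError,
    TruncatedArchiveError,
)

MAGIC = b"FQARCv01"
VERSION = 1

# stream ids
STREAM_IDENTIFIERS = 1
STREAM_SEQUENCES = 2
STREAM_PLUS = 3
STREAM_QUALITIES = 4

STREAM_NAMES = {
    STREAM_IDENTIFIERS: "identifiers",
    STREAM_SEQUENCES: "sequences",
    STREAM_PLUS: "plus",
    STREAM_QUALITIES: "qualities",
}

# codec ids
CODEC_FCM_ID = 1       # tokenised/delta identifier codec
CODEC_FCM_SEQ = 2      # competing-FCM nucleotide codec
CODEC_CM_QUALITY = 3   # context-mixing quality codec
CODEC_RAW = 4


def checksum64(data: bytes) -> int:
    """64-bit checksum (blake2b with an 8-byte digest)."""
    return int.from_bytes(
        hashlib.blake2b(data, digest_size=8).digest(), "little"
    )


@dataclass
class StreamEntry:
    stream_id: int
    codec_id: int
    params: Dict
    raw_length: int
    payload_length: int
    content_checksum: int
    payload_checksum: int

    @property
    def name(self):
        return STREAM_NAMES.get(self.stream_id, f"stream#{self.stream_id}")


@dataclass
class ArchiveHeader:
    plus_mode: int
    newline_style: int
    record_count: int
    global_checksum: int
    entries: List[StreamEntry] = field(default_factory=list)
    version: int = VERSION

    @property
    def header_size(self):
        n = 36
        for e in self.entries:
            n += 1 + 1 + 2 + len(_params_bytes(e.params)) + 8 + 8 + 8 + 8
        return n


def _params_bytes(params: Dict) -> bytes:
    return json.dumps(params, sort_keys=True, separators=(",", ":")).encode()


def write_archive(header: ArchiveHeader, payloads: List[bytes]) -> bytes:
    """Serialise header + payloads; ``read_archive`` inverts exactly."""
    if len(payloads) != len(header.entries):
        raise ValueError("one payload required per stream entry")
    buf = bytearray()
    buf += MAGIC
    buf += struct.pack("<H", header.version)
    flags = (header.plus_mode & 0x03) | ((header.newline_style & 0x01) << 2)
    buf.append(flags)
    buf += struct.pack("<Q", header.record_count)
    buf += struct.pack("<Q", header.global_checksum)
    buf += b"\x00" * 8  # header checksum, patched below
    buf.append(len(header.entries))
    for e, payload in zip(header.entries, payloads):
        if e.payload_length != len(payload):
            raise ValueError(
                f"entry {e.name}: declared payload length "
                f"{e.payload_length} != actual {len(payload)}"
            )
        pb = _params_bytes(e.params)
        buf.append(e.stream_id)
        buf.append(e.codec_id)
        buf += struct.pack("<H", len(pb))
        buf += pb
        buf += struct.pack("<Q", e.raw_length)
        buf += struct.pack("<Q", e.payload_length)
        buf += struct.pack("<Q", e.content_checksum)
        buf += struct.pack("<Q", e.payload_checksum)
    struct.pack_into("<Q", buf, 27, checksum64(bytes(buf)))
    for payload in payloads:
        buf += payload
    return bytes(buf)


def read_archive(data: bytes) -> Tuple[ArchiveHeader, List[bytes]]:
    """Parse and structurally validate an archive.

    Verifies the payload checksums immediately, so corruption anywhere in a
    payload is reported against the owning stream before any decoding runs.
    Content (post-decode) and whole-file checksums are the caller's job.
    """
    if len(data) < 36:
        raise TruncatedArchiveError(36, len(data))
    if data[:8] != MAGIC:
        raise ArchiveFormatError("not an fqarc archive (bad magic)")
    (version,) = struct.unpack_from("<H", data, 8)
    if version != VERSION:
        raise ArchiveVersionError(
            f"unsupported archive version {version} (supported: {VERSION})"
        )
    flags = data[10]
    plus_mode = flags & 0x03
    if plus_mode == 3:
        raise ArchiveFormatError("invalid plus-mode flag value 3")
    if flags & ~0x07:
        raise ArchiveFormatError(f"unknown flag bits set: {flags:#x}")
    newline_style = (flags >> 2) & 0x01
    (record_count,) = struct.unpack_from("<Q", data, 11)
    (global_checksum,) = struct.unpack_from("<Q", data, 19)
    (header_checksum,) = struct.unpack_from("<Q", data, 27)
    n_streams = data[35]
    pos = 36
    entries = []
    for _ in range(n_streams):
        if pos + 4 > len(data):
            raise TruncatedArchiveError(pos + 4, len(data))
        stream_id = data[pos]
        codec_id = data[pos + 1]
        (plen,) = struct.unpack_from("<H", data, pos + 2)
        pos += 4
        if pos + plen + 32 > len(data):
            raise TruncatedArchiveError(pos + plen + 32, len(data))
        try:
            params = json.loads(data[pos:pos + plen].decode())
        except (ValueError, UnicodeDecodeError) as exc:
            raise ArchiveFormatError(
                f"unreadable codec parameter block for stream id {stream_id}: "
                f"{exc}"
            ) from exc
        pos += plen
        raw_length, payload_length, content_ck, payload_ck = struct.unpack_from(
            "<QQQQ", data, pos
        )
        pos += 32
        entries.append(
            StreamEntry(
                stream_id, codec_id, params, raw_length, payload_length,
                content_ck, payload_ck,
            )
        )
    header_bytes = bytearray(data[:pos])
    header_bytes[27:35] = b"\x00" * 8
    if checksum64(bytes(header_bytes)) != header_checksum:
        raise ArchiveFormatError("header checksum mismatch: corrupt header")
    header = ArchiveHeader(
        plus_mode=plus_mode,
        newline_style=newline_style,
        record_count=record_count,
        global_checksum=global_checksum,
        entries=entries,
        version=version,
    )
    expected = pos + sum(e.payload_length for e in entries)
    if expected != len(data):
        if len(data) < expected:
            raise TruncatedArchiveError(expected, len(data))
        raise ArchiveFormatError(
            f"archive has {len(data) - expected} trailing bytes"
        )
    payloads = []
    for e in entries:
        payload = data[pos:pos + e.payload_length]
        pos += e.payload_length
        if checksum64(payload) != e.payload_checksum:
            raise StreamIntegrityError(
                e.name, f"payload checksum mismatch for stream '{e.name}'"
            )
        payloads.append(payload)
    return header, payloads
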