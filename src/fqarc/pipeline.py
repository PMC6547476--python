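"""End-to-end compression and decompression.

``compress_bytes`` decouples a FASTQ byte stream into its four component
streams, runs the stream-appropriate codec on each (tokenised/delta FCM for
identifiers, competing FCMs for sequences, context mixing for qualities;
the plus stream is dropped unless it must be stored verbatim), and packs
the payloads into one archive.  ``decompress_bytes`` inverts every step and
refuses to return output that fails any integrity check.
"""

from dataclasses import dataclass, field as dc_field
from typing import List

from . import container, fastq_streams, fcm, quality_cm
from .container import (
    ArchiveHeader,
    StreamEntry,
    checksum64,
    CODEC_CM_QUALITY,
    CODEC_FCM_ID,
    CODEC_FCM_SEQ,
    STREAM_IDENTIFIERS,
    STREAM_PLUS,
    STREAM_QUALITIES,
    STREAM_SEQUENCES,
)
from .errors import StreamIntegrityError
from .fastq_streams import NewlineStyle, PlusMode, StreamBundle

__all__ = ["CompressionConfig", "compress_bytes", "decompress_bytes",
           "compress_file", "decompress_file", "stream_sizes"]


@dataclass
class CompressionConfig:
    """Everything the two codecs can be tuned with; all of it is recorded in
    the archive header, so decompression never depends on defaults."""

    sequence: fcm.SequenceCodecConfig = dc_field(
        default_factory=fcm.SequenceCodecConfig
    )
    quality: quality_cm.QualityCodecConfig = dc_field(
        default_factory=quality_cm.QualityCodecConfig
    )
    identifier_order: int = 2


def _stream_raw_bytes(items: List[str]) -> bytes:
    """Canonical uncompressed representation of a text stream (one element
    per line), used for per-stream checksums and size accounting."""
    if not items:
        return b""
    return ("\n".join(items) + "\n").encode("latin-1")


def compress_bytes(data: bytes, config: CompressionConfig = None) -> bytes:
    """Compress a strict 4-line FASTQ byte stream into an archive."""
    if config is None:
        config = CompressionConfig()
    records, newline_style = fastq_streams.parse_fastq(data)
    bundle = fastq_streams.decouple(records, newline_style)

    id_payload = fcm.encode_identifiers(
        bundle.identifiers, order=config.identifier_order
    )
    seq_payload = fcm.encode_sequences(bundle.sequences, config.sequence)
    qual_payload = quality_cm.encode_qualities(bundle.qualities, config.quality)

    entries = []
    payloads = []

    def add(stream_id, codec_id, params, items, payload):
        raw = _stream_raw_bytes(items)
        entries.append(
            StreamEntry(
                stream_id=stream_id,
                codec_id=codec_id,
                params=params,
                raw_length=len(raw),
                payload_length=len(payload),
                content_checksum=checksum64(raw),
                payload_checksum=checksum64(payload),
            )
        )
        payloads.append(payload)

    add(STREAM_IDENTIFIERS, CODEC_FCM_ID,
        {"order": config.identifier_order}, bundle.identifiers, id_payload)
    add(STREAM_SEQUENCES, CODEC_FCM_SEQ,
        config.sequence.to_dict(), bundle.sequences, seq_payload)
    if bundle.plus_mode is PlusMode.VERBATIM:
        plus_payload = fcm.encode_identifiers(
            bundle.plus_payload, order=config.identifier_order
        )
        add(STREAM_PLUS, CODEC_FCM_ID,
            {"order": config.identifier_order}, bundle.plus_payload,
            plus_payload)
    add(STREAM_QUALITIES, CODEC_CM_QUALITY,
        config.quality.to_dict(), bundle.qualities, qual_payload)

    header = ArchiveHeader(
        plus_mode=bundle.plus_mode.value,
        newline_style=bundle.newline_style.value,
        record_count=bundle.record_count,
        global_checksum=checksum64(data),
        entries=entries,
    )
    return container.write_archive(header, payloads)


def decompress_bytes(archive: bytes) -> bytes:
    """Invert :func:`compress_bytes`; raises on any integrity failure."""
    header, payloads = container.read_archive(archive)
    by_id = {
        e.stream_id: (e, p) for e, p in zip(header.entries, payloads)
    }
    for required in (STREAM_IDENTIFIERS, STREAM_SEQUENCES, STREAM_QUALITIES):
        if required not in by_id:
            raise container.ArchiveFormatError(
                f"archive is missing the {container.STREAM_NAMES[required]} "
                "stream"
            )

    def decode(stream_id, decoder):
        entry, payload = by_id[stream_id]
        try:
            items = decoder(entry, payload)
        except StreamIntegrityError:
            raise
        except Exception as exc:
            raise StreamIntegrityError(
                entry.name,
                f"stream '{entry.name}' failed to decode: {exc}",
            ) from exc
        if checksum64(_stream_raw_bytes(items)) != entry.content_checksum:
            raise StreamIntegrityError(
                entry.name,
                f"content checksum mismatch for stream '{entry.name}'",
            )
        return items

    identifiers = decode(
        STREAM_IDENTIFIERS,
        lambda e, p: fcm.decode_identifiers(p, order=e.params["order"]),
    )
    sequences = decode(
        STREAM_SEQUENCES,
        lambda e, p: fcm.decode_sequences(
            p, fcm.SequenceCodecConfig.from_dict(e.params)
        ),
    )
    lengths = [len(s) for s in sequences]
    qualities = decode(
        STREAM_QUALITIES,
        lambda e, p: quality_cm.decode_qualities(
            p, lengths, quality_cm.QualityCodecConfig.from_dict(e.params)
        ),
    )
    plus_mode = PlusMode(header.plus_mode)
    if plus_mode is PlusMode.VERBATIM:
        if STREAM_PLUS not in by_id:
            raise container.ArchiveFormatError(
                "verbatim plus mode declared but plus stream missing"
            )
        plus_payload = decode(
            STREAM_PLUS,
            lambda e, p: fcm.decode_identifiers(p, order=e.params["order"]),
        )
    else:
        plus_payload = []

    n = header.record_count
    if not (len(identifiers) == len(sequences) == len(qualities) == n):
        raise container.ArchiveFormatError(
            f"decoded stream lengths {len(identifiers)}/{len(sequences)}/"
            f"{len(qualities)} disagree with record count {n}"
        )
    bundle = StreamBundle(
        identifiers=identifiers,
        sequences=sequences,
        qualities=qualities,
        plus_mode=plus_mode,
        plus_payload=plus_payload,
        newline_style=NewlineStyle(header.newline_style),
    )
    out = fastq_streams.reassemble(bundle)
    if checksum64(out) != header.global_checksum:
        raise StreamIntegrityError(
            "file", "whole-file checksum mismatch after reassembly"
        )
    return out


def compress_file(in_path, out_path, config: CompressionConfig = None) -> None:
    with open(in_path, "rb") as fh:
        data = fh.read()
    archive = compress_bytes(data, config)
    with open(out_path, "wb") as fh:
        fh.write(archive)


def decompress_file(in_path, out_path) -> None:
    with open(in_path, "rb") as fh:
        archive = fh.read()
    data = decompress_bytes(archive)
    with open(out_path, "wb") as fh:
        fh.write(data)


def stream_sizes(archive: bytes):
    """Per-stream (raw, payload) byte sizes from the header — the numbers
    behind the per-stream compression-ratio breakdown."""
    header, _ = container.read_archive(archive)
    return {
        e.name: (e.raw_length, e.payload_length) for e in header.entries
    }
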