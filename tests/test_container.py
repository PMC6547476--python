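"""Archive container: structure, idempotence, integrity attribution."""

import pytest

from fqarc import container
from fqarc.container import (
    ArchiveHeader,
    StreamEntry,
    checksum64,
    read_archive,
    write_archive,
)
from fqarc.errors import (
    ArchiveError,
    ArchiveFormatError,
    ArchiveVersionError,
    StreamIntegrityError,
    TruncatedArchiveError,
)
from fqarc.pipeline import compress_bytes, decompress_bytes
from fqarc.synthetic import GeneratorConfig, generate


def _toy_archive():
    payloads = [b"payload-one", b"payload-two-longer"]
    entries = [
        StreamEntry(container.STREAM_IDENTIFIERS, container.CODEC_RAW,
                    {"order": 2}, 20, len(payloads[0]),
                    checksum64(b"raw-one"), checksum64(payloads[0])),
        StreamEntry(container.STREAM_QUALITIES, container.CODEC_RAW,
                    {"k": 1}, 30, len(payloads[1]),
                    checksum64(b"raw-two"), checksum64(payloads[1])),
    ]
    header = ArchiveHeader(plus_mode=0, newline_style=0, record_count=5,
                           global_checksum=checksum64(b"whole"),
                           entries=entries)
    return header, payloads


class TestWriteRead:
    def test_round_trip(self):
        header, payloads = _toy_archive()
        blob = write_archive(header, payloads)
        header2, payloads2 = read_archive(blob)
        assert payloads2 == payloads
        assert header2.record_count == 5
        assert [e.params for e in header2.entries] == [{"order": 2}, {"k": 1}]

    def test_write_read_write_is_byte_stable(self):
        header, payloads = _toy_archive()
        blob = write_archive(header, payloads)
        header2, payloads2 = read_archive(blob)
        assert write_archive(header2, payloads2) == blob

    def test_archive_size_accounting_identity(self):
        header, payloads = _toy_archive()
        blob = write_archive(header, payloads)
        assert len(blob) == header.header_size + sum(len(p) for p in payloads)

    def test_empty_input_archive_round_trips(self):
        arc = compress_bytes(b"")
        assert decompress_bytes(arc) == b""

    def test_bad_magic(self):
        header, payloads = _toy_archive()
        blob = bytearray(write_archive(header, payloads))
        blob[0] ^= 0xFF
        with pytest.raises(ArchiveFormatError, match="magic"):
            read_archive(bytes(blob))

    def test_unsupported_version(self):
        header, payloads = _toy_archive()
        blob = bytearray(write_archive(header, payloads))
        blob[8] = 99
        with pytest.raises(ArchiveVersionError):
            read_archive(bytes(blob))

    def test_truncation_reports_expected_vs_actual(self):
        header, payloads = _toy_archive()
        blob = write_archive(header, payloads)
        with pytest.raises(TruncatedArchiveError) as exc:
            read_archive(blob[:-5])
        assert exc.value.expected == len(blob)
        assert exc.value.actual == len(blob) - 5

    def test_trailing_garbage_rejected(self):
        header, payloads = _toy_archive()
        blob = write_archive(header, payloads)
        with pytest.raises(ArchiveFormatError, match="trailing"):
            read_archive(blob + b"x")


@pytest.fixture(scope="module")
def small_archive():
    data = generate(GeneratorConfig(n_reads=25, read_length=60, seed=11))
    return data, compress_bytes(data)


class TestCorruptionAttribution:
    def test_payload_flip_attributed_to_owning_stream(self, small_archive):
        data, arc = small_archive
        header, payloads = read_archive(arc)
        pos = len(arc) - sum(e.payload_length for e in header.entries)
        for entry in header.entries:
            mid = pos + entry.payload_length // 2
            corrupted = bytearray(arc)
            corrupted[mid] ^= 0x01
            with pytest.raises(StreamIntegrityError) as exc:
                decompress_bytes(bytes(corrupted))
            assert exc.value.stream_name == entry.name
            pos += entry.payload_length

    def test_flip_in_one_payload_leaves_others_decodable(self, small_archive):
        """Payload corruption is detected at the owning stream, before any
        other stream is blamed."""
        data, arc = small_archive
        header, payloads = read_archive(arc)
        # flip the final payload (qualities): identifier/sequence streams
        # must still decode on their own
        corrupted = bytearray(arc)
        corrupted[-1] ^= 0xFF
        with pytest.raises(StreamIntegrityError) as exc:
            decompress_bytes(bytes(corrupted))
        assert exc.value.stream_name == header.entries[-1].name

    def test_every_corruption_is_detected_sampled(self, small_archive):
        """Flip every 7th byte of the archive: some error always raised."""
        data, arc = small_archive
        for i in range(0, len(arc), 7):
            corrupted = bytearray(arc)
            corrupted[i] ^= 0x10
            with pytest.raises(ArchiveError):
                decompress_bytes(bytes(corrupted))

    def test_mid_payload_truncation_detected(self, small_archive):
        data, arc = small_archive
        with pytest.raises(ArchiveError):
            decompress_bytes(arc[: len(arc) * 2 // 3])


# Golden fixture: a 2-record FASTQ and the archive this implementation wrote
# for it, frozen at format version 1. Guards on-disk format stability: a
# codec or layout change that breaks old archives must fail here.
_GOLDEN_FASTQ = (
    b"@SRR000001.1 1/1\nACGTNACGTA\n+\nIIIIHHGGFF\n"
    b"@SRR000001.2 2/1\nTTTTACGTAC\n+\nIIJJHHGGFF\n"
)
_GOLDEN_ARCHIVE_HEX = (
    "465141524376303101000002000000000000007eda5e43c5a33b9029e85deb0206d40f"
    "0301010b007b226f72646572223a327d20000000000000003200000000000000fdc4a4"
    "78001e72b4dc29c9c3cf885b9202027e007b22616c706861223a5b312c31365d2c2262"
    "6c656e64223a747275652c22636f756e745f6c696d6974223a31363338342c22646563"
    "61795f64656e223a3235362c2264656361795f6e756d223a3234332c22686173685f6f"
    "726465725f7468726573686f6c64223a382c226f7264657273223a5b322c352c382c31"
    "315d7d16000000000000002100000000000000ff94b4c98baa9b376d21783cc3c4c546"
    "0403a1007b2263617272795f6163726f73735f7265616473223a66616c73652c22636f"
    "6e7465787473223a5b227131222c227132222c22706f73222c2271316d617838222c22"
    "647369676e225d2c226d697865725f6275636b657473223a382c226d697865725f7261"
    "74655f7368696674223a31332c22706f736974696f6e5f6275636b657473223a31362c"
    "22707265646963746f725f726174655f7368696674223a357d16000000000000001100"
    "0000000000008915b6e6f359efb25c0d43b694d8eab602290107fffffffffff71dede4"
    "e2090936000b0d35ae261710204344dfeb22a7c0ad53f086c667b2232a92c8b2cfe6de"
    "0d04020f0213ffffffffffffec0000000000000d3f14e237c0bbba9f554d96d179014e"
    "c28b4d84ddbe675b436558148d4236d8d0"
)


def test_golden_archive_decodes_to_golden_fastq():
    archive = bytes.fromhex(_GOLDEN_ARCHIVE_HEX)
    assert decompress_bytes(archive) == _GOLDEN_FASTQ


def test_golden_fastq_still_compresses_to_golden_archive():
    assert compress_bytes(_GOLDEN_FASTQ).hex() == _GOLDEN_ARCHIVE_HEX
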