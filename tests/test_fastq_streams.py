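"""Parsing, decoupling and byte-exact reassembly of 4-line FASTQ."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fqarc.errors import FastqFormatError
from fqarc.fastq_streams import (
    FastqRecord,
    NewlineStyle,
    PlusMode,
    StreamBundle,
    classify_plus_lines,
    decouple,
    parse_fastq,
    reassemble,
)


class TestParse:
    def test_minimal_record(self):
        records, style = parse_fastq(b"@r1\nACGT\n+\nIIII\n")
        assert style is NewlineStyle.LF
        assert len(records) == 1
        r = records[0]
        assert (r.identifier, r.sequence, r.plus_line, r.quality) == (
            "r1", "ACGT", "", "IIII"
        )

    def test_quality_length_mismatch_names_record(self):
        with pytest.raises(FastqFormatError) as exc:
            parse_fastq(b"@r1\nACGT\n+\nIII\n")
        assert exc.value.record_index == 0
        assert "3" in str(exc.value) and "4" in str(exc.value)

    def test_plus_payloads_kept(self):
        records, _ = parse_fastq(
            b"@r1\nACGT\n+r1\nIIII\n@r2\nNNNN\n+r2\n!!!!\n"
        )
        assert [r.plus_line for r in records] == ["r1", "r2"]

    def test_truncated_trailing_record_reports_offset(self):
        data = b"@r1\nACGT\n+\nIIII\n@r2\nACGT\n+\n"
        with pytest.raises(FastqFormatError) as exc:
            parse_fastq(data)
        assert exc.value.byte_offset == 16

    def test_missing_final_newline_rejected(self):
        with pytest.raises(FastqFormatError):
            parse_fastq(b"@r1\nACGT\n+\nIIII")

    def test_mixed_newlines_rejected(self):
        with pytest.raises(FastqFormatError, match="mixed"):
            parse_fastq(b"@r1\r\nACGT\r\n+\r\nIIII\r\n@r2\nACGT\n+\nIIII\n")

    def test_crlf_detected(self):
        records, style = parse_fastq(b"@r1\r\nACGT\r\n+\r\nIIII\r\n")
        assert style is NewlineStyle.CRLF
        assert records[0].sequence == "ACGT"

    def test_wrapped_fastq_rejected(self):
        # multi-line sequences make line 3 not start with '+'
        with pytest.raises(FastqFormatError, match=r"\+"):
            parse_fastq(b"@r1\nAC\nGT\n+\nIIII\n@x\nA\n+\nI\n")

    def test_empty_input(self):
        records, style = parse_fastq(b"")
        assert records == [] and style is NewlineStyle.LF


class TestClassify:
    def _rec(self, ident, plus):
        return FastqRecord(ident, "ACGT", plus, "IIII")

    def test_all_bare(self):
        assert classify_plus_lines(
            [self._rec("a", ""), self._rec("b", "")]
        ) is PlusMode.BARE

    def test_mirror(self):
        recs = [self._rec("SRR554369.1", "SRR554369.1"),
                self._rec("SRR554369.2", "SRR554369.2")]
        assert classify_plus_lines(recs) is PlusMode.MIRROR

    def test_mixed_falls_back_to_verbatim(self):
        recs = [self._rec("a", ""), self._rec("b", "note")]
        assert classify_plus_lines(recs) is PlusMode.VERBATIM


class TestDecoupleReassemble:
    def test_bare_bundle(self):
        records, style = parse_fastq(b"@r1\nACGT\n+\nIIII\n@r2\nTTTT\n+\n!!!!\n")
        bundle = decouple(records, style)
        assert bundle.record_count == 2
        assert bundle.plus_mode is PlusMode.BARE
        assert bundle.plus_payload == []

    def test_empty_bundle(self):
        bundle = decouple([], NewlineStyle.LF)
        assert bundle.record_count == 0
        assert bundle.plus_mode is PlusMode.BARE
        assert reassemble(bundle) == b""

    def test_reassemble_minimal(self):
        bundle = StreamBundle(["r1"], ["ACGT"], ["IIII"], PlusMode.BARE)
        assert reassemble(bundle) == b"@r1\nACGT\n+\nIIII\n"

    def test_mirror_regenerates_plus(self):
        bundle = StreamBundle(["id9"], ["AC"], ["II"], PlusMode.MIRROR)
        assert reassemble(bundle) == b"@id9\nAC\n+id9\nII\n"

    def test_invalid_bundle_rejected_before_output(self):
        bundle = StreamBundle(["r1"], ["ACGT"], ["III"], PlusMode.BARE)
        with pytest.raises(FastqFormatError):
            reassemble(bundle)


_ident = st.text(
    st.characters(min_codepoint=33, max_codepoint=126), min_size=1, max_size=20
)
_seq_char = st.sampled_from("ACGTN")
_qual_char = st.characters(min_codepoint=33, max_codepoint=126)


@st.composite
def _fastq_bytes(draw):
    n = draw(st.integers(min_value=1, max_value=12))
    style = draw(st.sampled_from([NewlineStyle.LF, NewlineStyle.CRLF]))
    plus_kind = draw(st.sampled_from(["bare", "mirror", "free"]))
    nl = style.bytes.decode()
    out = []
    for _ in range(n):
        ident = draw(_ident)
        length = draw(st.integers(min_value=0, max_value=30))
        seq = "".join(draw(st.lists(_seq_char, min_size=length,
                                    max_size=length)))
        qual = "".join(draw(st.lists(_qual_char, min_size=length,
                                     max_size=length)))
        if plus_kind == "bare":
            plus = "+"
        elif plus_kind == "mirror":
            plus = "+" + ident
        else:
            plus = "+" + draw(st.text(
                st.characters(min_codepoint=33, max_codepoint=126),
                max_size=10))
        out.append(f"@{ident}{nl}{seq}{nl}{plus}{nl}{qual}{nl}")
    return "".join(out).encode("latin-1")


@given(_fastq_bytes())
@settings(max_examples=60, deadline=None, derandomize=True)
def test_round_trip_byte_identity(data):
    """reassemble(decouple(parse(x))) == x for arbitrary accepted input."""
    records, style = parse_fastq(data)
    bundle = decouple(records, style)
    assert reassemble(bundle) == data


@given(_fastq_bytes())
@settings(max_examples=30, deadline=None, derandomize=True)
def test_stream_length_conservation(data):
    """Stream byte totals plus per-record overhead account for every byte."""
    records, style = parse_fastq(data)
    bundle = decouple(records, style)
    nl = len(style.bytes)
    n = bundle.record_count
    total = sum(len(i) for i in bundle.identifiers)
    total += sum(len(s) for s in bundle.sequences)
    total += sum(len(q) for q in bundle.qualities)
    # markers: '@' and '+' per record; four newlines per record
    total += n * (2 + 4 * nl)
    if bundle.plus_mode is PlusMode.MIRROR:
        total += sum(len(i) for i in bundle.identifiers)
    elif bundle.plus_mode is PlusMode.VERBATIM:
        total += sum(len(p) for p in bundle.plus_payload)
    assert total == len(data)


def test_matrix_fixtures_parse_clean(matrix):
    for name, data in matrix.items():
        records, style = parse_fastq(data)
        bundle = decouple(records, style)
        assert reassemble(bundle) == data, name
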