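"""Finite-context models, identifier tokenization and the sequence codec."""

import random
from fractions import Fraction

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fqarc.errors import CodingError
from fqarc.fcm import (
    ContextModel,
    NUMERIC,
    SequenceCodecConfig,
    TEXT,
    decode_identifiers,
    decode_sequences,
    delta_encode_numeric,
    detokenize_identifier,
    encode_identifiers,
    encode_sequences,
    tokenize_identifier,
)


# --------------------------------------------------------------------------
# independent oracle: brute-force smoothed conditional frequency
# --------------------------------------------------------------------------

def brute_force_probability(text, order, alphabet, alpha, context, symbol):
    """Count every occurrence of ``context`` in ``text`` and apply additive
    smoothing directly — shares no code with ContextModel."""
    count = 0
    total = 0
    for i in range(order, len(text)):
        if text[i - order:i] == context:
            total += 1
            if text[i] == symbol:
                count += 1
    return Fraction(count * alpha.denominator + alpha.numerator,
                    total * alpha.denominator
                    + alpha.numerator * len(alphabet))


class TestContextModel:
    def test_worked_micro_example(self):
        """After 'ACGACG' with k=2, alpha=1: P(A|'CG') = (1+1)/(1+4) = 0.4."""
        m = ContextModel(2, "ACGT", alpha=(1, 1))
        m.observe_string("ACGACG")
        assert m.probability("CG", "A") == pytest.approx(0.4)
        oracle = brute_force_probability(
            "ACGACG", 2, "ACGT", Fraction(1, 1), "CG", "A"
        )
        assert m.probability("CG", "A") == pytest.approx(float(oracle))

    def test_fresh_model_is_uniform(self):
        m = ContextModel(3, "ACGT", alpha=(1, 2))
        assert m.probability("ACG", "T") == pytest.approx(0.25)

    def test_repeated_observation_approaches_certainty(self):
        # closed form (n+1)/(n+4) for alpha=1 over a 4-symbol alphabet
        m = ContextModel(1, "ACGT", alpha=(1, 1))
        last = 0.0
        for n in range(1, 30):
            m.observe("C", "A")
            p = m.probability("C", "A")
            assert p == pytest.approx((n + 1) / (n + 4))
            assert p > last
            last = p

    @given(st.text(alphabet="ACGT", min_size=3, max_size=60),
           st.integers(min_value=0, max_value=3))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_matches_brute_force_on_random_strings(self, text, order):
        m = ContextModel(order, "ACGT", alpha=(1, 2))
        m.observe_string(text)
        ctx = text[:order]
        for sym in "ACGT":
            oracle = brute_force_probability(
                text, order, "ACGT", Fraction(1, 2), ctx, sym
            )
            assert m.probability(ctx, sym) == pytest.approx(float(oracle))

    def test_distribution_sums_to_one(self):
        m = ContextModel(2, "ACGT", alpha=(1, 16))
        m.observe_string("ACGTACGGGA")
        dist = m.distribution("CG")
        assert sum(dist) == pytest.approx(1.0, abs=2 ** -16)
        assert all(0.0 < p < 1.0 for p in dist)

    def test_symbol_outside_alphabet(self):
        m = ContextModel(1, "ACGT")
        with pytest.raises(CodingError):
            m.probability("A", "N")


class TestTokenization:
    def test_srr_style_identifier(self):
        fields = tokenize_identifier("SRR554369.1 1/1")
        kinds = [(f.kind, f.text if f.kind == TEXT else (f.value, f.width))
                 for f in fields]
        assert kinds == [
            (TEXT, "SRR"), (NUMERIC, (554369, 6)), (TEXT, "."),
            (NUMERIC, (1, 1)), (TEXT, " "), (NUMERIC, (1, 1)),
            (TEXT, "/"), (NUMERIC, (1, 1)),
        ]
        assert detokenize_identifier(fields) == "SRR554369.1 1/1"

    def test_zero_padding_preserved(self):
        fields = tokenize_identifier("007")
        assert (fields[0].value, fields[0].width) == (7, 3)
        assert detokenize_identifier(fields) == "007"

    def test_empty_identifier(self):
        assert tokenize_identifier("") == []
        assert detokenize_identifier([]) == ""

    @given(st.text(st.characters(min_codepoint=33, max_codepoint=126),
                   max_size=40))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_concatenation_invariant(self, ident):
        assert detokenize_identifier(tokenize_identifier(ident)) == ident


class TestDeltaEncoding:
    def test_increment_pattern(self):
        prev = tokenize_identifier("SRR554369.1 1/1")
        cur = tokenize_identifier("SRR554369.2 2/1")
        residuals = [item[1] for item in delta_encode_numeric(prev, cur)
                     if item[0] == "delta"]
        assert residuals == [0, 1, 1, 0]

    def test_first_record_residuals_are_raw_values(self):
        cur = tokenize_identifier("read42")
        out = delta_encode_numeric(None, cur)
        assert out == [("changed", "read"), ("delta", 42, 2)]

    def test_template_mismatch_raises(self):
        with pytest.raises(ValueError):
            delta_encode_numeric(
                tokenize_identifier("a1"), tokenize_identifier("1a")
            )


class TestIdentifierCodec:
    def test_incrementing_ids_compress_below_5_percent(self):
        ids = [f"r{i}" for i in range(1, 1001)]
        payload = encode_identifiers(ids)
        raw = sum(len(i) for i in ids)
        assert len(payload) < 0.05 * raw
        assert decode_identifiers(payload) == ids

    def test_alternating_templates_round_trip(self):
        ids = ["alpha", "1", "alpha", "2", "beta/7"] * 20
        assert decode_identifiers(encode_identifiers(ids)) == ids

    def test_empty_stream(self):
        payload = encode_identifiers([])
        assert decode_identifiers(payload) == []

    @given(st.lists(st.text(
        st.characters(min_codepoint=33, max_codepoint=126),
        min_size=1, max_size=25), max_size=40))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_round_trip_property(self, ids):
        assert decode_identifiers(encode_identifiers(ids)) == ids


class TestSequenceCodec:
    def test_periodic_sequence_far_below_2bit_packing(self):
        seqs = ["ACGT" * 2500]
        payload = encode_sequences(seqs)
        assert len(payload) < 0.02 * (10_000 / 4)  # < 2% of 2-bit packing
        assert decode_sequences(payload) == seqs

    def test_iid_uniform_within_5_percent_of_entropy(self):
        rng = random.Random(0)
        seqs = ["".join(rng.choice("ACGT") for _ in range(100))
                for _ in range(100)]
        payload = encode_sequences(seqs)
        assert len(payload) * 8 <= 1.05 * 2 * 10_000 + 64
        assert decode_sequences(payload) == seqs

    def test_non_acgt_escape(self):
        seqs = ["ACGTN"]
        assert decode_sequences(encode_sequences(seqs)) == seqs

    def test_variable_lengths_and_heavy_n(self):
        rng = random.Random(2)
        seqs = ["".join(rng.choice("ACGTN") for _ in range(rng.randrange(0, 80)))
                for _ in range(60)]
        assert decode_sequences(encode_sequences(seqs)) == seqs

    def test_empty_stream(self):
        assert decode_sequences(encode_sequences([])) == []

    def test_unprintable_sequence_byte_rejected(self):
        with pytest.raises(CodingError):
            encode_sequences(["AC\x07T"])

    def test_monotone_learning_second_pass_cheaper(self):
        """Re-coding the same 1,000+ base sequence with carried model state
        costs strictly fewer bits the second time."""
        rng = random.Random(9)
        seq = "".join(rng.choice("ACGT") for _ in range(2000))
        # a repeat-containing (non-trivial) sequence: append a repeated block
        seq = seq[:1000] + seq[:1000]
        payload_once = encode_sequences([seq])
        payload_twice = encode_sequences([seq, seq])
        second_pass = len(payload_twice) - len(payload_once)
        assert second_pass < len(payload_once) - 8  # discount one coder flush

    def test_blend_no_worse_than_worst_single_model(self, illumina_fastq):
        from fqarc.fastq_streams import parse_fastq

        records, _ = parse_fastq(illumina_fastq)
        seqs = [r.sequence for r in records]
        blended = len(encode_sequences(seqs))
        singles = [
            len(encode_sequences(seqs, SequenceCodecConfig(orders=(k,))))
            for k in (2, 5, 8, 11)
        ]
        assert blended <= max(singles)

    def test_hard_switch_config_round_trips(self):
        cfg = SequenceCodecConfig(blend=False)
        rng = random.Random(4)
        seqs = ["".join(rng.choice("ACGT") for _ in range(200))
                for _ in range(20)]
        assert decode_sequences(encode_sequences(seqs, cfg), cfg) == seqs
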