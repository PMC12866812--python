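"""Codec module: radix conversion, rule tables, encode/decode, strands."""

import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from dnastore import codec
from dnastore.codec import (
    RuleTable,
    assemble_strands,
    bits_to_digits,
    build_rule_table,
    decode_sequence,
    digits_to_bits,
    encode_sequence,
    sequence_identity,
    simple_map,
    simple_unmap,
)
from dnastore.errors import (
    AlphabetError,
    CorruptSequenceError,
    FormatError,
    IndexOverflowError,
    InvalidRadixError,
    InvalidTableError,
    PaddingError,
    UndefinedMetricError,
)

RULES = codec.RULE_SCHEMES


class TestRadixConversion:
    def test_worked_base4_conversion(self):
        assert bits_to_digits("1110011100", 4, guard=False) == [3, 2, 1, 3, 0]

    def test_guarded_base4_conversion(self):
        # guarded value is 11110011100b = 1948 = 132130 in base 4
        assert bits_to_digits("1110011100", 4, guard=True) == [1, 3, 2, 1, 3, 0]

    def test_guard_bit_identity_radix(self):
        assert bits_to_digits("0", 2, guard=True) == [1, 0]
        assert digits_to_bits([1, 0], 2, guard=True) == "0"

    def test_guarded_16384_bit_payload_gives_4097_hex_digits(self, random_bits_16384):
        assert len(bits_to_digits(random_bits_16384, 16)) == 4097

    def test_digit_count_independent_of_content(self):
        # the guard bit pins the integer's magnitude, so at the canonical
        # payload size the all-zero and all-one extremes give the same
        # digit count in every shipped radix
        for radix in (3, 4, 9, 12, 16):
            counts = {
                len(bits_to_digits(b * 16384, radix))
                for b in ("0", "1")
            }
            assert len(counts) == 1

    def test_invalid_radix_rejected(self):
        with pytest.raises(InvalidRadixError):
            bits_to_digits("101", 1)

    def test_non_binary_rejected(self):
        with pytest.raises(AlphabetError):
            bits_to_digits("10a1", 2)

    def test_unguarded_inverse_of_worked_example(self):
        assert digits_to_bits([3, 2, 1, 3, 0], 4, guard=False) == "1110011100"

    def test_corrupt_guarded_value_detected(self):
        # value 0 cannot carry a guard bit
        with pytest.raises(CorruptSequenceError):
            digits_to_bits([0], 9, guard=True)

    @given(st.text(alphabet="01", min_size=0, max_size=256),
           st.sampled_from([3, 4, 9, 12, 16]))
    def test_round_trip_property(self, bits, radix):
        assert digits_to_bits(bits_to_digits(bits, radix), radix) == bits


class TestRuleTables:
    @pytest.mark.parametrize("scheme,radix,unit_len", [
        ("Rinf-B16", 16, 2), ("R1-B12", 12, 2), ("R0-B9", 9, 2),
        ("Rinf-B4", 4, 1), ("R0-B3", 3, 1),
    ])
    def test_row_cardinality_and_bijection(self, scheme, radix, unit_len):
        table = build_rule_table(scheme)
        assert table.radix == radix and table.unit_len == unit_len
        for row in table.rows.values():
            assert len(row) == radix == len(set(row))

    def test_r0b9_rows_exclude_homodimers_and_context_starts(self):
        table = build_rule_table("R0-B9")
        for context, row in table.rows.items():
            assert all(u[0] != u[1] for u in row)
            assert all(u[0] != context for u in row)

    def test_r1b12_rows_are_the_nonhomodimers(self):
        table = build_rule_table("R1-B12")
        for row in table.rows.values():
            assert sorted(row) == sorted(
                u for u in codec.DIMERS if u[0] != u[1]
            )

    def test_b4_worked_example_assignments(self):
        table = build_rule_table("Rinf-B4")
        assert table.rows["A"][3] == "C"
        assert table.rows["C"][1] == "G"
        assert table.rows["C"][2] == "C"
        assert table.rows["G"][3] == "T"
        assert table.rows["T"][0] == "G"

    def test_override_must_keep_bijection(self):
        with pytest.raises(InvalidTableError):
            build_rule_table("Rinf-B4", overrides={"A": ("A", "A", "C", "G")})

    def test_override_must_respect_run_constraint(self):
        # a unit starting with the context base breaks the R0 guarantee
        with pytest.raises(InvalidTableError):
            build_rule_table(
                "R0-B3", overrides={"A": ("A", "C", "G")}
            )

    def test_json_round_trip(self, tmp_path):
        table = build_rule_table("R0-B9")
        path = tmp_path / "r0b9.json"
        table.save(path)
        loaded = RuleTable.load(path)
        assert loaded.rows == dict(table.rows)
        assert loaded.initiator == table.initiator
        assert math.isinf(build_rule_table("Rinf-B16").max_run)

    def test_scheme_aliases(self):
        assert codec.canonical_scheme("r9") == "R0-B9"
        assert codec.canonical_scheme("R∞-B16") == "Rinf-B16"
        with pytest.raises(FormatError):
            codec.canonical_scheme("R5-B7")


class TestEncodeDecode:
    def test_worked_encoding(self):
        table = build_rule_table("Rinf-B4")
        assert encode_sequence("1110011100", table, guard=False) == "ACCGTG"
        assert decode_sequence("ACCGTG", table, guard=False) == "1110011100"

    def test_empty_payload_reduces_to_guard_bit(self):
        table = build_rule_table("R0-B9")
        seq = encode_sequence("", table)
        assert seq.startswith("AT") and len(seq) == 4
        assert decode_sequence(seq, table) == ""

    @pytest.mark.parametrize("scheme,length", [
        ("Rinf-B16", 8196), ("Rinf-B4", 8194), ("R1-B12", 9144),
        ("R0-B9", 10340), ("R0-B3", 10339),
    ])
    def test_encoded_lengths_16384_bits(self, scheme, length, random_bits_16384):
        assert len(encode_sequence(random_bits_16384, build_rule_table(scheme))) == length

    def test_homopolymer_impossible_under_r0_is_corrupt(self):
        with pytest.raises(CorruptSequenceError):
            decode_sequence("ATAAAT", build_rule_table("R0-B9"))

    def test_wrong_initiator_is_format_error(self):
        with pytest.raises(FormatError):
            decode_sequence("CCAT", build_rule_table("R0-B9"))

    def test_round_trip_all_schemes_fuzzed(self, fuzz_payloads):
        tables = {s: build_rule_table(s) for s in RULES}
        for bits in fuzz_payloads:
            for scheme, table in tables.items():
                assert decode_sequence(encode_sequence(bits, table), table) == bits

    def test_encoded_length_depends_only_on_bit_length(self):
        table = build_rule_table("R0-B3")
        lengths = {len(encode_sequence(b * 333, table)) for b in "01"}
        assert len(lengths) == 1


class TestSimpleMapping:
    def test_mapping_table(self):
        assert simple_map("00011011") == "ACGT"
        assert simple_unmap("ACGT") == "00011011"

    def test_empty(self):
        assert simple_map("") == ""
        assert simple_unmap("") == ""

    def test_16384_bits_give_8192_nt(self, random_bits_16384):
        assert len(simple_map(random_bits_16384)) == 8192

    def test_odd_length_errors(self):
        with pytest.raises(PaddingError):
            simple_map("101")

    @given(st.text(alphabet="01", max_size=128).map(lambda s: s[: len(s) // 2 * 2]))
    def test_mutually_inverse(self, bits):
        assert simple_unmap(simple_map(bits)) == bits


class TestStrands:
    def test_full_payload_gives_106_nt_strand(self):
        (strand,) = assemble_strands("A" * 57)
        assert len(strand) == 106
        assert strand.forward_region == "ACACGACGCTCTTCCGATCT"
        assert strand.reverse_region == "AGATCGGAAGAGCACACGTCT"
        assert len(strand.index_region) == 8

    def test_two_chunks_with_ordinals(self):
        strands = assemble_strands("AC" * 57, chunk=57)  # 114 nt
        assert [s.ordinal for s in strands] == [0, 1]
        assert strands[0].index_region == simple_map(format(0, "016b"))
        assert strands[1].index_region == simple_map(format(1, "016b"))

    def test_r0b9_sequence_strand_count(self, random_bits_16384):
        seq = encode_sequence(random_bits_16384, build_rule_table("R0-B9"))
        strands = assemble_strands(seq)
        assert len(strands) == 182
        assert len(strands[-1].payload) == 23
        assert all(len(s) == 106 for s in strands[:-1])

    def test_payload_reassembles(self):
        payload = "ACGTTGCA" * 40
        strands = assemble_strands(payload)
        assert "".join(s.payload for s in strands) == payload

    def test_index_overflow(self):
        with pytest.raises(IndexOverflowError):
            assemble_strands("A" * 70000, chunk=1)


class TestSequenceIdentity:
    def test_identical(self):
        assert sequence_identity("ACGT" * 14 + "A", "ACGT" * 14 + "A") == 100.0

    def test_single_mismatch_57nt(self):
        ref = "ACGT" * 14 + "A"
        read = ref[:-1] + "C"
        assert sequence_identity(read, ref) == pytest.approx(100 * 56 / 57)

    def test_length_difference_counts_as_errors(self):
        assert sequence_identity("ACGTACGT", "ACGT") == pytest.approx(50.0)
        assert sequence_identity("ACGT", "ACGTACGT") == pytest.approx(50.0)

    def test_empty_reference_undefined(self):
        with pytest.raises(UndefinedMetricError):
            sequence_identity("ACGT", "")


class TestFastaIO:
    def test_fasta_round_trip(self, tmp_path):
        path = tmp_path / "seqs.fasta"
        records = [("R0-B9_0", "ACGTACGT"), ("R0-B9_1", "TTGGCCAA")]
        codec.write_fasta(records, path)
        assert codec.read_fasta(path) == records

    def test_fastq_reading(self, tmp_path):
        path = tmp_path / "reads.fastq"
        path.write_text("@read1\nACGT\n+\nIIII\n")
        assert codec.read_seqs(path) == [("read1", "ACGT")]
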