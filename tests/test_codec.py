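"""Unit tests for the compression / fragmentation / DNA-mapping pipeline."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dnastore import codec
from dnastore.codec import (bases_to_bits, bits_to_bases, compress, decompress,
                            fragment_payload, make_header, parse_header)
from dnastore.error_models import substitute_bases
from dnastore.ldpc import ChannelSpec


class TestCompression:
    def test_empty_round_trip(self):
        assert decompress(compress(b"")) == b""

    def test_fixture_round_trip_bit_exact(self, fixture_image):
        assert len(fixture_image) == 438
        assert decompress(compress(fixture_image)) == fixture_image

    def test_degenerate_input_strictly_shrinks(self):
        raw = b"\x55" * 1024
        assert len(compress(raw)) < len(raw)

    @given(st.binary(max_size=400))
    @settings(max_examples=30, deadline=None)
    def test_lossless_for_arbitrary_bytes(self, raw):
        assert decompress(compress(raw)) == raw


class TestFragmentation:
    def test_exact_division_has_no_padding(self):
        frags = fragment_payload(b"\xAB" * 12, n_fragments=6, k=16)
        assert len(frags) == 6
        assert [f.pad_len for f in frags] == [0] * 6
        assert all(f.info_bits.size == 16 for f in frags)

    def test_tail_padding_is_recorded(self):
        frags = fragment_payload(b"\x01" * 11, n_fragments=6, k=16)
        assert frags[-1].pad_len == 8
        assert [f.pad_len for f in frags[:-1]] == [0] * 5

    def test_overflow_raises(self):
        with pytest.raises(codec.PayloadTooLargeError):
            fragment_payload(b"\x00" * 13, n_fragments=6, k=16)

    @given(st.binary(min_size=1, max_size=96), st.integers(1, 8))
    @settings(max_examples=50, deadline=None)
    def test_reassembly_in_address_order_is_exact(self, raw, n_fragments):
        k = 8 * ((len(raw) + n_fragments - 1) // n_fragments + 1)
        frags = fragment_payload(raw, n_fragments, k)
        assert [f.address for f in frags] == list(range(n_fragments))
        bits = np.concatenate([f.info_bits[:k - f.pad_len] for f in frags])
        assert np.packbits(bits).tobytes()[:len(raw)] == raw


class TestBaseMapping:
    def test_documented_digit_table(self):
        assert bits_to_bases([0, 0, 0, 1, 1, 0, 1, 1]) == "ATCG"
        assert bases_to_bits("GATC").tolist() == [1, 1, 0, 0, 0, 1, 1, 0]
        assert bases_to_bits("A" * 10).tolist() == [0] * 20

    def test_empty_and_odd_inputs(self):
        assert bits_to_bases([]) == ""
        with pytest.raises(ValueError):
            bits_to_bases([1, 0, 1])

    def test_invalid_symbol_error_names_position(self):
        with pytest.raises(ValueError, match="position 2"):
            bases_to_bits("ACNT")

    @given(st.lists(st.integers(0, 1), min_size=0, max_size=64).filter(
        lambda b: len(b) % 2 == 0))
    @settings(max_examples=50, deadline=None)
    def test_mapping_is_a_bijection(self, bits):
        assert bases_to_bits(bits_to_bases(bits)).tolist() == bits


class TestHeaders:
    def test_headers_are_mutually_distant(self):
        headers = [make_header(a, 6) for a in range(6)]
        for i in range(6):
            for j in range(i + 1, 6):
                dist = sum(x != y for x, y in zip(headers[i], headers[j]))
                assert dist >= 3

    def test_parse_inverts_make(self):
        for total in range(1, 7):
            for a in range(total):
                assert parse_header(make_header(a, total)) == (a, total)

    def test_majority_repair_of_one_error_per_digit(self):
        h = make_header(3, 6)
        corrupted = "C" + h[1:]  # damage one copy of the first digit
        assert parse_header(corrupted) == (3, 6)

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            make_header(6, 6)
        with pytest.raises(ValueError):
            make_header(0, 5000)


class TestMessageRoundTrip:
    def test_blocks_are_720_bases_with_distinct_headers(self, encoded_fixture):
        blocks, container = encoded_fixture
        assert len(blocks) == 6
        assert all(len(b) == 720 for b in blocks)
        assert len({b.header_bases for b in blocks}) == 6
        assert container.pad_lens[-1] >= 0

    def test_clean_decode_is_bit_exact(self, encoded_fixture, fixture_image):
        blocks, container = encoded_fixture
        out = codec.decode_message([b.sequence for b in blocks], container)
        assert out == fixture_image

    def test_decode_is_contig_order_invariant(self, encoded_fixture, fixture_image):
        blocks, container = encoded_fixture
        seqs = [b.sequence for b in blocks]
        shuffled = [seqs[i] for i in (4, 0, 5, 2, 1, 3)]
        assert codec.decode_message(shuffled, container) == fixture_image

    def test_recovery_under_two_percent_substitution(self, encoded_fixture,
                                                     fixture_image):
        blocks, container = encoded_fixture
        noisy = [substitute_bases(b.sequence, 0.02, 40 + i)
                 for i, b in enumerate(blocks)]
        out = codec.decode_message(noisy, container, ChannelSpec(0.02))
        assert out == fixture_image

    def test_missing_block_names_absent_address(self, encoded_fixture):
        blocks, container = encoded_fixture
        seqs = [b.sequence for b in blocks if b.address != 3]
        with pytest.raises(codec.MissingBlockError, match=r"\[3\]"):
            codec.decode_message(seqs, container)

    def test_duplicated_block_is_reported(self, encoded_fixture):
        blocks, container = encoded_fixture
        seqs = [b.sequence for b in blocks] + [blocks[2].sequence]
        with pytest.raises(codec.DuplicateBlockError):
            codec.decode_message(seqs, container)

    @given(st.binary(min_size=1, max_size=470))
    @settings(max_examples=10, deadline=None)
    def test_end_to_end_identity_for_random_payloads(self, raw):
        """Any payload within capacity survives the full pipeline."""
        try:
            blocks, container = codec.encode_message(raw)
        except codec.PayloadTooLargeError:
            return  # incompressible payloads may exceed the 6-block capacity
        out = codec.decode_message([b.sequence for b in blocks], container)
        assert out == raw
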