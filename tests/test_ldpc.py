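"""Unit tests for LDPC construction, encoding and belief propagation."""

import numpy as np
import pytest

from dnastore.ldpc import (ChannelSpec, build_regular_code, ldpc_decode,
                           ldpc_encode, read_alist, syndrome, write_alist)

from conftest import all_codewords


def gf2_rank(M):
    """Independent rank oracle: plain integer elimination over GF(2)."""
    M = [int("".join(map(str, row)), 2) for row in M.tolist()]
    rank = 0
    while M:
        pivot = max(M)
        if pivot == 0:
            break
        M.remove(pivot)
        top = pivot.bit_length()
        M = [(m ^ pivot) if m.bit_length() == top else m for m in M]
        rank += 1
    return rank


class TestConstruction:
    def test_shape_column_weight_and_rank(self, small_code):
        H = small_code.H
        assert H.shape == (6, 12)
        assert set(np.unique(H)) <= {0, 1}
        assert (H.sum(axis=0) == 3).all()
        assert gf2_rank(H) == 6

    def test_production_geometry(self, prod_code):
        assert prod_code.n == 1392 and prod_code.k == 640
        assert (prod_code.H.sum(axis=0) == 3).all()
        assert (prod_code.H.sum(axis=0) >= 2).all()
        assert 0 < prod_code.rate < 1
        assert gf2_rank(prod_code.H) == prod_code.m

    def test_construction_is_deterministic(self):
        build = build_regular_code.__wrapped__  # bypass the memo cache
        a = build(12, 6, 3, 1)
        b = build(12, 6, 3, 1)
        assert np.array_equal(a.H, b.H)
        c = build(12, 6, 3, 2)
        assert not np.array_equal(a.H, c.H)

    def test_invalid_parameters_raise(self):
        with pytest.raises(ValueError):
            build_regular_code(6, 6, 3, 0)
        with pytest.raises(ValueError):
            build_regular_code(12, 6, 1, 0)


class TestEncoding:
    def test_all_codewords_satisfy_parity(self, small_code):
        words = all_codewords(small_code)
        assert words.shape == (64, 12)
        assert not ((small_code.H @ words.T) % 2).any()

    def test_zero_maps_to_zero_and_encoding_is_injective(self, small_code):
        assert not ldpc_encode(np.zeros(6, dtype=np.uint8), small_code).any()
        words = all_codewords(small_code)
        assert len({w.tobytes() for w in words}) == 64

    def test_systematic_positions_carry_info(self, small_code):
        rng = np.random.default_rng(0)
        for _ in range(10):
            info = rng.integers(0, 2, size=6).astype(np.uint8)
            cw = ldpc_encode(info, small_code)
            assert np.array_equal(cw[small_code.info_cols], info)

    def test_length_mismatch_raises(self, small_code):
        with pytest.raises(ValueError):
            ldpc_encode(np.zeros(5, dtype=np.uint8), small_code)
        with pytest.raises(ValueError):
            syndrome(np.zeros(11, dtype=np.uint8), small_code)


class TestSyndrome:
    def test_single_flip_gives_matrix_column(self, small_code):
        cw = ldpc_encode(np.array([1, 0, 1, 1, 0, 0], dtype=np.uint8), small_code)
        for j in range(12):
            flipped = cw.copy()
            flipped[j] ^= 1
            assert np.array_equal(syndrome(flipped, small_code), small_code.H[:, j])

    def test_random_non_codeword_detected(self, small_code):
        words = {w.tobytes() for w in all_codewords(small_code)}
        rng = np.random.default_rng(3)
        hits = 0
        for _ in range(20):
            v = rng.integers(0, 2, size=12).astype(np.uint8)
            if v.tobytes() not in words:
                hits += 1
                assert syndrome(v, small_code).any()
        assert hits > 0


class TestDecoding:
    def test_valid_codeword_is_returned_unchanged(self, small_code):
        info = np.array([0, 1, 1, 0, 1, 0], dtype=np.uint8)
        cw = ldpc_encode(info, small_code)
        for p in (0.0, 0.05, 0.2):
            out, converged = ldpc_decode(cw, small_code, ChannelSpec(p))
            assert converged
            assert np.array_equal(out, info)

    def test_exhaustive_zero_error_round_trip(self, small_code):
        chan = ChannelSpec(0.05)
        for x in range(64):
            info = np.array([(x >> (5 - i)) & 1 for i in range(6)], dtype=np.uint8)
            out, converged = ldpc_decode(ldpc_encode(info, small_code),
                                         small_code, chan)
            assert converged and np.array_equal(out, info)

    def test_heavy_corruption_can_fail_to_converge(self, small_code):
        """Some 5-bit error pattern must defeat a 12-bit code."""
        cw = ldpc_encode(np.zeros(6, dtype=np.uint8), small_code)
        words = all_codewords(small_code)
        rng = np.random.default_rng(7)
        failed = 0
        for _ in range(50):
            pos = rng.choice(12, size=5, replace=False)
            rx = cw.copy()
            rx[pos] ^= 1
            out, converged = ldpc_decode(rx, small_code, ChannelSpec(0.05))
            if not converged or not np.array_equal(out, np.zeros(6, dtype=np.uint8)):
                failed += 1
        assert failed > 0

    def test_block_error_rate_monotone_in_channel_noise(self, small_code):
        """Paired-seed sweep: harder channels never decode more reliably."""
        from dnastore.error_models import substitute_bases
        from dnastore.codec import bases_to_bits, bits_to_bases
        info = np.array([1, 1, 0, 1, 0, 0], dtype=np.uint8)
        cw = ldpc_encode(info, small_code)
        bases = bits_to_bases(cw)
        failures = []
        for p in (0.0, 0.1, 0.45):
            f = 0
            for rep in range(40):
                rx = bases_to_bits(substitute_bases(bases, p, 900 + rep))
                out, conv = ldpc_decode(rx, small_code, ChannelSpec(max(p, 0.01)))
                if not conv or not np.array_equal(out, info):
                    f += 1
            failures.append(f)
        assert failures == sorted(failures)


def test_alist_round_trip(tmp_path, small_code, prod_code):
    for code in (small_code, prod_code):
        path = tmp_path / "code.alist"
        write_alist(code, path)
        H = read_alist(path)
        assert np.array_equal(H, code.H)
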