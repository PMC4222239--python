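"""The storage pipeline: compress, fragment, protect, write DNA; and back.

A binary message is LZMA-compressed, split into ``n_fragments``
non-overlapping slices of k bits each (the tail zero-padded, pad lengths
recorded), each slice LDPC-encoded, and the n-bit codeword mapped two
bits per base onto DNA.  A fixed-length address header (not
error-protected, but 3x base-repetition coded and recoverable by
nearest-match) is prepended, giving one *DNA information block* per
fragment.  With the default production code every block is exactly
720 bases: 24 header bases + 696 payload bases (n = 1392 bits, k = 640,
rate ~ 0.46).

Bit conventions, fixed once for interoperability: bytes are traversed
most-significant bit first; consecutive bit pairs, MSB first, map onto
bases via A=0, T=1, C=2, G=3 (00->A, 01->T, 10->C, 11->G).
"""

from __future__ import annotations

import lzma
import zlib
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

from .ldpc import ChannelSpec, LDPCCode, build_regular_code, ldpc_decode, ldpc_encode
from .container import StorageContainer

__all__ = [
    "BASES", "DEFAULT_N_FRAGMENTS", "HEADER_LEN", "HEADER_REPEAT",
    "MessagePayload", "Fragment", "DNABlock",
    "DecodeError", "MissingBlockError", "DuplicateBlockError",
    "BlockDecodeError", "ChecksumMismatchError", "PayloadTooLargeError",
    "compress", "decompress", "fragment_payload",
    "bits_to_bases", "bases_to_bits", "make_header", "parse_header",
    "production_code", "encode_message", "decode_message",
]

BASES = "ATCG"  # index == quaternary digit: A=0, T=1, C=2, G=3

# Production geometry: 24 header bases + n/2 payload bases = 720 per block.
DEFAULT_N_FRAGMENTS = 6
HEADER_LEN = 24
HEADER_REPEAT = 3
_HEADER_DIGITS = HEADER_LEN // HEADER_REPEAT // 2  # 4 quaternary digits each for address, total
PRODUCTION_N = 1392
PRODUCTION_K = 640
PRODUCTION_COL_WEIGHT = 3
PRODUCTION_CODE_SEED = 7
LZMA_PRESET = 6

_BASE2DIGIT = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _BASE2DIGIT[ord(_b)] = _i
_DIGIT2BASE = np.frombuffer(BASES.encode(), dtype=np.uint8)


class DecodeError(Exception):
    """Base class for message-decoding failures."""


class MissingBlockError(DecodeError):
    def __init__(self, addresses):
        self.addresses = sorted(addresses)
        super().__init__(f"missing DNA block address(es): {self.addresses}")


class DuplicateBlockError(DecodeError):
    def __init__(self, address):
        self.address = address
        super().__init__(f"duplicate DNA block for address {address}")


class BlockDecodeError(DecodeError):
    """LDPC decoding did not converge for a block."""

    def __init__(self, address):
        self.address = address
        super().__init__(f"LDPC decoding did not converge for block {address}")


class ChecksumMismatchError(DecodeError):
    def __init__(self, expected, got):
        super().__init__(f"CRC-32 mismatch: container says {expected:#010x}, "
                         f"decoded payload gives {got:#010x}")


class PayloadTooLargeError(ValueError):
    pass


@dataclass
class MessagePayload:
    """A named binary message with its lossless LZMA form."""

    name: str
    raw: bytes
    compressed: bytes


@dataclass
class Fragment:
    """One non-overlapping k-bit slice of the compressed bit stream."""

    address: int
    total: int
    info_bits: np.ndarray
    pad_len: int


@dataclass
class DNABlock:
    """One addressable DNA information block: header + protected payload."""

    address: int
    header_bases: str
    payload_bases: str

    @property
    def sequence(self) -> str:
        return self.header_bases + self.payload_bases

    def __len__(self) -> int:
        return len(self.header_bases) + len(self.payload_bases)


def compress(raw: bytes, preset: int = LZMA_PRESET) -> bytes:
    """LZMA-compress (classic .lzma container, dictionary coding)."""
    return lzma.compress(raw, format=lzma.FORMAT_ALONE, preset=preset)


def decompress(compressed: bytes) -> bytes:
    return lzma.decompress(compressed, format=lzma.FORMAT_ALONE)


_PAD_STREAM_SEED = 1_000_003


def fragment_payload(compressed: bytes, n_fragments: int, k: int) -> list[Fragment]:
    """Split a compressed byte string into n_fragments disjoint k-bit slices.

    Fragments are filled in address order; the unfilled tail of the last
    occupied fragment (and any wholly empty fragments) is padded with a
    deterministic pseudorandom bit stream, with the pad length recorded
    per fragment.  Random rather than zero padding keeps every encoded
    block content-bearing: an all-zero pad would synthesize long
    single-base runs (the all-zero codeword maps to a poly-A payload),
    which no overlap assembler can reconstruct unambiguously.  The pad is
    stripped by recorded length at decode, so its content never matters.
    """
    if n_fragments < 1:
        raise ValueError("n_fragments must be >= 1")
    if not compressed:
        raise ValueError("compressed payload is empty")
    bits = np.unpackbits(np.frombuffer(compressed, dtype=np.uint8))
    if bits.size > n_fragments * k:
        raise PayloadTooLargeError(
            f"payload of {bits.size} bits exceeds capacity "
            f"{n_fragments} x {k} = {n_fragments * k} bits")
    fragments = []
    for a in range(n_fragments):
        chunk = bits[a * k:(a + 1) * k]
        pad = k - chunk.size
        info = np.empty(k, dtype=np.uint8)
        info[:chunk.size] = chunk
        if pad:
            pad_rng = np.random.default_rng(_PAD_STREAM_SEED + a)
            info[chunk.size:] = pad_rng.integers(0, 2, size=pad, dtype=np.uint8)
        fragments.append(Fragment(address=a, total=n_fragments,
                                  info_bits=info, pad_len=pad))
    return fragments


def bits_to_bases(bits) -> str:
    """Map a bit vector, two bits per base MSB first, onto DNA (A0 T1 C2 G3)."""
    b = np.asarray(bits, dtype=np.uint8).ravel()
    if b.size % 2:
        raise ValueError(f"bit vector length must be even, got {b.size}")
    digits = 2 * b[0::2] + b[1::2]
    return _DIGIT2BASE[digits].tobytes().decode("ascii")


def bases_to_bits(seq: str) -> np.ndarray:
    """Exact inverse of :func:`bits_to_bases`."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    digits = _BASE2DIGIT[arr]
    bad = np.nonzero(digits == 255)[0]
    if bad.size:
        raise ValueError(f"invalid base {seq[bad[0]]!r} at position {int(bad[0])}")
    bits = np.empty(2 * digits.size, dtype=np.uint8)
    bits[0::2] = digits >> 1
    bits[1::2] = digits & 1
    return bits


def _quaternary_digits(x: int, ndigits: int = _HEADER_DIGITS) -> list[int]:
    return [(x >> (2 * (ndigits - 1 - i))) & 3 for i in range(ndigits)]


def make_header(address: int, total: int) -> str:
    """Fixed 24-base address header: 4 quaternary digits of the address and
    4 of the total block count, each digit written as 3 repeated bases.

    Distinct addresses differ in at least HEADER_REPEAT positions, so the
    decoder can identify headers by nearest match without side information.
    """
    capacity = 4 ** _HEADER_DIGITS
    if not 0 < total <= capacity:
        raise ValueError(f"total must be in [1, {capacity}], got {total}")
    if not 0 <= address < total:
        raise ValueError(f"address {address} out of range for total {total}")
    digits = _quaternary_digits(address) + _quaternary_digits(total)
    return "".join(BASES[d] * HEADER_REPEAT for d in digits)


def parse_header(header: str) -> tuple[int, int]:
    """Decode (address, total) by per-digit majority over the repetitions."""
    if len(header) != HEADER_LEN:
        raise ValueError(f"header must be {HEADER_LEN} bases, got {len(header)}")
    digits = []
    for i in range(0, HEADER_LEN, HEADER_REPEAT):
        votes = [int(_BASE2DIGIT[ord(c)]) for c in header[i:i + HEADER_REPEAT]]
        votes = [v for v in votes if v != 255]
        if not votes:
            raise ValueError(f"unreadable header digit at base {i}")
        digits.append(int(max(set(votes), key=lambda d: (votes.count(d), -d))))
    half = _HEADER_DIGITS
    address = sum(d << (2 * (half - 1 - i)) for i, d in enumerate(digits[:half]))
    total = sum(d << (2 * (half - 1 - i)) for i, d in enumerate(digits[half:]))
    return address, total


_production_cache: dict[tuple, LDPCCode] = {}


def production_code(seed: int = PRODUCTION_CODE_SEED) -> LDPCCode:
    """The default production code: n=1392, k=640, column weight 3."""
    key = (PRODUCTION_N, PRODUCTION_K, PRODUCTION_COL_WEIGHT, seed)
    if key not in _production_cache:
        _production_cache[key] = build_regular_code(*key)
    return _production_cache[key]


def encode_message(raw: bytes, n_fragments: int = DEFAULT_N_FRAGMENTS,
                   code: LDPCCode | None = None,
                   name: str = "message") -> tuple[list[DNABlock], StorageContainer]:
    """Encode a binary message into DNA information blocks plus metadata.

    Returns one block per fragment (header + LDPC-protected payload) and a
    :class:`StorageContainer` carrying everything the decoder needs: code
    parameters, pad lengths, compressed length and a CRC-32 of the raw bytes.
    """
    if code is None:
        code = production_code()
    payload = MessagePayload(name=name, raw=raw, compressed=compress(raw))
    fragments = fragment_payload(payload.compressed, n_fragments, code.k)
    blocks = [
        DNABlock(address=f.address,
                 header_bases=make_header(f.address, f.total),
                 payload_bases=bits_to_bases(ldpc_encode(f.info_bits, code)))
        for f in fragments
    ]
    container = StorageContainer(
        name=name,
        raw_len=len(raw),
        crc32=zlib.crc32(raw) & 0xFFFFFFFF,
        compressed_len=len(payload.compressed),
        preset=LZMA_PRESET,
        n_fragments=n_fragments,
        code_n=code.n, code_k=code.k,
        code_col_weight=code.col_weight, code_seed=code.seed,
        header_len=HEADER_LEN,
        pad_lens=[f.pad_len for f in fragments],
    )
    return blocks, container


def _locate_header(contig: str, header: str) -> tuple[int, int]:
    """Best (distance, offset) of a candidate header within a contig."""
    hlen = len(header)
    carr = np.frombuffer(contig.encode("ascii"), dtype=np.uint8)
    harr = np.frombuffer(header.encode("ascii"), dtype=np.uint8)
    if carr.size < hlen:
        pad = np.full(hlen - carr.size, 0, dtype=np.uint8)
        carr = np.concatenate([carr, pad])
    windows = np.lib.stride_tricks.sliding_window_view(carr, hlen)
    dists = (windows != harr).sum(axis=1)
    off = int(np.argmin(dists))
    return int(dists[off]), off


def decode_message(contigs: list[str], container: StorageContainer,
                   channel: ChannelSpec | None = None,
                   max_iter: int = 100) -> bytes:
    """Recover the original bytes from (possibly error-bearing) contigs.

    Addresses are identified by nearest-header matching: every candidate
    header is slid along every contig and the globally minimal one-to-one
    assignment of contigs to addresses is taken.  Payload bases after the
    header are mapped back to bits and LDPC-decoded; fragments are
    concatenated in address order, padding stripped, the byte stream
    LZMA-decompressed and the CRC-32 verified.

    Raises :class:`MissingBlockError`, :class:`DuplicateBlockError`,
    :class:`BlockDecodeError` or :class:`ChecksumMismatchError` as
    distinct failure states.
    """
    if channel is None:
        channel = ChannelSpec(0.0)
    total = container.n_fragments
    code = build_regular_code(container.code_n, container.code_k,
                              container.code_col_weight, container.code_seed)
    headers = [make_header(a, total) for a in range(total)]
    if len(contigs) < total:
        # Provisional best-match so the error can name the absent addresses.
        claimed = set()
        for contig in contigs:
            d = [_locate_header(contig, h)[0] for h in headers]
            claimed.add(int(np.argmin(d)))
        raise MissingBlockError(set(range(total)) - claimed)

    dist = np.zeros((len(contigs), total), dtype=np.int64)
    offs = np.zeros((len(contigs), total), dtype=np.int64)
    for i, contig in enumerate(contigs):
        for a, h in enumerate(headers):
            dist[i, a], offs[i, a] = _locate_header(contig, h)
    rows, cols = linear_sum_assignment(dist)
    assigned = {int(a): int(i) for i, a in zip(rows, cols)}
    if len(contigs) > total:
        leftover = set(range(len(contigs))) - set(int(i) for i in rows)
        for i in leftover:
            exact = np.nonzero(dist[i] == 0)[0]
            if exact.size:
                raise DuplicateBlockError(int(exact[0]))
    missing = set(range(total)) - set(assigned)
    if missing:
        raise MissingBlockError(missing)

    half = code.n // 2
    info_parts = []
    for a in range(total):
        contig = contigs[assigned[a]]
        start = offs[assigned[a], a] + container.header_len
        payload = contig[start:start + half]
        if len(payload) < half:
            payload = payload + "A" * (half - len(payload))
        info, converged = ldpc_decode(bases_to_bits(payload), code, channel, max_iter)
        if not converged:
            raise BlockDecodeError(a)
        pad = container.pad_lens[a]
        info_parts.append(info[:code.k - pad])
    bits = np.concatenate(info_parts)
    data = np.packbits(bits).tobytes()[:container.compressed_len]
    raw = decompress(data)
    crc = zlib.crc32(raw) & 0xFFFFFFFF
    if crc != container.crc32:
        raise ChecksumMismatchError(container.crc32, crc)
    if len(raw) != container.raw_len:
        raise ChecksumMismatchError(container.crc32, crc)
    return raw
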