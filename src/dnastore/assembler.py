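"""Greedy overlap-consensus assembly of DNA information blocks.

The decoder side of the storage system recovers each 720-base block from
short sequencing reads by a seed-extension walk in the style of SSAKE:
starting from the block's known address header, reads whose prefix
matches the growing contig's 3' suffix by at least a minimum overlap
(default 50 bases, SSAKE's ``-m 50``) vote on the next base; the majority
base is appended when supported by at least ``min_depth`` reads
(default 1, SSAKE's ``-w 1``).  When the 3' end is exhausted the contig
is reverse-complemented and the walk repeats on the other strand.  Ties
are broken deterministically (A < C < G < T).

Reads are first quality-trimmed: the longest prefix whose bases all have
Phred quality >= ``min_q`` (default 32) is kept, and reads shorter than
``min_keep_len`` (default 25) after trimming — or containing N — are
discarded.

Because the seed header is shorter than the 50-base minimum overlap, the
effective overlap requirement ramps with the contig length L as
``min(min_overlap, max(16, L - 16))``; 16 is the hard floor below which
overlaps are never accepted.  Without the ramp a sub-50-base seed could
never recruit its first read.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SequencingRead", "Contig", "reverse_complement",
    "quality_trim", "build_prefix_index", "PrefixIndex",
    "extend_seed", "assemble_blocks", "contig_report",
    "MIN_ANCHOR",
]

MIN_ANCHOR = 16  # hard floor on accepted overlap length
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_TIE_ORDER = "ACGT"  # lexicographic tie-break on equal vote counts


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class SequencingRead:
    """One FASTQ record: bases with per-base Phred qualities and mate info."""

    id: str
    bases: str
    quals: list[int]
    mate: int | None = None  # None, 1 or 2
    pair_id: str = ""

    def __post_init__(self) -> None:
        if len(self.bases) != len(self.quals):
            raise ValueError(
                f"read {self.id}: {len(self.bases)} bases but {len(self.quals)} qualities")
        if any(q < 0 for q in self.quals):
            raise ValueError(f"read {self.id}: negative Phred score")


@dataclass
class Contig:
    """Assembled consensus with per-position vote counts and depth."""

    consensus: str
    counts: list[dict[str, int]]
    coverage: np.ndarray
    seed_id: str = ""

    def __len__(self) -> int:
        return len(self.consensus)

    @property
    def mean_coverage(self) -> float:
        return float(np.mean(self.coverage)) if len(self.coverage) else 0.0


def quality_trim(read: SequencingRead, min_q: int = 32,
                 min_keep_len: int = 25) -> SequencingRead | None:
    """Keep the longest prefix with every quality >= min_q (3' trimming).

    Returns None when fewer than ``min_keep_len`` bases survive.
    """
    if min_q < 0:
        raise ValueError("min_q must be >= 0")
    n = len(read.quals)
    for i, q in enumerate(read.quals):
        if q < min_q:
            n = i
            break
    if n < min_keep_len:
        return None
    if n == len(read.bases):
        return read
    return SequencingRead(id=read.id, bases=read.bases[:n], quals=read.quals[:n],
                          mate=read.mate, pair_id=read.pair_id)


class PrefixIndex:
    """Prefix lookup over reads and their reverse complements.

    ``query(suffix)`` returns the ids of oriented reads whose prefix of
    length ``len(suffix)`` equals it; ``seq(id)`` gives the oriented read.
    Prefix lengths from MIN_ANCHOR up to len(read)-1 are indexed (a read
    must overhang by at least one base to vote).
    """

    def __init__(self, reads: list[SequencingRead], min_m: int = MIN_ANCHOR):
        self.min_m = min_m
        self._seqs: list[str] = []
        self._table: dict[str, list[int]] = {}
        self.max_read_len = 0
        for read in reads:
            if "N" in read.bases:
                continue
            for s in (read.bases, reverse_complement(read.bases)):
                sid = len(self._seqs)
                self._seqs.append(s)
                self.max_read_len = max(self.max_read_len, len(s))
                for m in range(min_m, len(s)):
                    self._table.setdefault(s[:m], []).append(sid)

    def query(self, suffix: str) -> list[int]:
        return self._table.get(suffix, [])

    def seq(self, sid: int) -> str:
        return self._seqs[sid]


def build_prefix_index(reads: list[SequencingRead]) -> PrefixIndex:
    """Index trimmed reads (both orientations) for overlap queries."""
    return PrefixIndex(reads)


def _effective_min_overlap(contig_len: int, min_overlap: int) -> int:
    return min(min_overlap, max(MIN_ANCHOR, contig_len - MIN_ANCHOR))


def _extend_right(contig: str, index: PrefixIndex, min_overlap: int,
                  min_depth: int) -> tuple[str, list[dict[str, int]]]:
    """Greedy 3' walk; returns (appended bases, per-appended-base votes).

    A read is retired once the walk has used its final base: past that
    point it lies entirely behind the frontier and could only re-anchor
    inside a repeat, where re-use would let the walk cycle forever.
    """
    ext = []
    counts: list[dict[str, int]] = []
    consumed: set[int] = set()
    while True:
        cur = contig + "".join(ext)
        L = len(cur)
        hi = min(L, index.max_read_len - 1)
        lo = _effective_min_overlap(L, min_overlap)
        votes: dict[str, int] = {}
        seen: set[int] = set()
        for m in range(hi, lo - 1, -1):
            for sid in index.query(cur[-m:]):
                if sid in seen or sid in consumed:
                    continue
                seen.add(sid)
                s = index.seq(sid)
                if len(s) > m:
                    b = s[m]
                    votes[b] = votes.get(b, 0) + 1
                    if m == len(s) - 1:
                        consumed.add(sid)
        if not votes:
            break
        best = min(votes, key=lambda b: (-votes[b], _TIE_ORDER.index(b)))
        if votes[best] < min_depth:
            break
        ext.append(best)
        counts.append(dict(votes))
        if len(ext) > 100_000:  # safety valve against pathological cycles
            break
    return "".join(ext), counts


def _complement_counts(counts: dict[str, int]) -> dict[str, int]:
    return {b.translate(_COMPLEMENT): c for b, c in counts.items()}


def extend_seed(seed: str, index: PrefixIndex, min_overlap: int = 50,
                min_depth: int = 1, seed_id: str = "") -> Contig:
    """Extend a seed in both directions by majority-vote overlap consensus.

    The seed itself contributes a count of 1 at each of its positions; an
    inextensible seed is returned unchanged as a contig.
    """
    if min_overlap < MIN_ANCHOR:
        raise ValueError(f"min_overlap must be >= {MIN_ANCHOR}")
    if min_depth < 1:
        raise ValueError("min_depth must be >= 1")
    right, right_counts = _extend_right(seed, index, min_overlap, min_depth)
    rc = reverse_complement(seed + right)
    left_rc, left_rc_counts = _extend_right(rc, index, min_overlap, min_depth)
    consensus = reverse_complement(rc + left_rc)
    # counts in final orientation: reversed+complemented left extension,
    # then the seed (count 1 per base), then the right extension.
    counts = ([_complement_counts(c) for c in reversed(left_rc_counts)]
              + [{b: 1} for b in seed]
              + right_counts)
    coverage = np.array([sum(c.values()) for c in counts], dtype=np.int64)
    return Contig(consensus=consensus, counts=counts, coverage=coverage,
                  seed_id=seed_id)


def assemble_blocks(reads: list[SequencingRead], headers: list[str],
                    min_overlap: int = 50, min_depth: int = 1) -> list[Contig]:
    """Assemble one contig per block header, in header order.

    Reads may support several contigs (no read claiming across blocks).
    Duplicate identical headers are ambiguous seeds and raise.
    """
    if len(set(headers)) != len(headers):
        raise ValueError("duplicate block headers: seeds are ambiguous")
    index = build_prefix_index(reads)
    return [extend_seed(h, index, min_overlap=min_overlap, min_depth=min_depth,
                        seed_id=f"block_{i}") for i, h in enumerate(headers)]


def contig_report(contigs: list[Contig], expected_len: int) -> pd.DataFrame:
    """Per-contig table: length, mean coverage, short flag."""
    return pd.DataFrame({
        "contig": [c.seed_id or f"contig_{i}" for i, c in enumerate(contigs)],
        "length": [len(c) for c in contigs],
        "mean_coverage": [round(c.mean_coverage, 3) for c in contigs],
        "short": [len(c) < expected_len for c in contigs],
    })
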