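"""Seeded stochastic channels and an Illumina-like paired-read simulator.

Two noise sources are modelled, both pure functions of (input,
parameters, seed):

* :func:`substitute_bases` — the memoryless base-substitution channel
  used for the error-tolerance sweep.  Each position is substituted
  independently with probability ``p_base``; the replacement is uniform
  over the other three bases.  The per-position uniform draws are taken
  before thresholding against ``p_base``, so runs with the same seed and
  increasing ``p_base`` have nested error sets (common random numbers).

* :func:`simulate_read_pairs` — 2 x 76 bp read pairs with a 200 bp
  insert, fragment starts uniform over the reference, and a per-base
  substitution/insertion/deletion profile.  The default profile is the
  empirical short-read error spectrum this codec is designed around:
  0.19% substitutions, 0.01% insertions, 0.38% deletions per base.
  Correct bases carry Phred Q40; erroneous (substituted or inserted)
  bases draw Q20–Q39 uniformly so that Q32 quality trimming has a real
  signal to act on.  At most one event occurs per template position
  (a single categorical draw).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .assembler import SequencingRead, reverse_complement

__all__ = [
    "ErrorProfile", "ReadSimSpec", "SimStats", "DEFAULT_PROFILE", "ZERO_PROFILE",
    "substitute_bases", "simulate_read_pairs", "tile_reads",
    "downsample_reads", "n_pairs_for_coverage",
]

_ACGT = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_ACGT)}
_Q_CORRECT = 40


@dataclass(frozen=True)
class ErrorProfile:
    """Per-base substitution / insertion / deletion probabilities."""

    p_sub: float = 0.0019
    p_ins: float = 0.0001
    p_del: float = 0.0038

    def __post_init__(self) -> None:
        for name in ("p_sub", "p_ins", "p_del"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ValueError(f"{name} must be in [0, 1), got {v}")
        if self.p_sub + self.p_ins + self.p_del >= 1.0:
            raise ValueError("total error probability must be < 1")


DEFAULT_PROFILE = ErrorProfile()
ZERO_PROFILE = ErrorProfile(0.0, 0.0, 0.0)


@dataclass(frozen=True)
class ReadSimSpec:
    """Read-pair geometry: 76 bp reads, 200 bp inserts by default."""

    coverage: float
    read_len: int = 76
    insert_size: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.read_len > self.insert_size:
            raise ValueError("read_len must not exceed insert_size")
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")


def substitute_bases(seq: str, p_base: float, seed: int) -> str:
    """Substitute each base independently with probability ``p_base``.

    Deterministic given (seq, p_base, seed); substitutes are uniform over
    the other three bases; length is preserved.  With a fixed seed the
    error sets are nested in ``p_base`` (the uniform draws are shared).
    """
    if not 0.0 <= p_base <= 1.0:
        raise ValueError(f"p_base must be in [0, 1], got {p_base}")
    if not seq:
        return seq
    rng = np.random.default_rng(seed)
    L = len(seq)
    u = rng.random(L)
    alt = rng.integers(0, 3, size=L)
    codes = np.array([_BASE_INDEX[b] for b in seq], dtype=np.int64)
    sub_codes = (codes + 1 + alt) % 4
    out = np.where(u < p_base, sub_codes, codes)
    return "".join(_ACGT[c] for c in out)


def n_pairs_for_coverage(coverage: float, reference_len: int, read_len: int) -> int:
    """ceil(coverage * reference_len / (2 * read_len)) read pairs."""
    return math.ceil(coverage * reference_len / (2 * read_len))


@dataclass
class SimStats:
    """Realized event tallies from one simulation run."""

    template_bases: int = 0
    n_sub: int = 0
    n_ins: int = 0
    n_del: int = 0


def _corrupt(template: str, profile: ErrorProfile, rng: np.random.Generator,
             stats: SimStats | None = None) -> tuple[str, list[int]]:
    """Apply the per-base error profile to one read template."""
    if stats is not None:
        stats.template_bases += len(template)
    if profile.p_sub == profile.p_ins == profile.p_del == 0.0:
        return template, [_Q_CORRECT] * len(template)
    u = rng.random(len(template))
    t_sub = profile.p_sub
    t_ins = t_sub + profile.p_ins
    t_del = t_ins + profile.p_del
    bases: list[str] = []
    quals: list[int] = []
    for i, b in enumerate(template):
        x = u[i]
        if x < t_sub:
            bases.append(_ACGT[(_BASE_INDEX[b] + 1 + int(rng.integers(3))) % 4])
            quals.append(int(rng.integers(20, 40)))
            if stats is not None:
                stats.n_sub += 1
        elif x < t_ins:
            bases.append(_ACGT[int(rng.integers(4))])
            quals.append(int(rng.integers(20, 40)))
            bases.append(b)
            quals.append(_Q_CORRECT)
            if stats is not None:
                stats.n_ins += 1
        elif x < t_del:
            if stats is not None:
                stats.n_del += 1
            continue
        else:
            bases.append(b)
            quals.append(_Q_CORRECT)
    return "".join(bases), quals


def simulate_read_pairs(reference: str, spec: ReadSimSpec,
                        profile: ErrorProfile = DEFAULT_PROFILE,
                        with_stats: bool = False):
    """Simulate paired 5'/3' reads from uniformly placed inserts.

    Mate 1 reads the 5' end of the insert on the forward strand; mate 2 is
    the reverse complement of the insert's 3' end.  The number of pairs is
    ``ceil(coverage * len(reference) / (2 * read_len))``.  With
    ``with_stats=True`` returns ``(reads, SimStats)`` with the realized
    substitution/insertion/deletion event counts.
    """
    if len(reference) < spec.insert_size:
        raise ValueError(
            f"reference ({len(reference)} bases) shorter than the "
            f"insert size ({spec.insert_size})")
    rng = np.random.default_rng(spec.seed)
    n_pairs = n_pairs_for_coverage(spec.coverage, len(reference), spec.read_len)
    starts = rng.integers(0, len(reference) - spec.insert_size + 1, size=n_pairs)
    reads: list[SequencingRead] = []
    stats = SimStats()
    for i, s in enumerate(starts):
        s = int(s)
        t1 = reference[s:s + spec.read_len]
        t2 = reverse_complement(
            reference[s + spec.insert_size - spec.read_len:s + spec.insert_size])
        pair = f"pair_{i}"
        for mate, template in ((1, t1), (2, t2)):
            bases, quals = _corrupt(template, profile, rng, stats)
            reads.append(SequencingRead(id=f"{pair}/{mate}", bases=bases,
                                        quals=quals, mate=mate, pair_id=pair))
    return (reads, stats) if with_stats else reads


def tile_reads(reference: str, read_len: int = 76, step: int = 3,
               quality: int = _Q_CORRECT) -> list[SequencingRead]:
    """Deterministic error-free reads tiling the reference.

    Start positions run 0, step, 2*step, ... with the final window
    forced to end flush with the reference, giving uniform coverage of
    roughly ``read_len / step`` fold.
    """
    if len(reference) < read_len:
        raise ValueError("reference shorter than read length")
    last = len(reference) - read_len
    starts = sorted(set(range(0, last + 1, step)) | {last})
    return [SequencingRead(id=f"tile_{s}", bases=reference[s:s + read_len],
                           quals=[quality] * read_len)
            for s in starts]


def downsample_reads(reads: list[SequencingRead], *, fraction: float | None = None,
                     target_coverage: float | None = None,
                     reference_len: int | None = None,
                     seed: int = 0) -> list[SequencingRead]:
    """Uniform subset of read *pairs* without replacement (mates kept together).

    Either ``fraction`` of the pairs, or the pair count implied by
    ``target_coverage`` over ``reference_len``.  Requesting more than is
    available raises.
    """
    order: list[str] = []
    groups: dict[str, list[SequencingRead]] = {}
    for r in reads:
        key = r.pair_id or r.id
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(r)
    n_groups = len(order)
    if fraction is not None:
        if not 0.0 <= fraction <= 1.0:
            raise ValueError("fraction must be in [0, 1]")
        n_keep = round(fraction * n_groups)
    elif target_coverage is not None:
        if reference_len is None:
            raise ValueError("reference_len is required with target_coverage")
        total_bases = sum(len(r.bases) for r in reads)
        available = total_bases / reference_len
        if target_coverage > available + 1e-9:
            raise ValueError(
                f"requested {target_coverage}x exceeds available {available:.2f}x")
        n_keep = round(n_groups * target_coverage / available)
    else:
        raise ValueError("give either fraction or target_coverage")
    rng = np.random.default_rng(seed)
    keep = set(rng.choice(n_groups, size=n_keep, replace=False).tolist())
    return [r for i, key in enumerate(order) if i in keep for r in groups[key]]
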