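"""In-silico characterisation of the codec: error tolerance and coverage.

Two studies define the operating envelope of the storage system:

* :func:`error_tolerance_sweep` — encode a payload, substitute bases in
  every block at rate p, decode; repeat over a grid of rates with
  seeded replicates.  The *tolerance threshold* is the largest grid rate
  up to which every grid point achieves full (bit-exact, CRC-verified)
  recovery in all replicates.  Replicate random streams are shared
  across grid points (common random numbers), so error sets are nested
  in p and the success curve is cleanly monotone.

* :func:`coverage_sweep` — simulate read pairs from one encoded block at
  a range of fold coverages, quality-trim, assemble from the block's
  header seed and score the consensus against the truth by global
  percent identity, averaged over seeded replicates.

Identity is scored with a global (Needleman-Wunsch) alignment, match +1,
mismatch -1, gap -2: contigs and references are near-full-length, and a
local aligner would hide terminal truncation.
"""

from __future__ import annotations

import json
import lzma
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import Align

from . import codec
from .assembler import build_prefix_index, extend_seed, quality_trim
from .error_models import DEFAULT_PROFILE, ErrorProfile, ReadSimSpec, \
    simulate_read_pairs, substitute_bases
from .ldpc import ChannelSpec, LDPCCode

__all__ = [
    "SweepResult", "CoverageCurve",
    "percent_identity", "error_tolerance_sweep", "coverage_sweep",
    "save_sweep_csv", "save_curve_csv",
]


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -2
    return aligner


_ALIGNER = _make_aligner()


def percent_identity(a: str, b: str) -> float:
    """Global-alignment percent identity: 100 * matches / alignment_length."""
    if not a or not b:
        raise ValueError("percent_identity requires two non-empty sequences")
    aln = _ALIGNER.align(a, b)[0]
    counts = aln.counts()
    length = counts.gaps + counts.identities + counts.mismatches
    return 100.0 * counts.identities / length


@dataclass
class SweepResult:
    """Error-tolerance sweep outcome."""

    grid: list[float]
    successes: list[int]
    reps: int
    seed: int
    threshold: float | None  # largest p with full recovery at every point <= p

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "p_base": self.grid,
            "successes": self.successes,
            "reps": self.reps,
            "success_rate": [s / self.reps for s in self.successes],
        })

    def manifest(self) -> dict:
        return {"experiment": "error_tolerance_sweep", "grid": self.grid,
                "reps": self.reps, "seed": self.seed, "threshold": self.threshold}


@dataclass
class CoverageCurve:
    """Coverage down-sampling curve outcome."""

    coverages: list[float]
    mean_identity: list[float]
    reps: int
    seed: int
    identities: list[list[float]] = field(default_factory=list, repr=False)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "coverage": self.coverages,
            "mean_identity": self.mean_identity,
            "reps": self.reps,
        })

    def manifest(self) -> dict:
        return {"experiment": "coverage_sweep", "coverages": self.coverages,
                "reps": self.reps, "seed": self.seed}


def _rep_seed(base_seed: int, *key: int) -> int:
    """Stable sub-seed below 2**31 derived from a base seed and indices."""
    ss = np.random.SeedSequence(entropy=base_seed, spawn_key=tuple(key))
    return int(ss.generate_state(1, dtype=np.uint64)[0] % (2 ** 31))


def error_tolerance_sweep(payload: bytes, grid, reps: int = 20, seed: int = 0,
                          n_fragments: int = codec.DEFAULT_N_FRAGMENTS,
                          code: LDPCCode | None = None,
                          max_iter: int = 100) -> SweepResult:
    """Sweep the base-substitution rate and count full payload recoveries.

    A replicate succeeds iff the decoded bytes equal the payload exactly
    (CRC-verified by the decoder).  Substitution seeds depend only on
    (seed, replicate, block), not on p, so error positions are nested
    across the grid.
    """
    grid = [float(p) for p in grid]
    if sorted(grid) != grid:
        raise ValueError("grid must be sorted ascending")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    blocks, container = codec.encode_message(payload, n_fragments=n_fragments,
                                             code=code)
    sequences = [b.sequence for b in blocks]
    successes = []
    for p in grid:
        ok = 0
        for rep in range(reps):
            noisy = [substitute_bases(s, p, _rep_seed(seed, rep, bi))
                     for bi, s in enumerate(sequences)]
            try:
                decoded = codec.decode_message(noisy, container,
                                               ChannelSpec(p), max_iter=max_iter)
            except (codec.DecodeError, lzma.LZMAError):
                # a block decoded to a wrong codeword can also surface as a
                # decompression failure; both count as an unrecovered replicate
                decoded = None
            if decoded == payload:
                ok += 1
        successes.append(ok)
    threshold: float | None = None
    for p, s in zip(grid, successes):
        if s == reps:
            threshold = p
        else:
            break
    return SweepResult(grid=grid, successes=successes, reps=reps, seed=seed,
                       threshold=threshold)


def coverage_sweep(reference: str, coverages, reps: int = 20, seed: int = 0,
                   read_len: int = 76, insert_size: int = 200,
                   profile: ErrorProfile = DEFAULT_PROFILE,
                   seed_seq: str | None = None,
                   min_overlap: int = 50, min_depth: int = 1,
                   min_q: int = 32) -> CoverageCurve:
    """Assembly identity as a function of simulated read coverage.

    Per (coverage, replicate): simulate read pairs, quality-trim, extend
    the block's header seed, and score the consensus against the
    reference by global percent identity.  Replicate seeds are shared
    across coverages (paired comparisons).
    """
    coverages = [float(c) for c in coverages]
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if seed_seq is None:
        seed_seq = reference[:codec.HEADER_LEN]
    means = []
    all_ids = []
    for cov in coverages:
        ids = []
        for rep in range(reps):
            spec = ReadSimSpec(coverage=cov, read_len=read_len,
                               insert_size=insert_size,
                               seed=_rep_seed(seed, rep))
            reads = simulate_read_pairs(reference, spec, profile)
            trimmed = [t for t in (quality_trim(r, min_q=min_q) for r in reads)
                       if t is not None]
            index = build_prefix_index(trimmed)
            contig = extend_seed(seed_seq, index, min_overlap=min_overlap,
                                 min_depth=min_depth)
            ids.append(percent_identity(contig.consensus, reference))
        all_ids.append(ids)
        means.append(float(np.mean(ids)))
    return CoverageCurve(coverages=coverages, mean_identity=means, reps=reps,
                         seed=seed, identities=all_ids)


def save_sweep_csv(result: SweepResult, csv_path, manifest_path=None) -> None:
    result.to_dataframe().to_csv(csv_path, index=False)
    if manifest_path is not None:
        with open(manifest_path, "w") as fh:
            json.dump(result.manifest(), fh, indent=2)


def save_curve_csv(curve: CoverageCurve, csv_path, manifest_path=None) -> None:
    curve.to_dataframe().to_csv(csv_path, index=False)
    if manifest_path is not None:
        with open(manifest_path, "w") as fh:
            json.dump(curve.manifest(), fh, indent=2)
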