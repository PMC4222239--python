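"""Regular low-density parity-check (LDPC) codes over GF(2).

An LDPC code is a linear block code defined by a sparse m x n parity-check
matrix H (m = n - k).  A length-n bit vector c is a codeword iff
H @ c = 0 (mod 2).  This module provides

* a seeded Gallager-style construction of regular codes (fixed column
  weight, row weights as even as possible, 4-cycles avoided where the
  geometry allows, rank repaired so a systematic encoder always exists);
* systematic encoding via the reduced row-echelon form of H: information
  bits occupy the non-pivot columns unchanged, parity bits fill the pivot
  columns;
* iterative sum-product (belief-propagation) decoding on the Tanner graph
  of H for a memoryless symmetric channel, with hard-decision input.

The channel is described at the DNA-base level: each base is substituted
independently with probability ``p_base``, the substitute drawn uniformly
from the other three bases.  Under the 2-bits-per-base mapping a
substitution flips each of the base's two bits with probability 2/3, so
the decoder initialises its log-likelihood ratios with the induced
bit-level crossover ``p_bit = (2/3) * p_base``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from itertools import combinations

import numpy as np

__all__ = [
    "ChannelSpec",
    "LDPCCode",
    "build_regular_code",
    "ldpc_encode",
    "ldpc_decode",
    "syndrome",
    "write_alist",
    "read_alist",
]

_ATANH_CLIP = 1.0 - 1e-12


@dataclass(frozen=True)
class ChannelSpec:
    """Memoryless base-substitution channel.

    p_base : probability that a DNA base is substituted (uniform over the
        other three bases).
    p_bit : induced crossover probability per bit, (2/3) * p_base.
    """

    p_base: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_base < 1.0:
            raise ValueError(f"p_base must be in [0, 1), got {self.p_base}")

    @property
    def p_bit(self) -> float:
        return (2.0 / 3.0) * self.p_base


@dataclass(eq=False)
class LDPCCode:
    """A regular LDPC code with a precomputed systematic encoder.

    Attributes
    ----------
    n, k : codeword and information lengths in bits (m = n - k check rows).
    H : (m, n) uint8 parity-check matrix, full row rank.
    col_weight : number of checks per bit column.
    seed : seed used by the construction (reconstruction is deterministic).
    info_cols : the k systematic (non-pivot) column indices; information
        bits appear at these positions of every codeword unchanged.
    """

    n: int
    k: int
    H: np.ndarray
    col_weight: int
    seed: int
    info_cols: np.ndarray = field(repr=False)
    _pivot_cols: np.ndarray = field(repr=False)
    _parity_map: np.ndarray = field(repr=False)  # (m, k): parity = A @ info % 2
    _edge_cache: dict = field(default_factory=dict, repr=False)

    @property
    def m(self) -> int:
        return self.n - self.k

    @property
    def rate(self) -> float:
        return self.k / self.n

    def _edges(self):
        """Edge arrays of the Tanner graph, sorted by check (row-major)."""
        if not self._edge_cache:
            ci, vi = np.nonzero(self.H)
            starts = np.searchsorted(ci, np.arange(self.m))
            self._edge_cache["ci"] = ci
            self._edge_cache["vi"] = vi
            self._edge_cache["starts"] = starts
        c = self._edge_cache
        return c["ci"], c["vi"], c["starts"]


def _gf2_row_reduce(H: np.ndarray):
    """Reduced row echelon form over GF(2).

    Returns (R, pivot_cols, rank, row_order) where row_order tracks the
    original index of each row of R; rows rank..m-1 of R are zero, so
    row_order[rank:] are (a maximal independent choice of) dependent rows.
    """
    R = H.astype(np.uint8).copy()
    m, n = R.shape
    order = np.arange(m)
    pivot_cols = []
    r = 0
    for c in range(n):
        if r == m:
            break
        hits = np.nonzero(R[r:, c])[0]
        if hits.size == 0:
            continue
        p = r + hits[0]
        if p != r:
            R[[r, p]] = R[[p, r]]
            order[[r, p]] = order[[p, r]]
        mask = R[:, c].astype(bool)
        mask[r] = False
        if mask.any():
            R[mask] ^= R[r]
        pivot_cols.append(c)
        r += 1
    return R, np.asarray(pivot_cols, dtype=np.int64), r, order


def _draw_matrix(m: int, n: int, col_weight: int, rng: np.random.Generator) -> np.ndarray:
    """Column-by-column fill: each column gets col_weight rows, preferring
    low-degree rows (even row weights) and avoiding repeated row pairs
    (4-cycles) when the geometry permits."""
    H = np.zeros((m, n), dtype=np.uint8)
    row_deg = np.zeros(m, dtype=np.int64)
    used_pairs: set[frozenset] = set()
    for j in range(n):
        rows: list[int] = []
        for _ in range(col_weight):
            perm = rng.permutation(m)
            cand = perm[np.argsort(row_deg[perm], kind="stable")]
            fallback = -1
            chosen = -1
            for r in cand:
                if r in rows:
                    continue
                if fallback < 0:
                    fallback = int(r)
                if all(frozenset((int(r), s)) not in used_pairs for s in rows):
                    chosen = int(r)
                    break
            rows.append(chosen if chosen >= 0 else fallback)
        for a, b in combinations(rows, 2):
            used_pairs.add(frozenset((a, b)))
        H[rows, j] = 1
        row_deg[rows] += 1
    return H


@lru_cache(maxsize=64)
def build_regular_code(n: int, k: int, col_weight: int = 3, seed: int = 0,
                       max_repair: int = 500) -> LDPCCode:
    """Construct a regular (col_weight, ~row_weight) LDPC code.

    Deterministic given (n, k, col_weight, seed).  If the drawn matrix is
    rank deficient, columns incident to dependent rows are redrawn from
    the same seeded stream until H has full row rank; pathological
    parameter combinations raise after ``max_repair`` attempts.
    Results are memoized; treat the returned code (and its H) as
    read-only.
    """
    if not (n > k > 0):
        raise ValueError(f"need n > k > 0, got n={n}, k={k}")
    m = n - k
    if col_weight < 2:
        raise ValueError("col_weight must be >= 2")
    if col_weight > m:
        raise ValueError("col_weight cannot exceed the number of check rows")
    rng = np.random.default_rng(seed)
    H = _draw_matrix(m, n, col_weight, rng)

    for _ in range(max_repair):
        R, pivots, rank, order = _gf2_row_reduce(H)
        if rank == m:
            break
        bad = int(order[rank])  # an original row dependent on the others
        cols = np.nonzero(H[bad])[0]
        j = int(cols[rng.integers(cols.size)]) if cols.size else int(rng.integers(n))
        H[:, j] = 0
        H[rng.choice(m, size=col_weight, replace=False), j] = 1
    else:
        raise RuntimeError(
            f"could not repair H to full row rank for n={n}, k={k}, "
            f"col_weight={col_weight}, seed={seed}")

    pivot_set = set(int(c) for c in pivots)
    info_cols = np.asarray([c for c in range(n) if c not in pivot_set], dtype=np.int64)
    parity_map = R[:m, :][:, info_cols].astype(np.uint8)
    return LDPCCode(n=n, k=k, H=H, col_weight=col_weight, seed=seed,
                    info_cols=info_cols, _pivot_cols=pivots, _parity_map=parity_map)


def ldpc_encode(info_bits, code: LDPCCode) -> np.ndarray:
    """Systematically encode k information bits into an n-bit codeword.

    The information bits appear unchanged at ``code.info_cols``.
    """
    info = np.asarray(info_bits, dtype=np.uint8).ravel()
    if info.size != code.k:
        raise ValueError(f"expected {code.k} information bits, got {info.size}")
    c = np.zeros(code.n, dtype=np.uint8)
    c[code.info_cols] = info
    c[code._pivot_cols] = (code._parity_map @ info.astype(np.int64)) % 2
    return c


def syndrome(bits, code: LDPCCode) -> np.ndarray:
    """H @ bits mod 2; the all-zero vector iff bits is a codeword."""
    b = np.asarray(bits, dtype=np.uint8).ravel()
    if b.size != code.n:
        raise ValueError(f"expected {code.n} bits, got {b.size}")
    return (code.H @ b.astype(np.int64)) % 2


def ldpc_decode(received_bits, code: LDPCCode, channel: ChannelSpec,
                max_iter: int = 100) -> tuple[np.ndarray, bool]:
    """Sum-product decoding of a hard-decision word.

    Messages are passed on the Tanner graph of H until the hard decision
    satisfies every parity check or ``max_iter`` iterations elapse.
    Returns (info_bits, converged); non-convergence is reported through
    the flag, never raised.
    """
    r = np.asarray(received_bits, dtype=np.uint8).ravel()
    if r.size != code.n:
        raise ValueError(f"expected {code.n} bits, got {r.size}")
    p = channel.p_bit
    if not 0.0 <= p < 0.5:
        raise ValueError(f"decoder requires 0 <= p_bit < 0.5, got {p}")

    if not syndrome(r, code).any():
        return r[code.info_cols].copy(), True
    if p == 0.0:
        # Channel claims no errors but the syndrome is nonzero: nothing to infer.
        return r[code.info_cols].copy(), False

    ci, vi, starts = code._edges()
    llr0 = np.log((1.0 - p) / p)
    Lch = (1.0 - 2.0 * r.astype(np.float64)) * llr0
    Mcv = np.zeros(ci.size, dtype=np.float64)
    hard = r.copy()
    for _ in range(max_iter):
        Ltot = Lch + np.bincount(vi, weights=Mcv, minlength=code.n)
        Mvc = Ltot[vi] - Mcv
        T = np.tanh(0.5 * Mvc)
        T = np.where(np.abs(T) < 1e-12, np.where(T < 0, -1e-12, 1e-12), T)
        T = np.clip(T, -_ATANH_CLIP, _ATANH_CLIP)
        P = np.multiply.reduceat(T, starts)
        Mcv = 2.0 * np.arctanh(np.clip(P[ci] / T, -_ATANH_CLIP, _ATANH_CLIP))
        Ltot = Lch + np.bincount(vi, weights=Mcv, minlength=code.n)
        hard = (Ltot < 0).astype(np.uint8)
        if not syndrome(hard, code).any():
            return hard[code.info_cols].copy(), True
    return hard[code.info_cols].copy(), False


def write_alist(code_or_H, path) -> None:
    """Write a parity-check matrix in the alist sparse text format."""
    H = code_or_H.H if isinstance(code_or_H, LDPCCode) else np.asarray(code_or_H, dtype=np.uint8)
    m, n = H.shape
    col_lists = [np.nonzero(H[:, j])[0] + 1 for j in range(n)]
    row_lists = [np.nonzero(H[i, :])[0] + 1 for i in range(m)]
    col_w = [len(c) for c in col_lists]
    row_w = [len(r) for r in row_lists]
    wmax_c, wmax_r = max(col_w), max(row_w)
    with open(path, "w") as fh:
        fh.write(f"{n} {m}\n{wmax_c} {wmax_r}\n")
        fh.write(" ".join(map(str, col_w)) + "\n")
        fh.write(" ".join(map(str, row_w)) + "\n")
        for lst, wmax in ((col_lists, wmax_c), (row_lists, wmax_r)):
            for entries in lst:
                padded = list(entries) + [0] * (wmax - len(entries))
                fh.write(" ".join(map(str, padded)) + "\n")


def read_alist(path) -> np.ndarray:
    """Read a parity-check matrix from the alist format (returns m x n uint8)."""
    with open(path) as fh:
        tokens = fh.read().split()
    it = iter(tokens)
    n, m = int(next(it)), int(next(it))
    next(it), next(it)  # max weights
    col_w = [int(next(it)) for _ in range(n)]
    [int(next(it)) for _ in range(m)]  # row weights
    H = np.zeros((m, n), dtype=np.uint8)
    wmax_c = max(col_w)
    for j in range(n):
        for _ in range(wmax_c):
            e = int(next(it))
            if e:
                H[e - 1, j] = 1
    return H
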