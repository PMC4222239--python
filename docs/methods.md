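# Methods

This note documents the models implemented by `dnastore`, the parameter
choices that matter, and what the synthetic experiments do and do not
show about real sequencing data.

## Storage layout

A message is LZMA-compressed (classic `.lzma` container, preset 6 —
recorded in the metadata so decoding never depends on library defaults)
and split into `n_fragments = 6` disjoint slices of `k = 640` bits each,
filled in address order.  The unfilled tail is padded with a
deterministic pseudorandom bit stream whose per-fragment length is
recorded in the container and stripped at decode.  Random rather than
zero padding is deliberate: the all-zero information word encodes to the
all-zero codeword, i.e. a 696-base poly-A payload, and a repeat longer
than the read length cannot be reconstructed by any overlap assembler.
Random padding keeps every synthesized block content-bearing regardless
of how small the compressed payload is; since the pad is stripped by
recorded length, its content never affects correctness.

Each slice is encoded by the production LDPC code (below) and mapped to
DNA two bits per base, most-significant bit first within each pair,
bytes traversed most-significant pair first, with digit table A=0, T=1,
C=2, G=3.  A 24-base header precedes the payload: four quaternary digits
of the block address and four of the total block count, each digit
written as three consecutive identical bases.  Distinct addresses
therefore differ in at least 3 of 24 header positions.  Headers are not
LDPC-protected; the decoder recovers them by nearest-match (it can
enumerate every candidate header), implemented as the minimum-total-
Hamming-distance one-to-one assignment of contigs to addresses
(`scipy.optimize.linear_sum_assignment`).  Global assignment is the same
nearest-match rule applied consistently across blocks; it cannot
silently give two contigs one address, and a surplus contig that exactly
duplicates an assigned header raises a distinct duplicate-address error.
Homopolymers are not avoided anywhere: tolerating them (rather than
re-coding around them) is the point of putting the error budget into
forward error correction.

Block geometry closes at exactly 720 bases: 24 header bases plus
`n/2 = 696` payload bases.

## LDPC code

`build_regular_code(n, k, col_weight, seed)` draws a column-weight-3
matrix with row weights as even as possible, avoiding repeated row
pairs (4-cycles) where the geometry permits, and repairs rank
deficiencies by redrawing columns incident to dependent rows from the
same seeded stream.  Construction is deterministic given
`(n, k, col_weight, seed)`, so the container only stores these four
integers.  The reduced row-echelon form of H yields a systematic
encoder: information bits occupy the non-pivot columns unchanged.

The production code is `n = 1392, k = 640, col_weight = 3, seed = 7`
(rate ≈ 0.46).  The rate was chosen, before any measurement, to sit well
below binary-symmetric-channel capacity at the 4% base-substitution
operating point: a substituted base (uniform over the other three)
flips each of its two bits with probability 2/3, so the decoder uses the
induced bit crossover `p_bit = (2/3)·p_base`; at `p_base = 0.04`,
`p_bit ≈ 0.027` and capacity allows rates up to ≈ 0.82.

Decoding is standard sum-product belief propagation on the Tanner graph
with hard-decision channel LLRs `±log((1−p)/p)`, early exit on zero
syndrome, `max_iter = 100`.  Message magnitudes are clipped before
`atanh` (`1 − 1e−12`) and zero tanh values are nudged to `±1e−12`;
these guards only matter in saturated, already-failed decodes.
Non-convergence is reported as a flag (and as a named error at the
message level), never as a crash.  `p_bit = 0` short-circuits to a
syndrome check.  Soft per-base qualities are not used: decoding starts
from an assembled consensus, which has no calibrated qualities.

## Read model

The paired-read simulator emulates the short-read library geometry this
system is designed around: 76-bp mates on 200-bp inserts, fragment
starts uniform over the reference, mate 2 reverse-complemented, with
`ceil(coverage·L/(2·read_len))` pairs.  The default per-base error
profile is 0.19% substitution, 0.01% insertion, 0.38% deletion — the
empirical error spectrum of the sequencing-plus-synthesis channel the
codec targets.  Correct bases carry Q40; substituted and inserted bases
draw Q20–Q39 uniformly, so Q32 trimming has a real signal without
inventing a full platform noise spectrum.  Per position a single
categorical draw selects substitution, insertion, deletion or identity
(rates are tiny, so composite events are negligible).  Deletions carry
no quality signal at all — which is exactly why the assembly layer, not
trimming, has to absorb them.

Deliberately not modelled: coverage bias across blocks (real libraries
can be orders of magnitude uneven; coverage is an explicit parameter
instead), cycle-dependent error ramps, PCR duplicates.  The
substitution channel used for the tolerance sweep draws its per-position
uniforms before thresholding, so with a fixed seed the error sets are
nested in `p` — success curves from one seed are monotone by
construction up to decoder effects.

## Assembly

Greedy seed-extension overlap consensus in the style of SSAKE with
`-m 50` (minimum overlap) and `-w 1` (minimum depth), seeded on the
known 24-base block header.  Reads are trimmed to their longest
all-Q≥32 prefix (3′ trim), discarded below 25 bases or if containing N,
and indexed in both orientations by every prefix of length ≥ 16.
At each step, reads whose prefix matches the contig's 3′ suffix by at
least the effective minimum overlap vote on the next base; the majority
base is appended (ties broken A < C < G < T); then the contig is
reverse-complemented and the other end extended the same way.

Two departures from a naive transcription of the rules, both required
for the algorithm to function:

* **Overlap ramp.**  A 24-base seed can never meet a 50-base overlap
  requirement.  The effective minimum overlap is
  `min(min_overlap, max(16, L − 16))` for contig length L — it starts
  at the 16-base floor (the smallest overlap the implementation ever
  accepts) and reaches the configured 50 once the contig outgrows it.
* **Read retirement.**  A read is retired from the walk once its final
  base has voted.  In non-repetitive sequence this changes nothing (a
  read behind the frontier can never re-anchor); inside a repeat it is
  what makes the walk terminate instead of cycling forever.

Per-position vote tallies and depths are kept on the contig; the seed
region itself counts as depth 1.

The terminal bases of a block deserve a caveat: a read can only cover
the final base if an insert starts exactly flush with the block end, so
under uniformly random fragment placement the last base (occasionally
the last few) is uncovered with non-vanishing probability at any
realistic coverage.  Assemblies are therefore exact up to this terminal
effect; the exactness tests use deterministic tiling reads, which is
also the regime where exact recovery is a well-posed claim.

## Experiments

* **Error-tolerance sweep** — encode the 438-byte fixture, substitute
  every block at rate p, decode, count bit-exact recoveries; the
  threshold is the largest grid rate up to which *every* grid point
  recovered all replicates (success is CRC-verified byte equality, the
  strictest reading of full recovery).  Desk-scale default: 0–8% in
  0.5% steps, 20 replicates — sized so the whole sweep runs in well
  under a minute while bracketing the 4% operating point; the full
  0–20% / 0.1% grid is a parameter choice away
  (`dnastore sweep-error --grid 0:0.20:0.001`).
* **Coverage curve** — simulate pairs from one block at each coverage,
  trim, assemble from the header, score by global percent identity
  (match +1, mismatch −1, gap −2, via Biopython's PairwiseAligner); a
  global rather than local aligner is used so terminal truncation is
  penalised rather than hidden.  Replicate seeds are shared across
  coverages for paired comparisons.

The fixture payload is a deterministic, valid 16-colour BMP of exactly
438 bytes (30 × 20 pixels; at 4 bits per pixel the BMP container is
14 + 40 + 64 + 320 bytes — the only standard pixel format that closes
at that file size).

## Known limitations

* Indels are corrected only by assembly-stage majority voting; the LDPC
  layer models substitutions.  A consensus that does retain an indel
  shifts the downstream bit frame of that block and will generally fail
  its CRC even if BP converges.
* Header recovery degrades gracefully under substitution but headers
  carry no parity; at extreme error rates address assignment, not the
  LDPC layer, can become the binding failure mode.
* The XML container is a clean-room, versioned minimal schema; unknown
  elements are preserved on round trip for forward compatibility, but
  no external schema standard is implemented.
* Synthetic reads are unbiased; conclusions about required coverage
  transfer to real libraries only up to library-preparation bias.
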