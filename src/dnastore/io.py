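"""FASTA and FASTQ readers/writers.

FASTQ is Sanger/Phred+33 by default (Phred+64 via an explicit offset
argument only); the reader is strict and reports the offending line
number on malformed input.  Mate numbers are inferred from ``/1`` and
``/2`` id suffixes.  FASTA goes through Biopython; sequences are
normalised to upper case (with a warning) and wrapped at 70 columns on
write.
"""

from __future__ import annotations

import warnings

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .assembler import SequencingRead

__all__ = ["FastqFormatError", "read_fastq", "write_fastq",
           "read_fasta", "write_fasta"]

_FASTA_WRAP = 70


class FastqFormatError(ValueError):
    def __init__(self, line: int, message: str):
        self.line = line
        super().__init__(f"line {line}: {message}")


def _mate_and_pair(read_id: str) -> tuple[int | None, str]:
    if read_id.endswith("/1"):
        return 1, read_id[:-2]
    if read_id.endswith("/2"):
        return 2, read_id[:-2]
    return None, read_id


def read_fastq(path, offset: int = 33) -> list[SequencingRead]:
    """Parse a FASTQ file into reads; errors name the offending line."""
    with open(path, newline=None) as fh:
        lines = fh.read().splitlines()
    while lines and not lines[-1].strip():
        lines.pop()
    if len(lines) % 4:
        raise FastqFormatError(len(lines) + 1,
                               "truncated record (file length not a multiple of 4 lines)")
    reads = []
    for i in range(0, len(lines), 4):
        head, seq, plus, qual = lines[i:i + 4]
        if not head.startswith("@"):
            raise FastqFormatError(i + 1, f"expected '@' header, got {head[:20]!r}")
        if not plus.startswith("+"):
            raise FastqFormatError(i + 3, f"expected '+' separator, got {plus[:20]!r}")
        if len(seq) != len(qual):
            raise FastqFormatError(
                i + 4, f"quality length {len(qual)} != sequence length {len(seq)}")
        read_id = head[1:].split()[0] if head[1:].split() else ""
        if not read_id:
            raise FastqFormatError(i + 1, "empty read id")
        quals = [ord(c) - offset for c in qual]
        if any(q < 0 for q in quals):
            raise FastqFormatError(i + 4, "quality character below the Phred offset")
        mate, pair_id = _mate_and_pair(read_id)
        reads.append(SequencingRead(id=read_id, bases=seq.upper(), quals=quals,
                                    mate=mate, pair_id=pair_id))
    return reads


def write_fastq(reads, path, offset: int = 33) -> None:
    with open(path, "w") as fh:
        for r in reads:
            qual = "".join(chr(q + offset) for q in r.quals)
            fh.write(f"@{r.id}\n{r.bases}\n+\n{qual}\n")


def read_fasta(path) -> list[tuple[str, str]]:
    """Read (id, sequence) pairs; lowercase input is upcased with a warning."""
    out = []
    for rec in SeqIO.parse(path, "fasta"):
        if not rec.id:
            raise ValueError("FASTA record with empty id")
        seq = str(rec.seq)
        if seq != seq.upper():
            warnings.warn(f"record {rec.id}: lowercase bases normalised to uppercase")
            seq = seq.upper()
        out.append((rec.id, seq))
    return out


def write_fasta(records, path) -> None:
    """Write (id, sequence) pairs wrapped at 70 columns."""
    recs = [SeqRecord(Seq(seq), id=str(name), description="")
            for name, seq in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=_FASTA_WRAP)
        writer.write_file(recs)
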