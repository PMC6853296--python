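"""Readers/writers for the standard formats the pipeline touches.

FASTA/FASTQ parsing is delegated to Biopython's SeqIO; everything here is a
thin shim that normalizes records to ``(id, sequence)`` tuples with
uppercased sequences, plus plain-text writers for SAM/BED/bedGraph exports.
Coordinates are 0-based half-open internally; user-facing TSVs document
their own convention per column.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO

from cpseq._util import ConfigurationError


@dataclass(frozen=True)
class SeqRecordTuple:
    id: str
    seq: str


@dataclass(frozen=True)
class FastqRead:
    id: str
    seq: str
    qual: str

    def __post_init__(self):
        if len(self.seq) != len(self.qual):
            raise ValueError(
                f"read {self.id}: sequence and quality lengths differ "
                f"({len(self.seq)} vs {len(self.qual)})"
            )


def _open_text(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_fasta(path) -> list[SeqRecordTuple]:
    """Read a (possibly gzipped) FASTA file, preserving order, uppercasing."""
    with _open_text(path) as fh:
        return [SeqRecordTuple(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(fh, "fasta")]


def read_fastq(path) -> list[FastqRead]:
    """Read a (possibly gzipped) FASTQ file into records.

    Raises ValueError naming the approximate line on malformed input
    (mismatched sequence/quality lengths, truncated records).
    """
    reads = []
    with _open_text(path) as fh:
        lines = fh.read().splitlines()
    if len(lines) % 4 != 0:
        raise ValueError(f"{path}: truncated FASTQ, {len(lines)} lines is not a multiple of 4")
    for i in range(0, len(lines), 4):
        header, seq, plus, qual = lines[i : i + 4]
        if not header.startswith("@"):
            raise ValueError(f"{path}:{i + 1}: expected '@' header")
        if not plus.startswith("+"):
            raise ValueError(f"{path}:{i + 3}: expected '+' separator")
        if len(seq) != len(qual):
            raise ValueError(
                f"{path}:{i + 2}: sequence length {len(seq)} != quality length {len(qual)}"
            )
        reads.append(FastqRead(header[1:].split()[0], seq.upper(), qual))
    return reads


def write_fasta(path, records: Iterable[SeqRecordTuple | tuple]) -> None:
    with open(path, "w") as fh:
        for rec in records:
            rid, seq = (rec.id, rec.seq) if isinstance(rec, SeqRecordTuple) else rec
            fh.write(f">{rid}\n{seq}\n")


def write_fastq(path, reads: Iterable[FastqRead]) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.id}\n{r.seq}\n+\n{r.qual}\n")


def iter_fastq(path) -> Iterator[FastqRead]:
    yield from read_fastq(path)


# ---------------------------------------------------------------------------
# Alignment exports

SAM_UNMAPPED_FLAG = 4
SAM_REVERSE_FLAG = 16


def write_sam(path, alignments, reads_by_id: dict[str, str], ref_lengths: dict[str, int]) -> None:
    """Write one SAM record per read; the assigned category goes in tag XC."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for rid, length in sorted(ref_lengths.items()):
            fh.write(f"@SQ\tSN:{rid}\tLN:{length}\n")
        for aln in alignments:
            seq = reads_by_id.get(aln.read_id, "*")
            if aln.category == "unmapped":
                fh.write(
                    f"{aln.read_id}\t{SAM_UNMAPPED_FLAG}\t*\t0\t0\t*\t*\t0\t0\t{seq}\t*"
                    f"\tXC:Z:unmapped\n"
                )
                continue
            flag = SAM_REVERSE_FLAG if aln.strand == "-" else 0
            cigar = f"{aln.end - aln.start}M"
            fh.write(
                f"{aln.read_id}\t{flag}\t{aln.ref_id}\t{aln.start + 1}\t255\t{cigar}\t*\t0\t0"
                f"\t{seq}\t*\tXC:Z:{aln.category}\tNM:i:{aln.n_mismatch}\n"
            )


def write_bed6(path, alignments) -> None:
    with open(path, "w") as fh:
        for aln in alignments:
            if aln.category == "unmapped":
                continue
            fh.write(
                f"{aln.ref_id}\t{aln.start}\t{aln.end}\t{aln.read_id}\t{aln.n_mismatch}"
                f"\t{aln.strand}\n"
            )


def write_bedgraph(path, ref_id: str, coverage) -> None:
    """Run-length-encoded bedGraph of a per-position coverage vector."""
    with open(path, "w") as fh:
        start = 0
        for i in range(1, len(coverage) + 1):
            if i == len(coverage) or coverage[i] != coverage[start]:
                if coverage[start] != 0:
                    fh.write(f"{ref_id}\t{start}\t{i}\t{int(coverage[start])}\n")
                start = i


# ---------------------------------------------------------------------------
# In-paper arithmetic


def compute_insert_range(
    product_sizes: tuple[int, int] | list[int], adapter5_bp: int, adapter3_bp: int
) -> list[int]:
    """Insert-size window implied by amplified product sizes and adapter lengths.

    insert = product - (adapter5 + adapter3), elementwise over [min, max].
    """
    lo, hi = product_sizes
    if lo <= 0 or hi <= 0 or adapter5_bp <= 0 or adapter3_bp <= 0:
        raise ConfigurationError("product and adapter sizes must be positive")
    if lo > hi:
        raise ConfigurationError("product size range must be [min, max]")
    total_adapter = adapter5_bp + adapter3_bp
    inserts = [lo - total_adapter, hi - total_adapter]
    if inserts[0] < 0:
        raise ConfigurationError(
            f"adapters ({total_adapter} bp) exceed the smallest product ({lo} bp)"
        )
    return inserts
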