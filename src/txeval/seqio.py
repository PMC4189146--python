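"""Thin FASTA / FASTQ / BLAST-outfmt-6 readers and writers.

Parsing goes through Biopython; the writers emit a fixed, deterministic
layout (60-column FASTA wrapping, four-line FASTQ, 12-column tab-separated
hit tables) so that a read-then-write round trip of a file produced by
these writers is byte-identical.
"""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterable, NamedTuple

from Bio import SeqIO

OUTFMT6_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]

FASTA_WIDTH = 60


class FastqRead(NamedTuple):
    id: str
    seq: str
    qual: str  # Phred+33 ASCII


def _open_text(path, mode="rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path) -> dict[str, str]:
    """Parse a FASTA file into an ``{id: sequence}`` mapping (order kept)."""
    with _open_text(path) as fh:
        return {rec.id: str(rec.seq) for rec in SeqIO.parse(fh, "fasta")}


def write_fasta(path, records: dict[str, str]) -> None:
    with _open_text(path, "wt") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), FASTA_WIDTH):
                fh.write(seq[i:i + FASTA_WIDTH] + "\n")


def read_fastq(path) -> list[FastqRead]:
    """Parse FASTQ (Phred+33) into a list of (id, seq, qual) tuples."""
    out = []
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            quals = rec.letter_annotations["phred_quality"]
            out.append(FastqRead(rec.id, str(rec.seq),
                                 "".join(chr(q + 33) for q in quals)))
    return out


def write_fastq(path, reads: Iterable[FastqRead]) -> None:
    with _open_text(path, "wt") as fh:
        for r in reads:
            fh.write(f"@{r.id}\n{r.seq}\n+\n{r.qual}\n")


def phred_values(qual: str) -> list[int]:
    return [ord(c) - 33 for c in qual]


def write_outfmt6(path, rows: Iterable[tuple]) -> None:
    """Write 12-column BLAST tabular rows.

    Numeric formatting is fixed (pident to 2 dp, evalue as compact
    scientific, bitscore to 1 dp) so output is deterministic.
    """
    with _open_text(path, "wt") as fh:
        for row in rows:
            (q, s, pid, length, mm, go, qs, qe, ss, se, ev, bs) = row
            fh.write(
                f"{q}\t{s}\t{pid:.2f}\t{length}\t{mm}\t{go}\t"
                f"{qs}\t{qe}\t{ss}\t{se}\t{ev:.2e}\t{bs:.1f}\n"
            )


def read_outfmt6_rows(path) -> list[list[str]]:
    """Raw rows of an outfmt-6 file (no typing, no filtering)."""
    rows = []
    with _open_text(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line:
                rows.append(line.split("\t"))
    return rows


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
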