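"""CDS-reconstruction evaluation of contigs against a reference proteome.

Starting from BLAST tabular (outfmt 6) hits of nucleotide contigs against
a protein database, each (contig, protein) pair gets a *subject coverage*:
the fraction of the protein's length covered by the union of the pair's
aligned subject intervals.  A protein (distinct CDS) counts as
reconstructed at a level L (99/90/80/50% by default) when some contig
covers >= L of its length; a gene counts when at least one of its isoform
proteins does; a contig counts when it achieves >= L on some protein.
Totals count everything with any significant hit, regardless of coverage.
Per-gene summaries keep only the best-covered isoform.

Subject intervals are stored 0-based half-open; outfmt-6 coordinates
(1-based inclusive) are converted on parse.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

DEFAULT_EVALUE = 1e-10
DEFAULT_LEVELS = (0.99, 0.90, 0.80, 0.50)


@dataclass
class ProteinDB:
    """Reference proteins (lengths in amino acids) and their gene grouping.

    The protein -> gene map plays the role of an orthology resource's
    isoform table (e.g. an oma-ensembl style two-column file): it lets
    hits to distinct protein isoforms be aggregated to one gene.
    """

    lengths: dict[str, int]
    gene_of: dict[str, str]

    def __post_init__(self):
        for pid, n in self.lengths.items():
            if n < 1:
                raise ValueError(f"protein {pid} has non-positive length")
        missing = set(self.lengths) - set(self.gene_of)
        if missing:
            raise ValueError(f"proteins missing from gene map: {sorted(missing)[:5]}")

    @property
    def n_proteins(self) -> int:
        return len(self.lengths)

    @property
    def isoforms_of(self) -> dict[str, set[str]]:
        iso: dict[str, set[str]] = {}
        for pid, gid in self.gene_of.items():
            iso.setdefault(gid, set()).add(pid)
        return iso

    @classmethod
    def from_files(cls, protein_fasta, gene_map_tsv) -> "ProteinDB":
        from .seqio import read_fasta
        seqs = read_fasta(protein_fasta)
        gene_of = {}
        with open(gene_map_tsv) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                pid, gid = line.split("\t")[:2]
                gene_of[pid] = gid
        return cls({pid: len(s) for pid, s in seqs.items()},
                   {pid: gene_of[pid] for pid in seqs})


@dataclass(frozen=True)
class HitRecord:
    query: str
    subject: str
    pident: float
    evalue: float
    sstart: int  # 0-based
    send: int    # half-open
    library: str | None = None

    @property
    def interval(self) -> tuple[int, int]:
        return (self.sstart, self.send)


def parse_blast_table(path, evalue: float = DEFAULT_EVALUE,
                      library: str | None = None) -> list[HitRecord]:
    """Parse outfmt-6 rows, keeping hits with evalue strictly below the
    threshold and converting subject coordinates to 0-based half-open.

    Rows with sstart > send are rejected: protein subjects of a
    BLASTX-style search have no minus strand.
    """
    hits: list[HitRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise ValueError(
                    f"{path}:{lineno}: expected 12 tab-separated columns, "
                    f"got {len(fields)}")
            try:
                pident = float(fields[2])
                sstart = int(fields[8])
                send = int(fields[9])
                ev = float(fields[10])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: unparsable numeric "
                                 f"field ({exc})") from None
            if sstart > send:
                raise ValueError(
                    f"{path}:{lineno}: sstart {sstart} > send {send} is "
                    "malformed for a protein subject")
            if ev >= evalue:
                continue
            hits.append(HitRecord(fields[0], fields[1], pident, ev,
                                  sstart - 1, send, library))
    return hits


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of half-open intervals as a sorted disjoint list."""
    ivs = sorted(intervals)
    merged: list[list[int]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def subject_coverage(hits: Sequence[HitRecord], db: ProteinDB) -> float:
    """Coverage of one protein by one contig: merged interval length over
    protein length.  All hits must share query and subject."""
    subjects = {h.subject for h in hits}
    queries = {h.query for h in hits}
    if len(subjects) != 1 or len(queries) != 1:
        raise ValueError("hits must share one (query, subject) pair")
    subject = subjects.pop()
    if subject not in db.lengths:
        raise KeyError(f"subject {subject!r} absent from protein database")
    covered = sum(e - s for s, e in merge_intervals(h.interval for h in hits))
    return covered / db.lengths[subject]


def coverage_table(hits: Iterable[HitRecord], db: ProteinDB
                   ) -> dict[tuple[str, str], float]:
    """Per (query, subject) coverage fractions for a full hit list."""
    grouped: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for h in hits:
        if h.subject not in db.lengths:
            raise KeyError(f"subject {h.subject!r} absent from protein database")
        grouped.setdefault((h.query, h.subject), []).append(h.interval)
    return {
        key: sum(e - s for s, e in merge_intervals(ivs)) / db.lengths[key[1]]
        for key, ivs in grouped.items()
    }


@dataclass
class ReconstructionReport:
    """Per-level counts of genes, distinct CDS and contigs, plus totals
    over everything with a significant hit."""

    levels: tuple
    n_genes: dict[float, int]
    n_cds: dict[float, int]
    n_contigs: dict[float, int]
    total_genes: int
    total_cds: int
    total_contigs: int

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"level": lvl, "genes": self.n_genes[lvl], "cds": self.n_cds[lvl],
             "contigs": self.n_contigs[lvl]}
            for lvl in self.levels
        ]
        rows.append({"level": "total", "genes": self.total_genes,
                     "cds": self.total_cds, "contigs": self.total_contigs})
        return pd.DataFrame(rows)

    def level_tallies(self) -> dict[float, tuple[int, int, int]]:
        return {lvl: (self.n_genes[lvl], self.n_cds[lvl], self.n_contigs[lvl])
                for lvl in self.levels}


def reconstruction_report(hits: Iterable[HitRecord], db: ProteinDB,
                          levels: Sequence[float] = DEFAULT_LEVELS,
                          ) -> tuple[ReconstructionReport,
                                     dict[tuple[str, str], float],
                                     dict[str, float]]:
    """Classify coverage fractions at reconstruction levels.

    Thresholds are applied as coverage >= level, so an exactly
    full-length reconstruction and an exact boundary value both count.
    Returns the report, the (query, subject) coverage table and the
    per-gene best coverage over all isoforms and contigs.
    """
    levels = tuple(sorted(levels, reverse=True))
    table = coverage_table(hits, db)

    gene_best: dict[str, float] = {}
    cds_best: dict[str, float] = {}
    contig_best: dict[str, float] = {}
    for (query, subject), frac in table.items():
        gene = db.gene_of[subject]
        gene_best[gene] = max(gene_best.get(gene, 0.0), frac)
        cds_best[subject] = max(cds_best.get(subject, 0.0), frac)
        contig_best[query] = max(contig_best.get(query, 0.0), frac)

    n_genes, n_cds, n_contigs = {}, {}, {}
    for lvl in levels:
        n_genes[lvl] = sum(1 for v in gene_best.values() if v >= lvl)
        n_cds[lvl] = sum(1 for v in cds_best.values() if v >= lvl)
        n_contigs[lvl] = sum(1 for v in contig_best.values() if v >= lvl)

    report = ReconstructionReport(
        levels, n_genes, n_cds, n_contigs,
        total_genes=len(gene_best), total_cds=len(cds_best),
        total_contigs=len(contig_best),
    )
    return report, table, gene_best


def union_reports(per_library_hits: Mapping[str, Iterable[HitRecord]],
                  db: ProteinDB, levels: Sequence[float] = DEFAULT_LEVELS,
                  ) -> tuple[ReconstructionReport,
                             dict[tuple[str, str], float],
                             dict[str, float]]:
    """Pool hits of several libraries into one report.

    Query ids are namespaced as ``<library>:<contig>`` before merging,
    since assembler contig ids restart per library; per-gene best
    coverage is then the max over libraries.
    """
    tags = list(per_library_hits)
    if len(tags) != len(set(tags)):
        raise ValueError("duplicate library tags")
    if not tags:
        raise ValueError("at least one library is required")
    merged: list[HitRecord] = []
    for tag, hits in per_library_hits.items():
        for h in hits:
            merged.append(HitRecord(f"{tag}:{h.query}", h.subject, h.pident,
                                    h.evalue, h.sstart, h.send, tag))
    return reconstruction_report(merged, db, levels)


def coverage_histogram(gene_best: Mapping[str, float],
                       bin_width: float = 0.01) -> pd.DataFrame:
    """Frequencies of genes per best-coverage bin.

    Bins are half-open [lo, lo+w) except the terminal bin, which is
    closed at 1.0 so fully reconstructed genes are counted once.
    """
    if not (0 < bin_width <= 1):
        raise ValueError("bin width must lie in (0, 1]")
    n_bins = int(np.ceil(1.0 / bin_width))
    edges = np.minimum(np.arange(n_bins + 1) * bin_width, 1.0)
    values = np.fromiter(gene_best.values(), dtype=float)
    counts, _ = np.histogram(values, bins=edges)  # last bin closed at 1.0
    total = len(values)
    freqs = counts / total if total else np.zeros_like(counts, dtype=float)
    return pd.DataFrame({
        "bin_low": edges[:-1], "bin_high": edges[1:],
        "n_genes": counts, "frequency": freqs,
    })
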