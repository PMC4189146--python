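"""Synthetic inputs with planted ground truth.

Every downstream stage of the toolkit can be exercised without external
downloads: this module fabricates a multi-isoform reference proteome with
a protein-to-gene map, contig sets that reconstruct known fractions of
known CDSs, BLAST outfmt-6 hit tables consistent with those contigs,
paired reads with controlled per-transcript depth and error rate, and a
panel of expression libraries sharing a planted highly expressed core.

The planted truth is exact: each contig's subject-coverage fraction is an
integer amino-acid count over the protein length, chosen strictly inside
the requested reconstruction band, so the homology evaluation must
recover the plan's level tallies without tolerance.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .normalize import revcomp
from .seqio import FastqRead, ensure_dir, write_fasta, write_fastq, write_outfmt6

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
# one fixed sense codon per amino acid: CDS length is exactly 3x protein length
_CODON_OF = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT",
    "G": "GGT", "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTT",
    "M": "ATG", "N": "AAT", "P": "CCT", "Q": "CAA", "R": "CGT",
    "S": "TCT", "T": "ACT", "V": "GTT", "W": "TGG", "Y": "TAT",
}

DEFAULT_LEVELS = (0.99, 0.90, 0.80, 0.50)
SUB_LEVEL_KEY = "sub"
# sub-threshold contigs land below the lowest reporting level
SUB_BAND = (0.10, 0.50)
DEFAULT_READ_LENGTH = 101
DEFAULT_N_LIBRARIES = 13
DEFAULT_CORE_MULTIPLIER = 10.0
DEFAULT_BASELINE_MEAN = 100.0


def _draw_ints(spec, rng: np.random.Generator, size: int) -> np.ndarray:
    """Integer distribution spec: a fixed int or an inclusive (lo, hi)
    range sampled uniformly."""
    if isinstance(spec, (int, np.integer)):
        if spec < 1:
            raise ValueError(f"distribution spec must be positive, got {spec}")
        return np.full(size, int(spec))
    lo, hi = spec
    if lo < 1 or hi < lo:
        raise ValueError(f"degenerate integer range ({lo}, {hi})")
    return rng.integers(lo, hi + 1, size=size)


@dataclass
class ReferenceSet:
    """Fabricated reference proteome: genes, their isoform proteins, the
    coding transcripts, and the protein -> gene map."""

    genes: list[str]
    isoforms: dict[str, list[tuple[str, str]]]  # gene -> [(protein id, aa seq)]
    transcripts: dict[str, str]                 # protein id -> CDS (nt)
    gene_map: list[tuple[str, str]]             # (protein id, gene id)

    @property
    def proteins(self) -> dict[str, str]:
        return {pid: seq for iso in self.isoforms.values() for pid, seq in iso}

    @property
    def protein_lengths(self) -> dict[str, int]:
        return {pid: len(seq) for pid, seq in self.proteins.items()}

    @property
    def gene_of(self) -> dict[str, str]:
        return {pid: gid for pid, gid in self.gene_map}

    def write(self, outdir) -> dict[str, Path]:
        out = ensure_dir(outdir)
        paths = {
            "proteins": out / "proteins.faa",
            "transcripts": out / "transcripts.fna",
            "gene_map": out / "gene_map.tsv",
        }
        write_fasta(paths["proteins"], self.proteins)
        write_fasta(paths["transcripts"], self.transcripts)
        with open(paths["gene_map"], "w") as fh:
            for pid, gid in self.gene_map:
                fh.write(f"{pid}\t{gid}\n")
        return paths


@dataclass
class PlantedTruth:
    """Ground truth planted by the generators.

    contig_provenance maps each emitted contig id to its source protein,
    the covered subject interval (0-based half-open, protein coordinates)
    and the exact coverage fraction.  level_of_gene records which
    reconstruction band each planned gene was planted in.
    """

    contig_provenance: dict[str, tuple[str, tuple[int, int], float]] = field(
        default_factory=dict)
    core_genes: set[str] = field(default_factory=set)
    depth_profile: dict[str, float] = field(default_factory=dict)
    level_of_gene: dict[str, object] = field(default_factory=dict)

    def validate(self, ref: ReferenceSet) -> None:
        lengths = ref.protein_lengths
        for cid, (pid, (s, e), frac) in self.contig_provenance.items():
            L = lengths[pid]
            assert 0 <= s < e <= L, f"{cid}: interval outside protein"
            assert abs(frac - (e - s) / L) < 1e-12, f"{cid}: fraction mismatch"
        assert self.core_genes <= set(ref.genes)


def generate_reference(n_genes: int, isoforms_per_gene=2,
                       protein_length=(100, 300), seed: int = 0,
                       outdir=None) -> ReferenceSet:
    """Fabricate a reference proteome with a protein-to-gene map.

    isoforms_per_gene and protein_length accept a fixed int or an
    inclusive (lo, hi) range.  Deterministic for a fixed seed; when
    outdir is given, writes protein FASTA, transcript FASTA and the
    two-column gene-map TSV.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    rng = np.random.default_rng(seed)
    n_iso = _draw_ints(isoforms_per_gene, rng, n_genes)
    genes = [f"GENE{g:05d}" for g in range(1, n_genes + 1)]
    isoforms: dict[str, list[tuple[str, str]]] = {}
    transcripts: dict[str, str] = {}
    gene_map: list[tuple[str, str]] = []
    aa = np.array(list(AMINO_ACIDS))
    for gid, k in zip(genes, n_iso):
        iso_list = []
        lengths = _draw_ints(protein_length, rng, int(k))
        for j, L in enumerate(lengths, 1):
            pid = f"{gid}.P{j}"
            seq = "".join(rng.choice(aa, size=int(L)))
            iso_list.append((pid, seq))
            transcripts[pid] = "".join(_CODON_OF[c] for c in seq)
            gene_map.append((pid, gid))
        isoforms[gid] = iso_list
    ref = ReferenceSet(genes, isoforms, transcripts, gene_map)
    if outdir is not None:
        ref.write(outdir)
    return ref


def _band_for_level(level, levels: Sequence[float]) -> tuple[float, float, bool]:
    """Coverage band [lo, hi) for a reporting level; the top band is
    closed at 1.0 so full-length reconstructions stay countable."""
    if level == SUB_LEVEL_KEY:
        return SUB_BAND[0], SUB_BAND[1], False
    ordered = sorted(levels, reverse=True)
    i = ordered.index(level)
    if i == 0:
        return level, 1.0, True
    return level, ordered[i - 1], False


def _pick_covered_length(L: int, lo: float, hi: float, closed_top: bool,
                         rng: np.random.Generator) -> int:
    """Integer covered length c with c/L strictly inside the band."""
    c_min = math.ceil(lo * L)
    if closed_top:
        c_max = L
    else:
        c_max = math.ceil(hi * L) - 1
    if c_min > c_max or c_min < 1:
        raise ValueError(
            f"protein of length {L} admits no integer coverage in "
            f"[{lo}, {hi}{']' if closed_top else ')'}")
    return int(rng.integers(c_min, c_max + 1))


def expected_level_tallies(plan: Mapping, levels: Sequence[float] = DEFAULT_LEVELS
                           ) -> dict[float, tuple[int, int, int]]:
    """Cumulative (genes, cds, contigs) tallies a reconstruction report
    must show for a completeness plan (one contig and one isoform per
    planned gene, no fragmentation, no spurious hits)."""
    planned = [l for l in plan if l != SUB_LEVEL_KEY]
    tallies = {}
    for lvl in sorted(levels, reverse=True):
        n = sum(plan[l] for l in planned if l >= lvl)
        tallies[lvl] = (n, n, n)
    return tallies


def generate_contigs(ref: ReferenceSet, completeness_plan: Mapping,
                     fragmentation: float = 0.0, seed: int = 0,
                     outpath=None) -> tuple[dict[str, str], PlantedTruth]:
    """Plant contigs that reconstruct known fractions of known CDSs.

    completeness_plan maps reconstruction levels (0.99, 0.90, 0.80, 0.50)
    and the key 'sub' to gene counts.  Each planned gene receives exactly
    one contig whose coverage fraction lies strictly inside the level's
    band (half-open below the next level up; the 0.99 band is closed at
    1.0; 'sub' lands in [0.10, 0.50)).  With probability ``fragmentation``
    a planned contig is emitted as two pieces whose subject intervals
    partition the planted interval.
    """
    n_planned = sum(completeness_plan.values())
    if n_planned > len(ref.genes):
        raise ValueError(
            f"plan covers {n_planned} genes but the reference has only "
            f"{len(ref.genes)}")
    if not (0 <= fragmentation <= 1):
        raise ValueError("fragmentation must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    gene_order = list(ref.genes)
    rng.shuffle(gene_order)
    truth = PlantedTruth()
    contigs: dict[str, str] = {}
    comp = 0
    cursor = 0
    for level, count in completeness_plan.items():
        lo, hi, closed = _band_for_level(level, DEFAULT_LEVELS)
        for _ in range(count):
            gid = gene_order[cursor]
            cursor += 1
            iso = ref.isoforms[gid]
            pid, pseq = iso[int(rng.integers(len(iso)))]
            L = len(pseq)
            c = _pick_covered_length(L, lo, hi, closed, rng)
            s = int(rng.integers(0, L - c + 1))
            e = s + c
            comp += 1
            cds = ref.transcripts[pid]
            truth.level_of_gene[gid] = level
            if fragmentation > 0 and c >= 2 and rng.random() < fragmentation:
                t = int(rng.integers(s + 1, e))
                for piece_no, (ps, pe) in enumerate(((s, t), (t, e)), 1):
                    cid = f"comp{comp}_c0_seq{piece_no}"
                    contigs[cid] = cds[3 * ps:3 * pe]
                    truth.contig_provenance[cid] = (pid, (ps, pe), (pe - ps) / L)
            else:
                cid = f"comp{comp}_c0_seq1"
                contigs[cid] = cds[3 * s:3 * e]
                truth.contig_provenance[cid] = (pid, (s, e), c / L)
    truth.validate(ref)
    if outpath is not None:
        write_fasta(outpath, contigs)
    return contigs, truth


def default_evalue_model(alignment_length_aa: int) -> float:
    """Monotone decreasing e-value, floored at 1e-180.

    Only the ordering relative to a significance cutoff matters; the
    model guarantees that any alignment of >= 3 aa clears 1e-10.
    """
    return 10.0 ** (-min(180.0, 8.0 + float(alignment_length_aa)))


def generate_alignments(truth: PlantedTruth, ref: ReferenceSet,
                        evalue_model=default_evalue_model,
                        spurious_rate: float = 0.0, seed: int = 0,
                        outpath=None) -> tuple[list[tuple], list[tuple]]:
    """Emit outfmt-6 rows consistent with the planted contigs.

    One row per (contig piece, source protein) with subject coordinates
    equal to the planted interval (written 1-based inclusive).  With
    probability ``spurious_rate`` per contig a random short hit to a
    different protein is added, always with subject coverage < 0.50 so it
    can only perturb the report's total rows; spurious rows are returned
    separately (and written to a ``.spurious.tsv`` side-channel file).
    """
    rng = np.random.default_rng(seed)
    lengths = ref.protein_lengths
    pids = sorted(lengths)
    rows: list[tuple] = []
    spurious: list[tuple] = []
    for cid, (pid, (s, e), _frac) in truth.contig_provenance.items():
        alen = e - s
        rows.append((cid, pid, float(rng.uniform(95.0, 100.0)), alen, 0, 0,
                     1, 3 * alen, s + 1, e, evalue_model(alen), 2.0 * alen))
        if spurious_rate > 0 and rng.random() < spurious_rate:
            other = pids[int(rng.integers(len(pids)))]
            if other == pid:
                continue
            L = lengths[other]
            hi = int(0.45 * L)
            if hi < 10:
                continue
            alen_s = int(rng.integers(10, hi + 1))
            ss = int(rng.integers(0, L - alen_s + 1))
            row = (cid, other, float(rng.uniform(90.0, 97.0)), alen_s, 2, 0,
                   1, 3 * alen_s, ss + 1, ss + alen_s,
                   evalue_model(alen_s), 1.5 * alen_s)
            rows.append(row)
            spurious.append(row)
    if outpath is not None:
        write_outfmt6(outpath, rows)
        side = Path(str(outpath) + ".spurious.tsv")
        write_outfmt6(side, spurious)
    return rows, spurious


def generate_reads(ref: ReferenceSet, truth: PlantedTruth,
                   read_length: int = DEFAULT_READ_LENGTH,
                   error_rate: float = 0.0, seed: int = 0,
                   out1=None, out2=None) -> tuple[list[FastqRead], list[FastqRead]]:
    """Simulate paired-end reads at the depths in truth.depth_profile.

    Fragments are drawn uniformly along each transcript; mate 1 is the
    fragment's 5' read, mate 2 the reverse complement of its 3' end.
    Substitution errors occur independently per base at ``error_rate``;
    qualities are a constant Phred 40.  Transcripts shorter than the read
    length are skipped with a warning.  Mate ids share a stem.
    """
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    reads1: list[FastqRead] = []
    reads2: list[FastqRead] = []
    qual = chr(40 + 33) * read_length
    for tid in sorted(truth.depth_profile):
        depth = truth.depth_profile[tid]
        tseq = ref.transcripts[tid]
        tlen = len(tseq)
        if tlen < read_length:
            warnings.warn(f"transcript {tid} ({tlen} bp) shorter than the "
                          f"read length {read_length}; skipped")
            continue
        frag = min(tlen, 2 * read_length + 50)
        n_pairs = int(round(depth * tlen / (2 * read_length)))
        starts = rng.integers(0, tlen - frag + 1, size=n_pairs)
        for i, st in enumerate(starts):
            r1 = tseq[st:st + read_length]
            r2 = revcomp(tseq[st + frag - read_length:st + frag])
            if error_rate > 0:
                r1 = _mutate(r1, error_rate, rng, bases)
                r2 = _mutate(r2, error_rate, rng, bases)
            stem = f"{tid}_frag{i}"
            reads1.append(FastqRead(f"{stem}/1", r1, qual))
            reads2.append(FastqRead(f"{stem}/2", r2, qual))
    if out1 is not None:
        write_fastq(out1, reads1)
    if out2 is not None:
        write_fastq(out2, reads2)
    return reads1, reads2


def _mutate(seq: str, rate: float, rng: np.random.Generator,
            bases: np.ndarray) -> str:
    arr = np.array(list(seq))
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hits:
        choices = bases[bases != arr[i]]
        arr[i] = choices[int(rng.integers(3))]
    return "".join(arr)


def gene_effective_lengths(ref: ReferenceSet) -> pd.Series:
    """Effective length per gene: the longest isoform CDS in bp."""
    lens = {gid: max(3 * len(seq) for _, seq in iso)
            for gid, iso in ref.isoforms.items()}
    return pd.Series(lens, name="eff_length").sort_index()


def generate_expression(ref: ReferenceSet, n_libraries: int = DEFAULT_N_LIBRARIES,
                        core_genes: Iterable[str] = (),
                        core_multiplier: float = DEFAULT_CORE_MULTIPLIER,
                        dispersion: float = 0.1, seed: int = 0,
                        baseline_mean: float = DEFAULT_BASELINE_MEAN,
                        outdir=None) -> tuple[pd.DataFrame, pd.Series]:
    """Simulate per-library gene counts with a planted high-expression core.

    Counts follow a negative-binomial-style (gamma-Poisson) model.  As in
    real RNA-seq, a gene's expected count is proportional to its
    expression rate times its effective length; all genes share one
    baseline rate and core genes get ``core_multiplier`` times that rate
    in every library, so the planted core dominates on both the count and
    the length-normalized (TPM) scale.  ``baseline_mean`` is the expected
    count of a non-core gene of average effective length.  dispersion is
    the NB overdispersion (var = mu + dispersion * mu^2); dispersion=0
    degenerates to Poisson.  Returns a genes x libraries count table and
    the per-gene effective lengths; when outdir is given, writes one
    count TSV per library plus the effective-length TSV.
    """
    core = set(core_genes)
    if not core <= set(ref.genes):
        raise ValueError("core genes must be a subset of the reference genes")
    if n_libraries < 1:
        raise ValueError("n_libraries must be >= 1")
    if not core and core_multiplier != 1:
        warnings.warn("empty core with core_multiplier != 1 has no effect")
    rng = np.random.default_rng(seed)
    genes = sorted(ref.genes)
    eff = gene_effective_lengths(ref)
    lengths = eff.loc[genes].to_numpy(dtype=float)
    mu = baseline_mean * lengths / lengths.mean()
    mu[[i for i, g in enumerate(genes) if g in core]] *= core_multiplier
    libs = [f"lib{j:02d}" for j in range(1, n_libraries + 1)]
    counts = np.empty((len(genes), n_libraries), dtype=np.int64)
    for j in range(n_libraries):
        if dispersion > 0:
            lam = rng.gamma(shape=1.0 / dispersion, scale=mu * dispersion)
        else:
            lam = mu
        counts[:, j] = rng.poisson(lam)
    table = pd.DataFrame(counts, index=genes, columns=libs)
    if outdir is not None:
        out = ensure_dir(outdir)
        for lib in libs:
            table[[lib]].rename(columns={lib: "count"}).to_csv(
                out / f"{lib}.counts.tsv", sep="\t", index_label="gene")
        eff.to_frame().to_csv(out / "eff_lengths.tsv", sep="\t",
                              index_label="gene")
    return table, eff
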