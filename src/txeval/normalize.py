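"""3' quality trimming and digital normalization by median k-mer abundance.

Digital normalization is a streaming, reference-free read-discarding
algorithm: for each read (or read pair) the median abundance of its
canonical k-mers is computed against the counts accumulated from reads
*kept so far*; if the median is below a coverage cutoff ``C`` the unit is
kept and its k-mers are counted, otherwise it is discarded without
touching the counter.  Counting only kept reads is what gives the exact
duplicate law (``D`` copies of one read with cutoff ``C < D`` retain
exactly ``C`` copies).

A second pass, :func:`filter_low_abundance`, trims each retained read to
its longest prefix whose k-mers all reach a trusted-count floor, removing
likely erroneous k-mers at read 3' ends.
"""

from __future__ import annotations

import random as _random
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

from .seqio import FastqRead, phred_values, read_fastq, write_fastq

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

DEFAULT_K = 25
DEFAULT_COVERAGE_CUTOFF = 30
DEFAULT_QUALITY_CUTOFF = 24
DEFAULT_ABUND_CUTOFF = 2
DEFAULT_MIN_READ_LENGTH = 25


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def canonical(kmer: str) -> str:
    """Strand-collapsed form: lexicographic min of a k-mer and its
    reverse complement."""
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


class KmerCounter:
    """Exact counts of canonical k-mers.

    An exact dict-backed mapping; any structure honouring
    ``get``/``add_sequence`` with the same canonicalization (e.g. a
    count-min sketch) can be dropped in for scale.
    """

    def __init__(self, k: int = DEFAULT_K):
        if k < 1:
            raise ValueError(f"k must be >= 1, got {k}")
        self.k = k
        self.counts: dict[str, int] = {}

    def get(self, kmer: str) -> int:
        return self.counts.get(canonical(kmer), 0)

    def add_sequence(self, seq: str) -> None:
        k = self.k
        counts = self.counts
        for i in range(len(seq) - k + 1):
            key = canonical(seq[i:i + k])
            counts[key] = counts.get(key, 0) + 1

    def sequence_counts(self, seq: str) -> list[int]:
        k = self.k
        return [self.get(seq[i:i + k]) for i in range(len(seq) - k + 1)]


@dataclass
class NormalizationParams:
    """Knobs of the normalization pass.

    k
        k-mer size in bp.
    coverage_cutoff
        ``C``: a unit is kept while its median k-mer abundance is < C.
    quality_cutoff
        ``Q``: 3' bases with Phred quality < Q are trimmed beforehand.
    abund_cutoff
        minimum trusted k-mer count for the low-abundance filter pass.
    paired_policy
        'keep-if-either' (default: a pair is kept if either mate's median
        is below C), 'keep-if-both', or 'unpaired'.
    min_read_length
        reads shorter than this after trimming are dropped.
    """

    k: int = DEFAULT_K
    coverage_cutoff: float = DEFAULT_COVERAGE_CUTOFF
    quality_cutoff: int = DEFAULT_QUALITY_CUTOFF
    abund_cutoff: int = DEFAULT_ABUND_CUTOFF
    paired_policy: str = "keep-if-either"
    min_read_length: int = DEFAULT_MIN_READ_LENGTH

    def __post_init__(self):
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.coverage_cutoff < 1:
            raise ValueError("coverage cutoff must be >= 1")
        if not (0 <= self.quality_cutoff <= 41):
            raise ValueError("quality cutoff must lie in [0, 41]")
        if self.paired_policy not in ("keep-if-either", "keep-if-both", "unpaired"):
            raise ValueError(f"unknown paired policy {self.paired_policy!r}")


@dataclass
class NormalizationLog:
    reads_in: int = 0
    reads_kept: int = 0
    reads_discarded: int = 0
    reads_skipped_short: int = 0

    @property
    def retention_fraction(self) -> float:
        return self.reads_kept / self.reads_in if self.reads_in else 0.0

    def check(self) -> None:
        assert self.reads_in == (self.reads_kept + self.reads_discarded
                                 + self.reads_skipped_short)


class Decision(NamedTuple):
    """One entry of the decision log: the unit id, the median abundance
    it was judged on, and whether it was kept."""
    unit_id: str
    median: int
    kept: bool


def trim_quality_3prime(read: FastqRead, quality_cutoff: int = DEFAULT_QUALITY_CUTOFF
                        ) -> FastqRead:
    """Remove the maximal 3' suffix in which every base has quality below
    the cutoff; the 5' end is never altered."""
    if len(read.seq) != len(read.qual):
        raise ValueError(
            f"read {read.id}: sequence length {len(read.seq)} != "
            f"quality length {len(read.qual)}")
    quals = phred_values(read.qual)
    end = len(quals)
    while end > 0 and quals[end - 1] < quality_cutoff:
        end -= 1
    return FastqRead(read.id, read.seq[:end], read.qual[:end])


def kmer_median_abundance(seq: str, counter: KmerCounter) -> int:
    """Median of the read's canonical k-mer counts.

    The median of the m counts is the element at index floor(m/2) of the
    ascending sort (the upper-middle value when m is even), so it is
    always an observed integer count.
    """
    if len(seq) < counter.k:
        raise ValueError(
            f"sequence length {len(seq)} shorter than k={counter.k}; "
            "median abundance is undefined")
    counts = sorted(counter.sequence_counts(seq))
    return counts[len(counts) // 2]


def _unit_median(reads: Sequence[FastqRead], counter: KmerCounter,
                 policy: str) -> int:
    meds = [kmer_median_abundance(r.seq, counter) for r in reads]
    if policy == "keep-if-both":
        # keep only if both mates look under-covered
        return max(meds)
    return min(meds)


def normalize_stream(units: Iterable[Sequence[FastqRead]],
                     params: NormalizationParams,
                     counter: KmerCounter | None = None,
                     ) -> tuple[list[tuple[FastqRead, ...]], NormalizationLog,
                                list[Decision]]:
    """Single-pass digital normalization over read units.

    ``units`` is an iterable of read tuples: 1-tuples for single-end
    data, 2-tuples for pairs.  With paired_policy='unpaired' mates are
    judged independently; otherwise the pair is kept or discarded as a
    whole.  Counts are incremented only for kept reads.

    Returns the kept units, a :class:`NormalizationLog`, and the decision
    log (one entry per judged unit, recording the median it saw).
    """
    if counter is None:
        counter = KmerCounter(params.k)
    elif counter.k != params.k:
        raise ValueError("counter k does not match params k")
    C = params.coverage_cutoff
    min_len = max(params.k, params.min_read_length)
    log = NormalizationLog()
    decisions: list[Decision] = []
    kept_units: list[tuple[FastqRead, ...]] = []

    for unit in units:
        log.reads_in += len(unit)
        usable = [r for r in unit if len(r.seq) >= min_len]
        log.reads_skipped_short += len(unit) - len(usable)
        if not usable:
            continue
        if params.paired_policy == "unpaired":
            for r in usable:
                med = kmer_median_abundance(r.seq, counter)
                keep = med < C
                decisions.append(Decision(r.id, med, keep))
                if keep:
                    counter.add_sequence(r.seq)
                    kept_units.append((r,))
                    log.reads_kept += 1
                else:
                    log.reads_discarded += 1
        else:
            med = _unit_median(usable, counter, params.paired_policy)
            keep = med < C
            decisions.append(Decision(usable[0].id, med, keep))
            if keep:
                for r in usable:
                    counter.add_sequence(r.seq)
                kept_units.append(tuple(usable))
                log.reads_kept += len(usable)
            else:
                log.reads_discarded += len(usable)
    log.check()
    return kept_units, log, decisions


def filter_low_abundance(reads: Iterable[FastqRead], counter: KmerCounter,
                         abund_cutoff: int = DEFAULT_ABUND_CUTOFF,
                         min_read_length: int = DEFAULT_MIN_READ_LENGTH,
                         ) -> list[FastqRead]:
    """Trim each read to its longest prefix whose k-mers all have count
    >= abund_cutoff; drop reads falling below min_read_length.

    The counter must be populated from the retained read set, so that
    singleton k-mers (most of which are sequencing errors) fall below the
    trusted-count floor.
    """
    k = counter.k
    out = []
    for read in reads:
        n_kmers = len(read.seq) - k + 1
        keep_len = len(read.seq)
        for i in range(max(n_kmers, 0)):
            if counter.get(read.seq[i:i + k]) < abund_cutoff:
                keep_len = i + k - 1  # prefix ends before the bad k-mer
                break
        if keep_len >= min_read_length:
            out.append(FastqRead(read.id, read.seq[:keep_len],
                                 read.qual[:keep_len]))
    return out


def pair_reads(reads1: Sequence[FastqRead], reads2: Sequence[FastqRead]
               ) -> list[tuple[FastqRead, FastqRead]]:
    if len(reads1) != len(reads2):
        raise ValueError("mate files have different read counts")
    return list(zip(reads1, reads2))


def normalize_fastq(in1, out1, in2=None, out2=None,
                    params: NormalizationParams | None = None,
                    trim: bool = True, shuffle_seed: int | None = None,
                    ) -> tuple[NormalizationLog, list[Decision]]:
    """File-level convenience wrapper: trim, (optionally) shuffle input
    order with a seeded RNG, normalize, and run the low-abundance filter
    over the kept set before writing FASTQ output."""
    params = params or NormalizationParams()
    reads1 = read_fastq(in1)
    if trim:
        reads1 = [trim_quality_3prime(r, params.quality_cutoff) for r in reads1]
    if in2 is not None:
        reads2 = read_fastq(in2)
        if trim:
            reads2 = [trim_quality_3prime(r, params.quality_cutoff)
                      for r in reads2]
        units: list[tuple[FastqRead, ...]] = [
            (a, b) for a, b in pair_reads(reads1, reads2)]
    else:
        units = [(r,) for r in reads1]
    if shuffle_seed is not None:
        _random.Random(shuffle_seed).shuffle(units)

    counter = KmerCounter(params.k)
    kept, log, decisions = normalize_stream(units, params, counter)
    flat = [r for unit in kept for r in unit]
    flat = filter_low_abundance(flat, counter, params.abund_cutoff,
                                params.min_read_length)
    filtered_ids = {r.id for r in flat}
    trimmed = {r.id: r for r in flat}
    if in2 is not None and out2 is not None:
        k1, k2 = [], []
        for unit in kept:
            survivors = [trimmed[r.id] for r in unit if r.id in filtered_ids]
            if len(unit) == 2 and len(survivors) == 2:
                k1.append(survivors[0])
                k2.append(survivors[1])
            elif survivors:
                k1.extend(survivors)
        write_fastq(out1, k1)
        write_fastq(out2, k2)
    else:
        write_fastq(out1, flat)
    return log, decisions


def write_decision_log(path, decisions: Iterable[Decision]) -> None:
    with open(path, "w") as fh:
        fh.write("unit_id\tmedian\tkept\n")
        for d in decisions:
            fh.write(f"{d.unit_id}\t{d.median}\t{int(d.kept)}\n")
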