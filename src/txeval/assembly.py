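"""Descriptive statistics of contig sets.

Summaries follow the usual assembly-report conventions: contigs below a
minimum length (default 201 bp) are excluded, the median of an even-sized
set is the mean of the two middle lengths, and length histograms use
half-open doubling bins anchored at 200 bp with an open top bin at
6400 bp.  The isotig mean measures how many alternative reconstructions
(putative isoforms) share a Trinity graph component, by grouping
``compX_cY_seqZ`` identifiers on their prefix before ``_seq``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

DEFAULT_MIN_LENGTH = 201
DEFAULT_BIN_EDGES = (200, 400, 800, 1600, 3200, 6400)


@dataclass
class ContigSet:
    """Contig id -> nucleotide sequence."""
    records: dict[str, str]

    def __post_init__(self):
        for cid, seq in self.records.items():
            if not seq:
                raise ValueError(f"contig {cid} has an empty sequence")

    @property
    def lengths(self) -> dict[str, int]:
        return {cid: len(s) for cid, s in self.records.items()}


@dataclass
class StatsSummary:
    total: int
    max_len: int | None
    min_len: int | None
    mean_len: float | None
    median_len: float | None

    def to_dict(self) -> dict:
        return {
            "total": self.total, "max_len": self.max_len,
            "min_len": self.min_len, "mean_len": self.mean_len,
            "median_len": self.median_len,
        }


@dataclass
class LengthHistogram:
    bin_edges: tuple  # finite ascending lower edges; last bin is open
    counts: list[int]
    proportions: list[float]

    def bin_labels(self) -> list[str]:
        labels = []
        edges = list(self.bin_edges)
        for lo, hi in zip(edges[:-1], edges[1:]):
            labels.append(f"[{lo},{hi})")
        labels.append(f">={edges[-1]}")
        return labels


def _contig_lengths(contigs) -> Sequence[int]:
    if isinstance(contigs, ContigSet):
        return list(contigs.lengths.values())
    if isinstance(contigs, Mapping):
        return [len(s) for s in contigs.values()]
    return list(contigs)


def contig_stats(contigs, min_length: int = DEFAULT_MIN_LENGTH) -> StatsSummary:
    """Total / max / min / mean / median length of contigs >= min_length.

    Mean is reported to 0 dp; an empty surviving set yields the
    empty-summary sentinel (total 0, all lengths None) rather than an
    error.
    """
    lengths = np.array([n for n in _contig_lengths(contigs) if n >= min_length])
    if lengths.size == 0:
        return StatsSummary(0, None, None, None, None)
    return StatsSummary(
        total=int(lengths.size),
        max_len=int(lengths.max()),
        min_len=int(lengths.min()),
        mean_len=float(round(lengths.mean())),
        median_len=float(np.median(lengths)),
    )


def length_histogram(contigs, bin_edges: Sequence[int] = DEFAULT_BIN_EDGES
                     ) -> LengthHistogram:
    """Counts and proportions of contigs per half-open length bin.

    Bins are [e0,e1), [e1,e2), ..., [e_last, inf); contigs shorter than
    the first edge are excluded from the histogram.
    """
    edges = list(bin_edges)
    if any(b <= a for a, b in zip(edges, edges[1:])):
        raise ValueError("bin edges must be strictly ascending")
    lengths = np.asarray(_contig_lengths(contigs))
    lengths = lengths[lengths >= edges[0]]
    counts = np.histogram(lengths, bins=edges + [np.inf])[0]
    total = int(counts.sum())
    props = (counts / total).tolist() if total else [0.0] * len(counts)
    return LengthHistogram(tuple(edges), counts.astype(int).tolist(), props)


@dataclass
class IsotigMean:
    mean_group_size: float
    n_components: int
    n_unparsed: int = 0


def component_key(contig_id: str) -> str | None:
    """Trinity graph-component key: the id prefix before ``_seq``.

    Returns None when the id does not carry a ``_seq`` part.
    """
    idx = contig_id.rfind("_seq")
    if idx <= 0:
        return None
    return contig_id[:idx]


def isotig_mean(contig_ids: Iterable[str]) -> IsotigMean:
    """Mean number of contigs (putative isotigs) per graph component."""
    ids = list(contig_ids)
    if not ids:
        raise ValueError("no contig ids supplied")
    groups: dict[str, int] = {}
    unparsed = 0
    for cid in ids:
        key = component_key(cid)
        if key is None:
            key = cid  # singleton group
            unparsed += 1
        groups[key] = groups.get(key, 0) + 1
    if unparsed:
        warnings.warn(f"{unparsed} contig id(s) without a _seq part form "
                      "singleton components")
    return IsotigMean(len(ids) / len(groups), len(groups), unparsed)


def n50(contigs, min_length: int = 0) -> int | None:
    """N50 of the length distribution (offered as an extra summary)."""
    lengths = sorted((n for n in _contig_lengths(contigs) if n >= min_length),
                     reverse=True)
    if not lengths:
        return None
    half = sum(lengths) / 2
    acc = 0
    for n in lengths:
        acc += n
        if acc >= half:
            return n
    return lengths[-1]
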