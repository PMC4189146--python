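"""Gene-level TPM, per-library top-fraction sets, the cross-library core
set, and gene-set fold enrichment.

TPM (transcripts per million) length-normalizes counts within a library:
``TPM_i = (c_i / l_i) / sum_j (c_j / l_j) * 1e6``, so every library sums
to one million.  The "core" of a multi-library experiment is the
intersection of each library's top expressed fraction (default: the top
5% of genes with TPM > 0).  Enrichment of a gene set against a background
uses the hypergeometric upper tail with Benjamini-Hochberg adjustment;
fold enrichment is ``(k/n) / (K/N)``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

DEFAULT_TOP_FRACTION = 0.05
DEFAULT_ALPHA = 0.05


def tpm(counts: pd.Series, eff_lengths: pd.Series) -> pd.Series:
    """TPM vector for one library.

    counts and eff_lengths are indexed by gene; effective lengths are in
    bp and must be positive.
    """
    counts = counts.astype(float)
    lengths = eff_lengths.reindex(counts.index).astype(float)
    if lengths.isna().any():
        missing = list(counts.index[lengths.isna()])[:5]
        raise ValueError(f"genes missing effective lengths: {missing}")
    if (lengths <= 0).any():
        raise ValueError("effective lengths must be positive")
    if not (counts > 0).any():
        raise ValueError("library has no expressed genes (all counts zero)")
    rate = counts / lengths
    return rate / rate.sum() * 1e6


def tpm_matrix(counts: pd.DataFrame, eff_lengths: pd.Series) -> pd.DataFrame:
    """Per-library TPM for a genes x libraries count table."""
    return counts.apply(lambda col: tpm(col, eff_lengths), axis=0)


def top_fraction(tpm_vector: pd.Series, q: float = DEFAULT_TOP_FRACTION
                 ) -> set[str]:
    """Top expressed genes of one library.

    Ranks the G genes with TPM > 0 by descending TPM and takes the first
    ceil(q * G); ties at the boundary are broken by ascending gene id.
    """
    if not (0 < q <= 1):
        raise ValueError("q must lie in (0, 1]")
    expressed = tpm_vector[tpm_vector > 0]
    if expressed.empty:
        raise ValueError("no expressed genes in library")
    n_take = math.ceil(q * len(expressed))
    order = sorted(expressed.items(), key=lambda kv: (-kv[1], kv[0]))
    return {gene for gene, _ in order[:n_take]}


@dataclass
class CoreSet:
    """Genes in the top fraction of every library, sorted by descending
    mean TPM."""
    genes: list[str]
    avg_tpm: dict[str, float]
    q: float

    def __len__(self) -> int:
        return len(self.genes)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"gene": self.genes,
                             "avg_tpm": [self.avg_tpm[g] for g in self.genes]})


def core_set(per_library_top: Sequence[set[str]], tpm_table: pd.DataFrame,
             q: float = DEFAULT_TOP_FRACTION) -> CoreSet:
    """Intersection of per-library top sets, annotated with the unweighted
    mean TPM across libraries."""
    if not per_library_top:
        raise ValueError("at least one top set is required")
    genes = set.intersection(*map(set, per_library_top))
    means = tpm_table.mean(axis=1)
    ordered = sorted(genes, key=lambda g: (-means[g], g))
    return CoreSet(ordered, {g: float(means[g]) for g in ordered}, q)


def core_set_from_counts(counts: pd.DataFrame, eff_lengths: pd.Series,
                         q: float = DEFAULT_TOP_FRACTION) -> CoreSet:
    """Counts -> TPM -> per-library top-q -> intersection, in one call."""
    tpms = tpm_matrix(counts, eff_lengths)
    tops = [top_fraction(tpms[lib], q) for lib in tpms.columns]
    return core_set(tops, tpms, q)


def overlap_with_list(core: CoreSet | Iterable[str], reference_list: Iterable[str]
                      ) -> tuple[set[str], int]:
    """Intersection of the core set with an external gene list."""
    core_genes = set(core.genes) if isinstance(core, CoreSet) else set(core)
    ref = set(reference_list)
    if not ref:
        warnings.warn("reference gene list is empty")
    common = core_genes & ref
    return common, len(common)


def enrich(term_map: Mapping[str, Iterable[str]], study: Iterable[str],
           background: Iterable[str], alpha: float = DEFAULT_ALPHA
           ) -> pd.DataFrame:
    """Fold enrichment and hypergeometric upper-tail p per term.

    For a term with K background genes, a study set of size n drawn from
    a background of size N, and k study hits:
    fold = (k/n) / (K/N) and p = P[X >= k] with X ~ Hypergeom(N, K, n).
    p values are Benjamini-Hochberg adjusted over all tested terms;
    terms with adjusted p < alpha are flagged enriched.
    """
    study = set(study)
    background = set(background)
    if not study <= background:
        extra = sorted(study - background)[:5]
        raise ValueError(f"study genes outside background: {extra}")
    N, n = len(background), len(study)
    rows = []
    for term, genes in term_map.items():
        term_genes = set(genes) & background
        K = len(term_genes)
        k = len(term_genes & study)
        fold = (k / n) / (K / N) if K and n else 0.0
        p = float(hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        rows.append({"term": term, "k": k, "n": n, "K": K, "N": N,
                     "fold": fold, "p": p})
    table = pd.DataFrame(rows)
    if len(table):
        table["p_adj"] = multipletests(table["p"], method="fdr_bh")[1]
        table["enriched"] = table["p_adj"] < alpha
        table = table.sort_values(["p_adj", "term"]).reset_index(drop=True)
    return table
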