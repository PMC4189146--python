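# Methods

This note documents the models and procedures `txeval` implements, the
parameters that matter, what the synthetic-data generator does and does
not emulate, and the numerical choices made where the design was open.

## Digital normalization

Digital normalization estimates a read's sequencing depth without a
reference by the median abundance of its k-mers and discards reads from
already well-covered loci. The implementation is a single streaming
pass: for each unit (a read, or a mate pair) the median count of its
canonical k-mers — each k-mer collapsed with its reverse complement to
the lexicographic minimum — is looked up in a counter accumulated from
*kept* units only. If the median is below the coverage cutoff *C* the
unit is kept and its k-mers are counted; otherwise it is discarded and
the counter is untouched. Counting only kept reads is essential: it is
what makes the retention law exact (D identical copies of a read with
C < D retain exactly C copies, because copy *i* is judged on median
*i* − 1).

Parameters and defaults:

| parameter | default | meaning |
| --- | --- | --- |
| `k` | 25 bp | k-mer size; reads shorter than max(k, `min_read_length`) are skipped |
| `coverage_cutoff` (*C*) | 30 | keep while median k-mer abundance < C |
| `quality_cutoff` (*Q*) | 24 (Phred) | 3' trimming: the maximal suffix in which every base has quality < Q is removed; the 5' end is never altered |
| `abund_cutoff` | 2 | trusted-count floor for the low-abundance filter pass |
| `paired_policy` | keep-if-either | a pair is kept if either mate's median is below C (keep-if-both and unpaired are available); the default preserves pairing while erring toward retention |
| `min_read_length` | 25 bp | reads below this after trimming are dropped |

The median of *m* counts is the element at index ⌊m/2⌋ of the ascending
sort — for even *m* the upper-middle element — so it is always an
observed integer count and the decision rule is deterministic. The
k-mer counter is an exact hash map; at desk scale exactness keeps every
test deterministic, and any probabilistic counting structure honouring
the same query/increment contract can be dropped in for large data.
Input-order shuffling before normalization is exposed as a seeded
option, since the retained set (though not its coverage guarantee)
depends on stream order.

The low-abundance filter pass (`filter_low_abundance`) runs after
normalization with the counter populated from the kept set: each read
is truncated to its longest prefix in which every k-mer reaches
`abund_cutoff`, i.e. at the first untrusted k-mer starting at position
*p* the read keeps *p* + *k* − 1 bases; reads falling below
`min_read_length` are dropped. With the default k = 25 and minimum
length 25, a read whose first k-mer is untrusted is removed entirely.

Expected behaviour on uniform error-free coverage: the retained
per-base depth lies between *C* and 3*C*. The lower bound is the
decision rule itself; the slack above *C* arises because the median of
a read's k-mers lags the per-base depth at the read's ends and because
decisions are made on whole reads in stream order. Measured on a 10 kb
transcript at depth 100 (the acceptance condition) the interior depth
settles around 40–45.

## Assembly metrics

Summary statistics count contigs at or above a minimum length, default
201 bp, the conventional reporting floor for Trinity-style assemblies;
the median of an even-sized set is the mean of the two middle lengths
and the mean is reported to 0 dp. Length histograms use half-open bins
on a doubling ladder (200, 400, 800, 1600, 3200, 6400, ∞ by default;
the edges are overridable) with the top bin closed only by infinity, so
a 6400 bp contig falls in the open top bin. The isotig mean groups
contig ids by their prefix before `_seq` — the assembly-graph component
plus Trinity's `c` sub-cluster — and reports the mean group size; ids
without a `_seq` part form singleton groups and are tallied as a
warning count rather than an error. N50 is offered as an extra summary
but is not part of the evaluation surface.

## CDS-reconstruction evaluation

The evaluation frame is a reference proteome: protein lengths in amino
acids plus a two-column protein → gene map (the shape of an
oma-ensembl orthology file), letting hits against distinct isoforms
aggregate to one gene. Hits arrive as 12-column BLAST tabular rows from
a BLASTX-style search (nucleotide query, protein subject); rows with
e-value ≥ 1e-10 are dropped at parse time (per-HSP filtering), 1-based
inclusive subject coordinates become 0-based half-open intervals, and
rows with sstart > send are rejected as malformed for protein subjects.

Subject coverage of a (contig, protein) pair is the length of the
*union* of the pair's subject intervals divided by the protein length.
Union (rather than best-HSP) is the most faithful reading of "fraction
of the protein's length covered" when an alignment splits into several
HSPs, and it is oracle-testable against per-residue bitmap marking.
Query-side coordinates and reading frame are ignored: reconstruction is
defined on the protein's length.

The report classifies coverage at levels 0.99/0.90/0.80/0.50, applied
as coverage ≥ level so that an exactly full-length reconstruction
(1.00) and an exact boundary value both count; a gene counts at a level
when at least one isoform does, a contig when it achieves the level on
some protein, and totals count everything with any significant hit.
Counts are therefore non-decreasing from the strictest level down to
the totals. Per-gene summaries (and the coverage histogram, bin width
0.01, terminal bin closed at 1.0) use the best-covered isoform, never
an average. Multi-library unions namespace query ids as
`<library>:<contig>` before merging, because assembler ids restart per
assembly; union counts consequently dominate every constituent
library's counts. Whether the "contigs" rows count distinct contigs or
contig–protein pairs was an open reading; distinct contigs was chosen
as the natural meaning of "contigs that reconstructed a CDS at this
level".

## Expression core set and enrichment

Gene-level quantification starts from a supplied count table — the
multi-mapping EM estimator of an aligner/quantifier pipeline is out of
scope — plus per-gene effective lengths. TPM for gene *i* in one
library is (c_i/l_i) / Σ_j (c_j/l_j) × 10⁶ and sums to one million by
construction. The top fraction of a library ranks the G genes with
TPM > 0 (the strict-positivity filter is stated explicitly because the
choice of universe changes G) and takes the first ⌈q·G⌉, default
q = 0.05, with boundary ties broken by ascending gene id for
determinism. The core set is the plain intersection of all libraries'
top sets, annotated with the unweighted mean TPM across libraries; an
empty intersection is a valid result. Overlap with an external gene
list is a set intersection reported with both counts.

Enrichment of a study set against a background uses, per term, the
hypergeometric upper tail P[X ≥ k] (scipy) with fold enrichment
(k/n)/(K/N), and Benjamini–Hochberg step-up adjustment over all tested
terms (statsmodels); terms with adjusted p below α = 0.05 are flagged.
The EASE-style deflated Fisher statistic used by some web services is
deliberately not replicated; the standard hypergeometric is the
documented stand-in.

## Synthetic data: what is emulated, what is not

The generator fabricates the full input chain with planted truth:

* **Reference** — `n_genes` genes with 1–3 isoforms (configurable int
  or inclusive range), protein lengths uniform on 100–300 aa by
  default, i.i.d. amino-acid sequences, and a CDS built from one fixed
  sense codon per amino acid so CDS length is exactly 3× protein
  length. Deterministic per seed, byte-identical outputs.
* **Contigs** — a completeness plan assigns genes to reconstruction
  bands: [0.99, 1.0], [0.90, 0.99), [0.80, 0.90), [0.50, 0.80) and a
  sub-threshold band [0.10, 0.50). Bands are half-open below the next
  level so each planted gene lands in exactly one report row. The
  covered length is an integer amino-acid count sampled inside the
  band (a protein too short to admit one raises a parameter error),
  and the contig is the corresponding CDS slice. Optional
  fragmentation splits a planted contig into two pieces whose subject
  intervals partition the planted interval; since pieces are distinct
  queries, exact plan recovery is only guaranteed at fragmentation 0.
* **Alignments** — one outfmt-6 row per contig piece with subject
  coordinates equal to the planted interval. The e-value model is
  monotone decreasing in alignment length, 10^−(8 + length), floored
  at 1e-180 — only the ordering against the 1e-10 cutoff matters, and
  every planted alignment (≥ 10 aa under the defaults) clears it.
  Optional spurious hits always have subject coverage below 0.50 and so
  perturb only the report's total rows; they are recorded in a
  side-channel file.
* **Reads** — paired, default 101 bp, drawn from fragments placed
  uniformly along each transcript at the depth given per transcript;
  mate 2 is the reverse complement of the fragment's 3' end.
  Substitution errors are i.i.d. per base; qualities are a constant
  Phred 40. Expected interior depth matches the requested depth within
  a few percent for transcripts much longer than the fragment.
* **Expression** — gamma-Poisson (negative-binomial) counts with
  variance μ + φμ², φ = 0 degenerating to Poisson. As in real RNA-seq,
  a gene's expected count is proportional to its effective length times
  its expression rate; all genes share one baseline rate
  (`baseline_mean` = 100 expected counts at the average length) and
  core genes get `core_multiplier` (default 10) times that rate in
  every library. Planting the multiplier on the rate rather than the
  raw count mean means the full 10× margin survives length
  normalization, so the planted core is recoverable on the TPM scale
  and, with the ≤ 3× default length spread, also dominates raw counts
  in the Poisson limit.

Not emulated: splice isoforms sharing sequence (isoforms are
independent draws, so contigs never hit several isoforms at once),
instrument-specific quality profiles, indels and chimeras, positional
coverage bias, and library-size differences beyond what TPM removes.
Passing tests therefore demonstrate the correctness of the computations
on inputs whose ground truth is known exactly — not robustness to the
alignment ambiguity and annotation noise of real data.

The core-recovery study condition uses 400 genes with a 13-gene planted
core and q = 0.05, so the core (13) is a strict subset of each
library's top set (20). That mirrors real multi-library designs — a
universal core roughly half the size of the per-library top sets —
and leaves the slack that makes exact intersection recovery the
expected outcome rather than a zero-margin ranking feat. Per-library
depth distributions are not prescribed anywhere authoritative, so depth
is an explicit parameter rather than a built-in guess.

## Pipeline and determinism

The `txeval run` pipeline executes simulate → normalize → stats →
recon → core → enrich from one flat config with per-stage toggles;
skipping a stage never alters the outputs of stages that run. Every
bundle carries a manifest with the package version, all stage
parameters and seeds, and SHA-256 checksums of outputs; identical
configs over identical inputs produce byte-identical bundles. All
randomness flows through explicit integer seeds into numpy Generators;
writers emit fixed layouts (60-column FASTA, four-line FASTQ, fixed
numeric formats in hit tables) so round trips are byte-stable.

## Problem sizes in the test and acceptance runs

The bundled checks run at desk scale, chosen as the package's own
test-design sizes: 100 random completeness plans of up to 200 genes
with up to 3 isoforms; 1,000 random coverage instances on proteins of
≤ 50 aa with ≤ 5 intervals; a duplicate-law grid of D ∈ {10, 50, 100} ×
C ∈ {1, 5, 30}; one 10 kb transcript at depth 100 for the normalization
depth bound; 100 random count matrices for TPM conservation; 100 seeded
13-library runs for core recovery; and a dense (N ≤ 60, K, n, k) grid
for the hypergeometric oracle. The whole suite and the acceptance
script each complete in well under a minute on one CPU.

## Known limitations

* The two normalization variants reported around Trinity-based
  workflows differ in internals that are not publicly specified; both
  are realized here as the one parameterized algorithm above.
* Normalization output depends on read order (the coverage guarantee
  does not); use the seeded shuffle for reproducible order-sensitivity
  studies.
* The exact k-mer counter holds all canonical k-mers in memory —
  appropriate for the desk-scale inputs the package targets, not for
  hundreds of millions of reads.
* Coverage is measured purely on the subject side; percent identity is
  carried through but not thresholded beyond the e-value cut.
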