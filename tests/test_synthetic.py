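"""The synthetic-data generators and their planted ground truth."""

import numpy as np
import pytest

from txeval import synthetic
from txeval.normalize import revcomp
from txeval.synthetic import (PlantedTruth, expected_level_tallies,
                              generate_alignments, generate_contigs,
                              generate_expression, generate_reads,
                              generate_reference)


class TestGenerateReference:
    def test_deterministic_outputs(self, tmp_path):
        a, b = tmp_path / "a", tmp_path / "b"
        generate_reference(10, isoforms_per_gene=1, protein_length=100,
                           seed=1, outdir=a)
        generate_reference(10, isoforms_per_gene=1, protein_length=100,
                           seed=1, outdir=b)
        for name in ("proteins.faa", "transcripts.fna", "gene_map.tsv"):
            assert (a / name).read_bytes() == (b / name).read_bytes()

    def test_cds_is_three_times_protein_length(self, small_ref):
        for pid, pseq in small_ref.proteins.items():
            assert len(small_ref.transcripts[pid]) == 3 * len(pseq)

    def test_gene_map_row_count(self):
        ref = generate_reference(5, isoforms_per_gene=3, seed=4)
        assert len(ref.gene_map) == 15
        assert len({pid for pid, _ in ref.gene_map}) == 15

    def test_every_protein_maps_to_one_gene(self, small_ref):
        gene_of = small_ref.gene_of
        assert set(gene_of) == set(small_ref.proteins)
        assert set(gene_of.values()) <= set(small_ref.genes)

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            generate_reference(0)
        with pytest.raises(ValueError):
            generate_reference(3, isoforms_per_gene=(5, 2))


class TestGenerateContigs:
    def test_single_gene_full_plan(self):
        ref = generate_reference(1, isoforms_per_gene=1, seed=2)
        contigs, truth = generate_contigs(ref, {0.99: 1, "sub": 0}, seed=3)
        assert len(contigs) == 1
        (_, _, frac), = truth.contig_provenance.values()
        assert frac >= 0.99

    def test_plan_counts_by_construction(self, small_ref):
        plan = {0.99: 2, 0.90: 3, 0.80: 1, 0.50: 2, "sub": 1}
        contigs, truth = generate_contigs(small_ref, plan, seed=5)
        assert len(contigs) == 9
        levels = list(truth.level_of_gene.values())
        assert [levels.count(l) for l in (0.99, 0.90, 0.80, 0.50, "sub")] \
            == [2, 3, 1, 2, 1]

    def test_fractions_inside_their_bands(self, small_ref):
        plan = {0.99: 3, 0.90: 3, 0.80: 3, 0.50: 3, "sub": 3}
        _, truth = generate_contigs(small_ref, plan, seed=6)
        bands = {0.99: (0.99, 1.0 + 1e-12), 0.90: (0.90, 0.99),
                 0.80: (0.80, 0.90), 0.50: (0.50, 0.80), "sub": (0.10, 0.50)}
        by_protein = {pid: frac for pid, _, frac
                      in truth.contig_provenance.values()}
        for gid, level in truth.level_of_gene.items():
            fracs = [f for p, f in by_protein.items()
                     if small_ref.gene_of[p] == gid]
            lo, hi = bands[level]
            assert len(fracs) == 1 and lo <= fracs[0] < hi

    def test_fraction_equals_interval_over_length(self, small_ref):
        _, truth = generate_contigs(small_ref, {0.90: 4, "sub": 2}, seed=7)
        lengths = small_ref.protein_lengths
        for pid, (s, e), frac in truth.contig_provenance.values():
            assert 0.0 <= frac <= 1.0
            assert frac == (e - s) / lengths[pid]

    def test_contig_sequence_matches_planted_cds_slice(self, small_ref):
        contigs, truth = generate_contigs(small_ref, {0.80: 3}, seed=8)
        for cid, (pid, (s, e), _) in truth.contig_provenance.items():
            assert contigs[cid] == small_ref.transcripts[pid][3 * s:3 * e]

    def test_full_fragmentation_partitions_intervals(self, small_ref):
        contigs, truth = generate_contigs(small_ref, {0.90: 4},
                                          fragmentation=1.0, seed=9)
        assert len(contigs) == 8  # every planned contig in 2 pieces
        by_comp = {}
        for cid, (pid, iv, _) in truth.contig_provenance.items():
            by_comp.setdefault(cid.split("_")[0], []).append(iv)
        for pieces in by_comp.values():
            (s1, e1), (s2, e2) = sorted(pieces)
            assert e1 == s2  # union is the planted interval, no overlap

    def test_plan_exceeding_gene_count_rejected(self, small_ref):
        with pytest.raises(ValueError, match="plan"):
            generate_contigs(small_ref, {0.99: 100})


class TestGenerateAlignments:
    def test_rows_biject_with_pieces(self, small_ref):
        _, truth = generate_contigs(small_ref, {0.99: 2, 0.50: 2}, seed=10)
        rows, spurious = generate_alignments(truth, small_ref, seed=11)
        assert spurious == []
        assert {(r[0], r[1]) for r in rows} == {
            (cid, pid) for cid, (pid, _, _)
            in truth.contig_provenance.items()}

    def test_subject_coordinates_one_based_inclusive(self):
        ref = generate_reference(1, isoforms_per_gene=1, protein_length=100,
                                 seed=12)
        pid = next(iter(ref.transcripts))
        truth = PlantedTruth(
            contig_provenance={"c1": (pid, (0, 100), 1.0)})
        rows, _ = generate_alignments(truth, ref)
        assert (rows[0][8], rows[0][9]) == (1, 100)

    def test_evalues_below_significance_cutoff(self, small_ref):
        _, truth = generate_contigs(small_ref, {0.50: 3, "sub": 3}, seed=13)
        rows, _ = generate_alignments(truth, small_ref, seed=14)
        assert all(r[10] < 1e-10 for r in rows)

    def test_evalue_model_monotone_with_floor(self):
        evs = [synthetic.default_evalue_model(n) for n in range(1, 400)]
        assert all(a >= b for a, b in zip(evs, evs[1:]))
        assert min(evs) == 1e-180

    def test_spurious_hits_stay_subthreshold_coverage(self, small_ref):
        _, truth = generate_contigs(small_ref, {0.99: 5, 0.50: 5}, seed=15)
        _, spurious = generate_alignments(truth, small_ref,
                                          spurious_rate=1.0, seed=16)
        assert spurious  # rate 1 on 10 contigs
        lengths = small_ref.protein_lengths
        for row in spurious:
            coverage = (row[9] - row[8] + 1) / lengths[row[1]]
            assert coverage < 0.50
            assert row[10] < 1e-10


class TestGenerateReads:
    def _one_transcript_ref(self, aa_len, seed=17):
        ref = generate_reference(1, isoforms_per_gene=1,
                                 protein_length=aa_len, seed=seed)
        return ref, next(iter(ref.transcripts))

    def test_error_free_reads_are_exact_substrings(self):
        ref, pid = self._one_transcript_ref(400)
        truth = PlantedTruth(depth_profile={pid: 50.0})
        r1, r2 = generate_reads(ref, truth, error_rate=0.0, seed=18)
        tseq = ref.transcripts[pid]
        for r in r1:
            assert r.seq in tseq
        for r in r2:
            assert revcomp(r.seq) in tseq

    def test_same_seed_same_bytes(self, tmp_path):
        ref, pid = self._one_transcript_ref(200)
        truth = PlantedTruth(depth_profile={pid: 20.0})
        for sub in ("x", "y"):
            d = tmp_path / sub
            d.mkdir()
            generate_reads(ref, truth, seed=19, out1=d / "r1.fq",
                           out2=d / "r2.fq")
        assert (tmp_path / "x/r1.fq").read_bytes() == \
            (tmp_path / "y/r1.fq").read_bytes()
        assert (tmp_path / "x/r2.fq").read_bytes() == \
            (tmp_path / "y/r2.fq").read_bytes()

    def test_interior_depth_near_target(self):
        # 10 kb transcript at depth 100: binomial coverage bound
        ref, pid = self._one_transcript_ref(3334)
        truth = PlantedTruth(depth_profile={pid: 100.0})
        r1, r2 = generate_reads(ref, truth, seed=20)
        tlen = len(ref.transcripts[pid])
        depth = np.zeros(tlen)
        tseq = ref.transcripts[pid]
        for r in list(r1) + list(r2):
            start = tseq.find(r.seq if r.seq in tseq else revcomp(r.seq))
            depth[start:start + len(r.seq)] += 1
        interior = depth[500:-500]
        assert 90 <= interior.mean() <= 110

    def test_mate_ids_share_stem(self):
        ref, pid = self._one_transcript_ref(300)
        truth = PlantedTruth(depth_profile={pid: 10.0})
        r1, r2 = generate_reads(ref, truth, seed=21)
        for a, b in zip(r1, r2):
            assert a.id[:-2] == b.id[:-2]
            assert a.id.endswith("/1") and b.id.endswith("/2")

    def test_short_transcript_skipped_with_warning(self):
        ref, pid = self._one_transcript_ref(20)  # 60 bp < 101 bp read
        truth = PlantedTruth(depth_profile={pid: 10.0})
        with pytest.warns(UserWarning, match="shorter"):
            r1, r2 = generate_reads(ref, truth, seed=22)
        assert r1 == [] and r2 == []


class TestGenerateExpression:
    def test_thirteen_libraries_by_default(self, small_ref, tmp_path):
        counts, eff = generate_expression(
            small_ref, core_genes={small_ref.genes[0]}, seed=23,
            outdir=tmp_path)
        assert counts.shape[1] == 13
        assert len(list(tmp_path.glob("*.counts.tsv"))) == 13
        assert (eff.index == sorted(small_ref.genes)).all()

    def test_poisson_limit_core_dominates_counts(self, small_ref):
        core = set(small_ref.genes[:3])
        counts, _ = generate_expression(small_ref, core_genes=core,
                                        core_multiplier=10.0, dispersion=0.0,
                                        seed=24)
        non_core = [g for g in counts.index if g not in core]
        for lib in counts.columns:
            assert counts.loc[sorted(core), lib].min() >= \
                counts.loc[non_core, lib].max()

    def test_deterministic_for_seed(self, small_ref):
        a, _ = generate_expression(small_ref, core_genes=set(), seed=25,
                                   core_multiplier=1.0)
        b, _ = generate_expression(small_ref, core_genes=set(), seed=25,
                                   core_multiplier=1.0)
        assert a.equals(b)

    def test_empty_core_with_multiplier_warns(self, small_ref):
        with pytest.warns(UserWarning, match="empty core"):
            generate_expression(small_ref, core_genes=set(), seed=26)

    def test_foreign_core_gene_rejected(self, small_ref):
        with pytest.raises(ValueError, match="subset"):
            generate_expression(small_ref, core_genes={"NOT_A_GENE"})


class TestExpectedTallies:
    def test_cumulative_over_levels(self):
        plan = {0.99: 2, 0.90: 3, 0.80: 1, 0.50: 2, "sub": 1}
        assert expected_level_tallies(plan) == {
            0.99: (2, 2, 2), 0.90: (5, 5, 5),
            0.80: (6, 6, 6), 0.50: (8, 8, 8)}
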