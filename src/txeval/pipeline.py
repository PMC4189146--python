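"""End-to-end pipeline runner.

One flat config drives the stage sequence simulate -> normalize -> stats
-> recon -> core -> enrich; stages can be toggled off individually and a
skipped stage never alters the outputs of stages that do run.  Every run
writes a manifest recording the package version, all parameters and
seeds, and SHA-256 checksums of inputs and outputs, so an identical
config over identical inputs yields a byte-identical bundle.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, assembly, expression, homology, normalize, synthetic
from .seqio import ensure_dir, read_fasta

log = logging.getLogger("txeval")

STAGE_ORDER = ("simulate", "normalize", "stats", "recon", "core", "enrich")


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    return cfg


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage_cfg(config: dict, name: str) -> dict | None:
    stage = config.get(name)
    if stage is None or stage.get("enabled", True) is False:
        return None
    return stage


def run_pipeline(config: dict, outdir) -> dict:
    """Run the configured stages in order and write the report bundle.

    Returns the manifest dict (also written as manifest.json).  Any stage
    error aborts with the stage name attached.
    """
    out = ensure_dir(outdir)
    manifest: dict = {
        "version": __version__,
        "stages_run": [],
        "parameters": {},
        "inputs": {},
        "outputs": {},
    }
    state: dict = {}
    for stage in STAGE_ORDER:
        cfg = _stage_cfg(config, stage)
        if cfg is None:
            continue
        log.info("[%s] starting", stage)
        try:
            _RUNNERS[stage](cfg, out, state, manifest)
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        manifest["stages_run"].append(stage)
        manifest["parameters"][stage] = {
            k: v for k, v in cfg.items() if k != "enabled"}
        log.info("[%s] done", stage)
    for name, path in sorted(state.get("written", {}).items()):
        manifest["outputs"][name] = _sha256(path)
    manifest_path = out / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


def _record(state: dict, name: str, path) -> None:
    state.setdefault("written", {})[name] = str(path)


def _run_simulate(cfg, out, state, manifest):
    simdir = ensure_dir(out / "sim")
    seed = int(cfg.get("seed", 0))
    ref = synthetic.generate_reference(
        n_genes=int(cfg.get("n_genes", 50)),
        isoforms_per_gene=cfg.get("isoforms_per_gene", 2),
        protein_length=tuple(cfg.get("protein_length", (100, 300))),
        seed=seed, outdir=simdir)
    plan = {float(k) if k != "sub" else k: v
            for k, v in cfg.get("plan", {"0.99": 5, "0.90": 5, "0.80": 5,
                                         "0.50": 5, "sub": 5}).items()}
    contigs, truth = synthetic.generate_contigs(
        ref, plan, fragmentation=float(cfg.get("fragmentation", 0.0)),
        seed=seed + 1, outpath=simdir / "contigs.fna")
    synthetic.generate_alignments(
        truth, ref, spurious_rate=float(cfg.get("spurious_rate", 0.0)),
        seed=seed + 2, outpath=simdir / "hits.tsv")
    core = set(list(sorted(ref.genes))[: int(cfg.get("n_core", 3))])
    truth.core_genes = core
    synthetic.generate_expression(
        ref, n_libraries=int(cfg.get("n_libraries", 13)), core_genes=core,
        core_multiplier=float(cfg.get("core_multiplier", 10.0)),
        dispersion=float(cfg.get("dispersion", 0.1)),
        seed=seed + 3, outdir=simdir / "expr")
    if cfg.get("reads", False):
        truth.depth_profile = {
            pid: float(cfg.get("depth", 30.0)) for pid in ref.transcripts}
        synthetic.generate_reads(
            ref, truth, read_length=int(cfg.get("read_length", 101)),
            error_rate=float(cfg.get("error_rate", 0.0)), seed=seed + 4,
            out1=simdir / "reads_1.fastq", out2=simdir / "reads_2.fastq")
        _record(state, "sim/reads_1.fastq", simdir / "reads_1.fastq")
        _record(state, "sim/reads_2.fastq", simdir / "reads_2.fastq")
    with open(simdir / "truth_core.txt", "w") as fh:
        fh.write("\n".join(sorted(core)) + "\n")
    with open(simdir / "truth_provenance.tsv", "w") as fh:
        fh.write("contig\tprotein\tsstart\tsend\tfraction\n")
        for cid, (pid, (s, e), frac) in sorted(truth.contig_provenance.items()):
            fh.write(f"{cid}\t{pid}\t{s}\t{e}\t{frac:.10f}\n")
    state["sim"] = {"ref": ref, "truth": truth, "dir": simdir, "plan": plan}
    for name in ("proteins.faa", "transcripts.fna", "gene_map.tsv",
                 "contigs.fna", "hits.tsv", "truth_core.txt",
                 "truth_provenance.tsv"):
        _record(state, f"sim/{name}", simdir / name)


def _run_normalize(cfg, out, state, manifest):
    params = normalize.NormalizationParams(
        k=int(cfg.get("k", 25)),
        coverage_cutoff=float(cfg.get("coverage_cutoff", 30)),
        quality_cutoff=int(cfg.get("quality_cutoff", 24)),
        abund_cutoff=int(cfg.get("abund_cutoff", 2)),
        paired_policy=cfg.get("paired_policy", "keep-if-either"),
        min_read_length=int(cfg.get("min_read_length", 25)))
    simdir = state.get("sim", {}).get("dir")
    in1 = cfg.get("in1") or (simdir and simdir / "reads_1.fastq")
    in2 = cfg.get("in2") or (simdir and (simdir / "reads_2.fastq"
                                         if (simdir / "reads_2.fastq").exists()
                                         else None))
    if in1 is None or not Path(in1).exists():
        raise FileNotFoundError("normalize stage: no input FASTQ")
    out1 = out / "normalized_1.fastq"
    out2 = out / "normalized_2.fastq" if in2 else None
    logrec, decisions = normalize.normalize_fastq(
        in1, out1, in2, out2, params,
        shuffle_seed=cfg.get("shuffle_seed"))
    normalize.write_decision_log(out / "normalize_decisions.tsv", decisions)
    with open(out / "normalize_log.json", "w") as fh:
        json.dump({"reads_in": logrec.reads_in, "reads_kept": logrec.reads_kept,
                   "reads_discarded": logrec.reads_discarded,
                   "reads_skipped_short": logrec.reads_skipped_short,
                   "retention_fraction": logrec.retention_fraction},
                  fh, indent=2, sort_keys=True)
        fh.write("\n")
    _record(state, "normalized_1.fastq", out1)
    if out2:
        _record(state, "normalized_2.fastq", out2)
    _record(state, "normalize_log.json", out / "normalize_log.json")
    _record(state, "normalize_decisions.tsv", out / "normalize_decisions.tsv")


def _contigs_for(cfg, state):
    if cfg.get("contigs"):
        return read_fasta(cfg["contigs"])
    simdir = state.get("sim", {}).get("dir")
    if simdir:
        return read_fasta(simdir / "contigs.fna")
    raise FileNotFoundError("stats stage: no contig FASTA")


def _run_stats(cfg, out, state, manifest):
    contigs = _contigs_for(cfg, state)
    summary = assembly.contig_stats(contigs,
                                    min_length=int(cfg.get("min_length", 201)))
    hist = assembly.length_histogram(
        contigs, bin_edges=cfg.get("bin_edges", assembly.DEFAULT_BIN_EDGES))
    iso = assembly.isotig_mean(list(contigs))
    with open(out / "assembly_stats.json", "w") as fh:
        json.dump({**summary.to_dict(),
                   "isotig_mean": iso.mean_group_size,
                   "n50": assembly.n50(contigs)},
                  fh, indent=2, sort_keys=True)
        fh.write("\n")
    pd.DataFrame({"bin": hist.bin_labels(), "count": hist.counts,
                  "proportion": hist.proportions}).to_csv(
        out / "length_histogram.tsv", sep="\t", index=False)
    _record(state, "assembly_stats.json", out / "assembly_stats.json")
    _record(state, "length_histogram.tsv", out / "length_histogram.tsv")


def _run_recon(cfg, out, state, manifest):
    simdir = state.get("sim", {}).get("dir")
    if cfg.get("proteins") and cfg.get("gene_map"):
        db = homology.ProteinDB.from_files(cfg["proteins"], cfg["gene_map"])
    elif simdir:
        db = homology.ProteinDB.from_files(simdir / "proteins.faa",
                                           simdir / "gene_map.tsv")
    else:
        raise FileNotFoundError("recon stage: no protein database")
    hit_files = cfg.get("hits") or [str(simdir / "hits.tsv")]
    if isinstance(hit_files, str):
        hit_files = [hit_files]
    levels = tuple(cfg.get("levels", homology.DEFAULT_LEVELS))
    evalue = float(cfg.get("evalue", homology.DEFAULT_EVALUE))
    if len(hit_files) == 1:
        hits = homology.parse_blast_table(hit_files[0], evalue)
        report, table, best = homology.reconstruction_report(hits, db, levels)
    else:
        per_lib = {f"lib{i}": homology.parse_blast_table(p, evalue, f"lib{i}")
                   for i, p in enumerate(hit_files, 1)}
        report, table, best = homology.union_reports(per_lib, db, levels)
    report.to_frame().to_csv(out / "reconstruction_report.tsv", sep="\t",
                             index=False)
    homology.coverage_histogram(
        best, bin_width=float(cfg.get("bin_width", 0.01))).to_csv(
        out / "coverage_histogram.tsv", sep="\t", index=False)
    state["recon_report"] = report
    _record(state, "reconstruction_report.tsv", out / "reconstruction_report.tsv")
    _record(state, "coverage_histogram.tsv", out / "coverage_histogram.tsv")


def _run_core(cfg, out, state, manifest):
    simdir = state.get("sim", {}).get("dir")
    if cfg.get("counts_dir"):
        cdir = Path(cfg["counts_dir"])
    elif simdir:
        cdir = simdir / "expr"
    else:
        raise FileNotFoundError("core stage: no count tables")
    count_files = sorted(cdir.glob("*.counts.tsv"))
    cols = {}
    for f in count_files:
        lib = f.name.replace(".counts.tsv", "")
        cols[lib] = pd.read_csv(f, sep="\t", index_col="gene")["count"]
    counts = pd.DataFrame(cols)
    eff = pd.read_csv(cdir / "eff_lengths.tsv", sep="\t",
                      index_col="gene")["eff_length"]
    q = float(cfg.get("q", expression.DEFAULT_TOP_FRACTION))
    core = expression.core_set_from_counts(counts, eff, q)
    core.to_frame().to_csv(out / "core_set.tsv", sep="\t", index=False)
    state["core"] = core
    _record(state, "core_set.tsv", out / "core_set.tsv")


def _run_enrich(cfg, out, state, manifest):
    term_map: dict[str, set[str]] = {}
    with open(cfg["term_map"]) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            term, gene = line.split("\t")[:2]
            term_map.setdefault(term, set()).add(gene)
    background = set(Path(cfg["background"]).read_text().split())
    if cfg.get("study"):
        study = set(Path(cfg["study"]).read_text().split())
    elif "core" in state:
        study = set(state["core"].genes)
    else:
        raise FileNotFoundError("enrich stage: no study gene set")
    table = expression.enrich(term_map, study, background,
                              alpha=float(cfg.get("alpha", 0.05)))
    table.to_csv(out / "enrichment.tsv", sep="\t", index=False)
    _record(state, "enrichment.tsv", out / "enrichment.tsv")


_RUNNERS = {
    "simulate": _run_simulate,
    "normalize": _run_normalize,
    "stats": _run_stats,
    "recon": _run_recon,
    "core": _run_core,
    "enrich": _run_enrich,
}
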