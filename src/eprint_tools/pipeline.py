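"""End-to-end orchestration: cascade -> differential binding -> feature
annotation -> motif GSEA -> optional CLIP overlap / network -> optional
k-mer discovery, with a machine-readable run manifest.

The on-disk experiment layout is the one the simulator writes (and that a
user can assemble from their own data):

    samples.tsv                name / assay / condition / batch / library_size
    calls_<sample>.bed         per-sample peak calls (BED6)
    true_peaks.bed | peaks.bed intervals keying the count table
    peak_counts.tsv            peaks x samples
    gene_counts.tsv            genes x input samples
    annotation.gtf             minimal gene annotation
    genome.fa                  sequence (optional; needed for motif/k-mer)

Each stage writes into its own subdirectory exactly once; a failure leaves
a ``.partial`` marker naming the failed stage.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cascade import CascadeConfig, map_counts_to_merged, merge_replicate_peaks, run_cascade
from .core import (GeneExpressionTable, SampleInfo, read_annotation, read_bed,
                   read_count_table, read_fasta, write_bed)
from .differential import PRESETS, DifferentialBindingModel, deg_on_input
from .features import classify_peaks, feature_density
from .kmers import (cluster_kmer_enrichment, cluster_peaks, kmer_presence,
                    partition_known_unknown, unknown_kmer_gsea)
from .motifs import gsea_batch, feature_enrichment_batch, motif_peakset, read_matrix_motifs, read_meme_motifs
from .overlap import proximity_peakset
from .core import anchored_window

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    input_dir: str
    output_dir: str
    motif_file: str | None = None
    clip_bed: str | None = None
    run_kmer: bool = False
    preset: str = "fus"
    expanded: bool = False
    min_support: int = 2
    enrichment_p: float | None = None
    min_peak_count: int | None = None
    min_gene_count: int | None = None
    motif_threshold: float = 0.8
    kmer_k: int = 6
    kmer_n_clusters: int = 12
    n_perm: int = 1000
    seed: int = 0
    log_level: str = "INFO"

    def cascade_config(self) -> CascadeConfig:
        cfg = CascadeConfig.expanded() if self.expanded else CascadeConfig()
        cfg.min_support = self.min_support
        if self.enrichment_p is not None:
            cfg.enrichment_p = self.enrichment_p
        if self.min_peak_count is not None:
            cfg.min_peak_count = self.min_peak_count
        if self.min_gene_count is not None:
            cfg.min_gene_count = self.min_gene_count
        return cfg


def read_sample_sheet(path) -> list[SampleInfo]:
    df = pd.read_csv(path, sep="\t")
    return [SampleInfo(str(r["name"]), str(r["assay"]), str(r["condition"]),
                       str(r["batch"]), int(r["library_size"]))
            for _, r in df.iterrows()]


@dataclass
class Experiment:
    samples: list
    per_sample_calls: dict
    count_peaks: list
    counts: object
    gene_expr: GeneExpressionTable
    genes: list
    sequences: dict = field(default_factory=dict)


def load_experiment(input_dir) -> Experiment:
    d = Path(input_dir)
    samples = read_sample_sheet(d / "samples.tsv")
    calls = {}
    for s in samples:
        if s.assay == "eprint":
            calls[s.name] = read_bed(d / f"calls_{s.name}.bed")
    peaks_bed = d / "peaks.bed"
    if not peaks_bed.exists():
        peaks_bed = d / "true_peaks.bed"
    count_peaks = read_bed(peaks_bed)
    counts = read_count_table(d / "peak_counts.tsv", samples)
    input_samples = [s for s in samples if s.assay == "input"]
    gene_counts = read_count_table(d / "gene_counts.tsv", input_samples)
    gene_expr = GeneExpressionTable(gene_counts.peak_ids, gene_counts.samples,
                                    gene_counts.counts)
    genes = read_annotation(d / "annotation.gtf")
    seqs = {}
    fasta = d / "genome.fa"
    if fasta.exists():
        seqs = read_fasta(fasta)
    return Experiment(samples, calls, count_peaks, counts, gene_expr, genes,
                      seqs)


def run_full_pipeline(config: RunConfig) -> dict:
    """Execute the full workflow; returns the manifest dictionary."""
    logging.basicConfig(level=config.log_level)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"version": __version__, "config": asdict(config),
                "stages": {}}
    stage = "load"
    try:
        exp = load_experiment(config.input_dir)

        stage = "cascade"
        sdir = out / "cascade"
        sdir.mkdir(exist_ok=True)
        ccfg = config.cascade_config()
        eprint_names = [s.name for s in exp.samples if s.assay == "eprint"]
        per_sample = [exp.per_sample_calls[n] for n in eprint_names]
        merged = merge_replicate_peaks(per_sample, ccfg.min_support,
                                       ccfg.strand_aware_merge)
        merged_counts = map_counts_to_merged(exp.count_peaks, exp.counts,
                                             merged)
        peaks, report = run_cascade(per_sample, merged_counts, exp.gene_expr,
                                    exp.genes, ccfg)
        write_bed(peaks, sdir / "filtered_peaks.bed")
        with open(sdir / "report.json", "w") as fh:
            json.dump(report.to_dict(), fh, indent=1)
        manifest["stages"]["cascade"] = report.to_dict()

        stage = "differential"
        sdir = out / "differential"
        sdir.mkdir(exist_ok=True)
        hosts = {p.peak_id: p.host_gene for p in peaks}
        model = DifferentialBindingModel(merged_counts.subset(
            [p.peak_id for p in peaks]), exp.gene_expr, hosts)
        results = model.fit()
        results.to_tsv(sdir / "differential_peaks.tsv")
        results.ranking().to_csv(sdir / "ranked_peaks.rnk", sep="\t",
                                 header=False)
        deg = deg_on_input(exp.gene_expr)
        deg.to_tsv(sdir / "input_deg.tsv")
        max_padj, min_lfc = PRESETS[config.preset]
        sig = results.significant(preset=config.preset)
        manifest["stages"]["differential"] = {
            "n_tested": int(results.frame["p"].notna().sum()),
            "n_significant": int(len(sig)),
            "preset": config.preset,
            "max_padj": max_padj, "min_abs_log2fc": min_lfc,
        }

        stage = "annotation"
        sdir = out / "annotation"
        sdir.mkdir(exist_ok=True)
        cats = classify_peaks(peaks, exp.genes)
        pd.Series({k: str(v) for k, v in cats.items()}).rename(
            "category").to_csv(sdir / "peak_categories.tsv", sep="\t")
        dens = feature_density(peaks, exp.genes)
        pd.Series({str(k): v for k, v in dens.items()}).rename(
            "peaks_per_100kb").to_csv(sdir / "feature_density.tsv", sep="\t")
        manifest["stages"]["annotation"] = {
            "categories": {str(c): sum(1 for v in cats.values() if v == c)
                           for c in set(cats.values())}}

        ranked = results.ranking()
        if config.motif_file and exp.sequences:
            stage = "motif"
            sdir = out / "motif"
            sdir.mkdir(exist_ok=True)
            path = Path(config.motif_file)
            motifs = (read_meme_motifs(path) if path.suffix == ".meme"
                      else read_matrix_motifs(path))
            peaksets = [motif_peakset(m, peaks, exp.sequences,
                                      threshold=config.motif_threshold)
                        for m in motifs]
            peaksets = [ps for ps in peaksets
                        if 0 < len(ps.peak_ids & set(ranked.index))
                        < len(ranked)]
            gsea = gsea_batch(ranked, peaksets, n_perm=config.n_perm,
                              seed=config.seed)
            gsea.to_csv(sdir / "motif_gsea.tsv", sep="\t", index=False)
            fenr = feature_enrichment_batch(peaksets, cats)
            fenr.to_csv(sdir / "feature_enrichment.tsv", sep="\t",
                        index=False)
            manifest["stages"]["motif"] = {"n_motifs": len(motifs),
                                           "n_tested_sets": len(peaksets)}

        if config.clip_bed:
            stage = "overlap"
            sdir = out / "overlap"
            sdir.mkdir(exist_ok=True)
            clip = read_bed(config.clip_bed)
            ps = proximity_peakset(peaks, clip)
            gsea = gsea_batch(ranked, [ps], n_perm=config.n_perm,
                              seed=config.seed)
            gsea.to_csv(sdir / "clip_gsea.tsv", sep="\t", index=False)
            manifest["stages"]["overlap"] = {
                "n_clip_sites": len(clip),
                "n_proximal_peaks": len(ps.peak_ids)}

        if config.run_kmer and exp.sequences:
            stage = "kmer"
            sdir = out / "kmer"
            sdir.mkdir(exist_ok=True)
            seq_of = {p.peak_id: anchored_window(p, exp.sequences, 25)
                      for p in peaks}
            km = kmer_presence(seq_of, k=config.kmer_k)
            n_clusters = min(config.kmer_n_clusters, len(km.peak_ids))
            labels = cluster_peaks(km, n_clusters=n_clusters)
            pd.Series(labels, index=km.peak_ids).rename("cluster").to_csv(
                sdir / "clusters.tsv", sep="\t")
            enr = cluster_kmer_enrichment(km, labels)
            enr.to_csv(sdir / "kmer_enrichment.tsv", sep="\t", index=False)
            manifest["stages"]["kmer"] = {"n_clusters": int(n_clusters),
                                          "n_enrichment_tests": len(enr)}

        stage = "manifest"
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1)
    except Exception:
        (out / ".partial").write_text(f"failed at stage: {stage}\n")
        raise
    return manifest
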