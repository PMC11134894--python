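# eprint-tools

Analysis toolkit for **ePRINT**-style global protein–RNA interaction
mapping. ePRINT captures the footprints of all expressed RNA-binding
proteins (RBPs) at once: a 5'→3' exonuclease (XRN1) digests RNA up to each
protein–RNA crosslink, so the **5' end of a peak marks the footprint start
of the bound protein**. Comparing two cellular states then yields, in a
single experiment, which binding events change, which RBPs drive those
changes, and which downstream genes respond.

The package is aimed at computational biologists who have per-sample peak
calls (from CLIPper or any peak caller), per-peak read counts for the
footprint and size-matched input libraries, and a gene annotation. It
provides:

* **Peak cascade** — merge peaks across replicates (≥ 2 samples), keep
  intragenic peaks, test enrichment over the size-matched input (one-sided
  binomial against the library-size proportion, p < 0.001), and filter on
  cumulative peak counts (≥ 50) and host-gene input expression (≥ 50).
* **Differential binding** — a negative-binomial GLM per peak,
  `K_pj ~ NB(mu_pj, alpha_p)` with
  `log mu_pj = o_pj + x_j' beta_p`, where the per-peak, per-sample offset
  `o_pj = log s_j + log E_{g(p),j}` carries the size factor and the
  host-gene expression measured in the matched input library. The
  condition coefficient is therefore the change in peak amplitude *beyond*
  the change in host-gene expression. Wald tests with Benjamini–Hochberg
  correction; the signed Wald statistic ranks peaks from most enhanced to
  most reduced.
* **Feature annotation** — classify each peak by where its strand-aware
  start and end sites fall (5'UTR / exon / intron / 3'UTR and the junction
  categories EX_IN, IN_EX, EX_EX, IN_IN), peak densities per 100 kb of
  feature, and matched random peak backgrounds.
* **Motif activity** — PWM scanning with relative log-odds scores in
  [0, 1] (threshold 0.8), positional z-profiles in a 200-bp window around
  peak starts, motif peaksets from a 50-bp window, directional preranked
  GSEA of each motif's peakset over the ranked peak list, and
  hypergeometric feature enrichment/depletion per motif.
* **Overlap & networks** — CLIP-proximity peaksets (within 200 bp),
  gene-level hypergeometric overlap with UP/DOWN/UP-only/DOWN-only groups,
  and layered root-RBP → downstream-RBP → gene regulatory networks with a
  random-gene null simulation.
* **K-mer discovery** — 6-mer presence matrices, average-linkage Jaccard
  clustering of differential peaks, per-cluster hypergeometric k-mer
  enrichment, known/unknown partition against a motif database, and GSEA
  re-assessment of unknown k-mers.
* **Synthetic experiments** — a seeded generator of complete experiments
  (genome, annotation, per-sample calls, NB counts, ground truth) so every
  stage is testable without downloads.

## Worked example

Simulate a small two-condition experiment and run the cascade and the
differential model:

```sh
eprint-tools simulate --preset tiny --seed 11 --out demo
eprint-tools cascade --input-dir demo --out demo_out
```

The cascade report counts survivors of each stage (104 per-sample calls →
24 replicate-supported merged peaks, all of which here are intragenic,
input-enriched and well covered):

```
{
 "n_initial": 104,
 "n_merged": 24,
 "n_intragenic": 24,
 "n_input_enriched": 24,
 "n_count_filtered": 24,
 "n_final": 24,
 ...
}
```

From Python, fit the differential binding model on the filtered peaks:

```python
from eprint_tools import DifferentialBindingModel, merge_replicate_peaks, run_cascade
from eprint_tools.cascade import map_counts_to_merged
from eprint_tools.pipeline import load_experiment

exp = load_experiment("demo")
calls = [exp.per_sample_calls[s.name] for s in exp.samples if s.assay == "eprint"]
merged = merge_replicate_peaks(calls, min_support=2)
counts = map_counts_to_merged(exp.count_peaks, exp.counts, merged)
peaks, report = run_cascade(calls, counts, exp.gene_expr, exp.genes)

hosts = {p.peak_id: p.host_gene for p in peaks}
model = DifferentialBindingModel(counts.subset(list(hosts)), exp.gene_expr, hosts)
results = model.fit()
print(results.summary())
```

```
Differential binding (NB GLM, Wald test)
============================================
condition:          treat vs reference
samples:            4
peaks tested:       24 / 24
padj < 0.05:        2 (0 enhanced, 2 reduced)
median dispersion:  0.1145
host-gene offsets:  yes
```

`results.frame` holds the per-peak table; for example peak_000003 has
log2FC −1.58 (SE 0.52), Wald −3.03, p = 0.0024, padj = 0.045 — a binding
event reduced about three-fold after knockdown, beyond any change in its
host gene's expression. `results.ranking()` gives the signed-Wald ranked
list consumed by the motif GSEA (`eprint-tools motif-gsea`), CLIP overlap
(`overlap`) and k-mer (`kmer`) subcommands; `run-all` chains every stage
and writes a manifest.

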