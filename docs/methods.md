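# Methods

This note documents the statistical models, conventions and defaults
implemented in `eprint_tools`, the design choices made where more than one
reasonable option existed, and what the synthetic-data tests do and do not
demonstrate.

## Coordinates and conventions

All intervals are 0-based half-open (BED convention) internally; GTF-style
annotation is converted on read (start − 1). Overlap means ≥ 1 shared base
on the same chromosome; strand-aware operations additionally require equal
strand, because the footprinting libraries are stranded. The **peak start**
(5' anchor) is `interval.start` on the plus strand and `interval.end − 1`
on the minus strand: the exonuclease digests 5'→3' and halts at the
crosslink, so the strand-aware 5' end is the biologically meaningful
coordinate. Distance between intervals follows the bedtools convention:
0 when overlapping, 1 for book-ended intervals, otherwise one more than the
number of bases strictly between. "Within 200 bp" is therefore
`distance ≤ 200`, and a proximity search with `max_gap=0` degenerates to
exact strand-aware overlap.

The annotation dialect is a minimal GTF subset (feature types `gene`,
`exon`, `five_prime_utr`, `three_prime_utr`; attribute `gene_id`). Introns
are always derived as inter-exon gaps, never read. Multi-transcript genes
are expected to be flattened by the caller to one feature set per gene
(e.g. the longest transcript); the classifier is deterministic given that
flattening.

## The filtering cascade

Stages, in order, with defaults:

1. **Merge** (`min_support = 2`): per-sample calls that transitively
   overlap (strand-aware) form one merged peak whose interval is the union
   envelope; it is kept when calls from ≥ 2 distinct samples participate.
   The merged peak's anchor is the anchor of the union interval.
2. **Intragenic**: a peak is intragenic when it overlaps a gene span on
   the same strand; ties between hosts are broken by maximal bp overlap,
   then lexicographic gene id. Intergenic peaks stay in the peak universe
   but are excluded from differential analysis (their amplitude cannot be
   normalised to a host gene).
3. **Input enrichment** (`p < 0.001`; the relaxed preset uses 0.01): with
   x = summed footprint count, n = x + summed input count and
   p0 = lib_fp / (lib_fp + lib_in), the peak is kept when the one-sided
   binomial upper tail P[X ≥ x] falls below the threshold. The binomial
   form was chosen because it is depth-aware, exact at low counts, and
   matches the "enriched relative to the size-matched input" semantics;
   counts are pooled across replicates (the downstream count filters are
   cumulative, so sum semantics are used consistently). A per-replicate
   paired variant would be a straightforward config extension.
4. **Peak amplitude**: cumulative footprint count ≥ 50.
5. **Host expression**: cumulative input count of the host gene ≥ 50; a
   host gene missing from the expression table fails this filter and is
   logged.

On a null simulation (footprint and input drawn from identical Poisson
rates, equal libraries) the binomial test passes p < 0.001 in well under
0.5% of peaks, so stage 3 controls its error rate conservatively.

## Differential binding model

Counts for peak p in footprint sample j follow a negative binomial,

    K_pj ~ NB(mu_pj, alpha_p),   log mu_pj = o_pj + x_j' beta_p,

with design `x_j` = intercept + condition indicator (+ batch indicators
when more than one batch is present; a batch perfectly confounded with
condition raises a rank error). The reference condition is the
lexicographically first level unless configured.

**Host-gene expression enters as an offset, not a design column.** A
covariate that differs per peak *and* per sample cannot occupy a shared
design matrix; the standard mechanism for exactly this situation is a
matrix of gene-specific normalisation factors, i.e. per-observation log
offsets:

    o_pj = log s_j + log max(E_{g(p), m(j)}, 0.5)

where `s_j` are median-of-ratios size factors of the footprint counts,
`E_gm` is the host gene's input count normalised by the input libraries'
own size factors, and `m(j)` matches footprint sample j to its input
library by (condition, batch, replicate order). The pseudocount floor of
0.5 keeps offsets finite for host genes that drop to zero in one library.
Under this parameterisation the condition coefficient estimates the change
in binding per unit of host-gene expression: a peak whose amplitude merely
tracks a two-fold expression shift gets log2FC ≈ 0. Whether the original
formulation used normalisation-factor matrices or another mechanism is not
determinable from its description; the offset interpretation reproduces the
stated semantics and is documented as this package's choice.

**Dispersion** is estimated per peak by moment matching: with Poisson
fitted means `mu_j` (same design and offsets), `alpha` solves

    sum_j (y_j − mu_j)^2 / (mu_j + alpha mu_j^2) = n − p,

a Pearson-statistic match with a degrees-of-freedom correction (solved by
bisection; `alpha = 0` when even the Poisson over-fits). Raw estimates are
then shrunk 50/50 toward a mean-dispersion trend `a0 + a1/mu` fitted by
least squares across peaks, and clamped to [1e−8, 10]. All-zero peaks take
the trend value and are flagged. This is a deliberate simplification of
empirical-Bayes shrinkage: with thousands of peaks the trend is accurate,
and the equal-weight blend keeps per-peak noise in check at 2 + 2
replicates. It is an approximation, and the small residual
anti-conservativeness of the Wald test at four samples (type-I error
≈ 0.055–0.07 at nominal 0.05 in the null simulations) is inherited from
the plug-in dispersion.

**Fitting** is Fisher-scoring IRLS with fixed dispersion (weights
`mu/(1 + alpha mu)`), initialised from a least-squares fit to
`log max(y, 0.5) − offset`, converged at max |Δβ| < 1e−8 or 100
iterations; linear predictors are clipped at ±30 to avoid overflow.
Non-converged or degenerate fits yield NA p-values and are flagged rather
than dropped silently. Wald p-values are two-sided normal on the condition
coefficient; BH adjustment runs over all tested peaks (no independent
filtering, no fold-change shrinkage). The ranked list uses the signed Wald
statistic with peak-id tie-break, giving a strict total order.

Significance presets: `fus` (padj < 0.05, |log2FC| > 1) and `mn`
(padj < 0.01, fold change 2). Gene-level differential expression on the
input libraries (`deg_on_input`) reuses the same machinery with
size-factor-only offsets.

## Feature classification and densities

Start and end sites are taken in transcription orientation (start = 5'
anchor), so EX_IN (start exon, end intron) is meaningful on both strands.
A site exactly on an exon/intron boundary is exonic (half-open tiling), a
site in UTR base pairs takes the UTR label (UTR is exonic sequence; the
more specific label wins), and the four single-feature categories require
both sites in the *same* feature instance — otherwise the pair of site
types yields EX_EX, IN_IN, EX_IN or IN_EX, with UTR sites counting as
exonic in the mixed cases. Peaks overhanging their host gene's span are
clamped to the terminal bases. Densities are peaks per 100 kb of feature,
with UTR base pairs excluded from the exon class so the four classes
partition exonic+intronic space; only single-feature peaks are counted.
Random backgrounds draw, per feature class, a multiple (default 10×) of
the observed peak count uniformly within that class's intervals with
lengths resampled from the observed per-class length distribution;
infeasible draws are retried up to 100 times, then truncated.

## Motif scanning and activity

PWM match scores are **relative log-odds**: the log2 likelihood ratio
against the background (probabilities floored at 1e−3), rescaled between
the minimum and maximum attainable scores so 1 is the consensus and 0 the
anti-consensus; the hit threshold is 0.8. Base-2 logs and a uniform
background are defaults (both configurable — the original tooling's
choices are not stated). Ambiguous bases contribute 0 (score-neutral).
Scanning is on the peak's strand in transcription orientation only, since
the footprinted molecule is single-stranded RNA; U is mapped to T at load
so RNA-alphabet motifs (e.g. Transite-style matrices) apply directly to
DNA sequence, and plain k-mers become degenerate 0.97/0.01 PWMs so k-mer
motif lists share the code path.

Positional profiles scan motif start offsets −100..+100 relative to the
anchor (a 200-bp window), average the per-offset scores across peaks, and
z-score **across offsets** (the alternative reading — z across motifs —
is noted as ambiguous in the source description; across-offset
normalisation is what makes a single motif's profile interpretable).
Motif peaksets use a 50-bp window (offsets −25..+25) and max-over-window ≥
threshold. Windows at contig edges are N-padded (neutral).

**Directional GSEA** is classic preranked enrichment: weighted
Kolmogorov–Smirnov running sum with weight exponent 1 (|signed Wald|), ES
the signed extremum. The null permutes peakset membership (random
same-size sets), not ranks. The p-value is one-sided among same-sign null
scores with a +1 floor, and NES divides ES by the mean |null ES| of the
same sign — the standard preranked convention. BH runs across all motifs
tested together. Results are bit-reproducible for a fixed seed. Permutation
resolution bounds attainable p-values at 1/(n_perm + 1); analyses that BH
many peaksets should use ≥ 1000 permutations.

Per-motif feature enrichment is hypergeometric per category (upper tail
for enrichment, lower for depletion) with BH within the motif × category
grid.

## Overlap, networks, k-mers

CLIP-proximity peaksets take peaks within 200 bp (inclusive, edge-to-edge
distance as defined above) of any same-strand CLIP site. Gene-level
overlap conditions on the tested universe — genes hosting ≥ 1 tested
peak — and reports hypergeometric upper-tail p and fold enrichment
(observed/expected) for UP, DOWN, UP-only and DOWN-only groups, where the
"-only" groups drop genes with significant peaks in both directions.

The regulatory network has two layers: root → RBP edges for RBPs with
significantly changed motif activity that are themselves direct CLIP
targets of the root, and RBP → gene edges for differentially expressed
genes among each RBP's targets (targets supplied by a pluggable
`target_caller`: CLIP peak sets, motif-carrying differential peaks, or
k-mer carriers). The random-gene null redraws the DEG set (default 53
genes, matching the design it emulates) without replacement and rebuilds
the network per draw; the empirical p uses a +1 correction.

K-mer analysis reduces "alignment against all 6-mers" to exact-substring
presence: for k = 6 against peak-length sequences a local alignment
saturates its maximal score exactly when the k-mer occurs verbatim, and
the clustering consumes the binarised matrix anyway. Peaks are clustered
by average-linkage hierarchical clustering on Jaccard distance between
presence rows (enhanced and reduced sets separately), cut at a configured
cluster count (default 12) or dendrogram height; the linkage is
deterministic. Per-cluster k-mer enrichment is hypergeometric against all
analysed peaks, BH-corrected across the whole cluster × k-mer grid
(conservative single family), skipping k-mers carried by < 5 peaks.
Enriched k-mers are "known" when their best full-overlap alignment against
any database PWM (shorter sequence slid along the longer, rescaled to the
covered columns) reaches the 0.8 threshold; unknown k-mers are re-assessed
by carrier-peakset GSEA.

## Synthetic experiments

The generator emulates the statistical structure the analysis assumes, in
one RNG stream per bundle (same seed → byte-identical output):

* genes with valid exon/intron/UTR structure on both strands over i.i.d.
  uniform sequence; UTRs carved from terminal exons;
* gene expression levels lognormal (σ = 0.5) around a mean input count of
  200 with NB noise (dispersion 0.05), optionally shifted ×2 in the
  second condition for a chosen fraction of genes;
* peak counts NB(mean = size factor × host expression × binding activity,
  dispersion 0.1 by default) with binding activity lognormal (σ = 0.5)
  around a mean count of 150, and planted log2 fold changes on a chosen
  fraction of peaks (balanced up/down by default — one-directional
  planting would contaminate median-of-ratios normalisation, which is a
  real phenomenon but not the property under test);
* per-sample peak calls jittered ±10 bp with 10% dropout, so
  replicate-support filtering is exercised;
* motif consensus sequences written into the genome at peak anchors
  (per-base mutation rate 0.05 by default) — overlapping peaks may
  occasionally clobber one another's planted word;
* the default design is two conditions × two replicates for both assays
  (four footprint + four input libraries), mirroring the scale of the
  experiments it emulates.

Named presets: `tiny` (end-to-end smoke runs), `null` (5,000 peaks, no
effects anywhere — calibration), `confounded` (40% of genes shifted ×2 in
one condition, binding unchanged, dispersion 0.05 — the
offset-normalisation contrast; 40% keeps the size-factor median anchored
on unshifted genes so the contrast isolates the offsets), `planted_motif`
(consensus at 90% of anchors), `planted_network`. Separate helpers
generate planted k-mer families (two families of 200 sequences, three
12-nt block insertions each) and a planted two-layer network over a
200-gene universe.

What the synthetic data does **not** emulate: read-level artifacts
(PCR duplicates, mappability, soft-clipping), crosslink-induced mutations,
non-uniform background composition, isoform structure, correlated peaks
within a gene, or realistic motif co-occurrence. Passing tests therefore
demonstrate correctness of the statistical machinery under its own
assumptions, not robustness to every artifact of real libraries.

## Problem sizes and numerical defaults

The test and reproduction runs use: 5,000 null peaks and 2,000 confounded
peaks for calibration contrasts, 500 planted-effect peaks among 2,500,
500 motif windows with 100 null repetitions, 2,000 ranked peaks with 20
decoy peaksets at 2,000 permutations, 200 k-mer family sequences, and
500 network null draws — sizes at which the measured properties (SE of a
proportion at 5,000 ≈ 0.003) are informative while a full run stays under
a minute per check. Key numeric constants: PWM probability floor 1e−3,
expression pseudocount 0.5, dispersion clamps [1e−8, 10], IRLS tolerance
1e−8 / 100 iterations, linear-predictor clip ±30.

## Known limitations

* Dispersion shrinkage is a fixed 50/50 blend, not empirical Bayes; Wald
  tests at two replicates per condition run slightly hot (see above).
  Outlier handling (Cook's-style) is not implemented.
* The input-enrichment test pools replicates; strong replicate imbalance
  is better served by the (unimplemented) paired variant.
* Motif hit thresholds are global (0.8); per-motif thresholds calibrated
  on background score distributions would detect low-information motifs
  more accurately.
* The k-mer clustering cut (count or height) is a user choice; no
  automatic model selection is attempted.
* Gene models are single-isoform; UTR precedence and longest-transcript
  flattening are conventions, not inferences.
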