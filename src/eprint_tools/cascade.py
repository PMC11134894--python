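"""High-confidence peak filtering cascade.

Per-sample peak calls are merged across replicates (transitive genomic
overlap, strand-aware), restricted to intragenic peaks, filtered for
enrichment over the size-matched input, and finally filtered on cumulative
peak counts and on host-gene expression in the input libraries.  Each stage's
survivor count is recorded in a :class:`CascadeReport`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
from intervaltree import IntervalTree
from scipy import stats

from .core import CountTable, GeneExpressionTable, GeneModel, GenomicInterval, Peak

logger = logging.getLogger(__name__)


@dataclass
class CascadeConfig:
    """Thresholds for the filtering cascade.

    Defaults are the stringent preset: input-enrichment p < 0.001, minimum
    cumulative peak count 50 across the footprint samples, minimum cumulative
    input count 50 for the host gene.  ``expanded()`` relaxes input filtering
    to p < 0.01 (the relaxed upstream peak-caller threshold is applied by the
    caller, whose per-sample calls are this cascade's input).
    """

    min_support: int = 2
    enrichment_p: float = 0.001
    min_peak_count: int = 50
    min_gene_count: int = 50
    strand_aware_merge: bool = True

    @classmethod
    def expanded(cls) -> "CascadeConfig":
        return cls(enrichment_p=0.01)


@dataclass
class CascadeReport:
    n_initial: int = 0
    n_merged: int = 0
    n_intragenic: int = 0
    n_input_enriched: int = 0
    n_count_filtered: int = 0
    n_final: int = 0
    thresholds: dict = field(default_factory=dict)

    def validate(self) -> None:
        stages = [self.n_merged, self.n_intragenic, self.n_input_enriched,
                  self.n_count_filtered, self.n_final]
        for a, b in zip(stages, stages[1:]):
            if b > a:
                raise ValueError(f"cascade counts not monotone: {stages}")

    def to_dict(self) -> dict:
        return asdict(self)


def merge_replicate_peaks(per_sample_peaks: list[list[Peak]],
                          min_support: int = 2,
                          strand_aware: bool = True) -> list[Peak]:
    """Merge transitively overlapping per-sample peaks into union intervals.

    A merged peak is retained when calls from at least ``min_support``
    distinct samples participate in its connected overlap component.  The
    merged interval is the union envelope; support is the number of distinct
    contributing samples.
    """
    n_samples = len(per_sample_peaks)
    if min_support > n_samples:
        raise ValueError(f"min_support={min_support} exceeds number of "
                         f"samples ({n_samples})")
    records = []  # (chrom, strandkey, start, end, sample_idx)
    for si, peaks in enumerate(per_sample_peaks):
        for p in peaks:
            key = (p.interval.chrom,
                   p.interval.strand if strand_aware else ".")
            records.append((key, p.interval.start, p.interval.end, si,
                            p.interval.strand))
    by_key: dict = {}
    for key, s, e, si, strand in records:
        by_key.setdefault(key, []).append((s, e, si, strand))

    merged: list[Peak] = []
    for key in sorted(by_key):
        items = sorted(by_key[key])
        # sweep: transitively overlapping intervals form one component
        cur_s, cur_e, cur_samples, strands = None, None, set(), set()
        components = []
        for s, e, si, strand in items:
            if cur_s is None:
                cur_s, cur_e, cur_samples, strands = s, e, {si}, {strand}
            elif s < cur_e:
                cur_e = max(cur_e, e)
                cur_samples.add(si)
                strands.add(strand)
            else:
                components.append((cur_s, cur_e, cur_samples, strands))
                cur_s, cur_e, cur_samples, strands = s, e, {si}, {strand}
        if cur_s is not None:
            components.append((cur_s, cur_e, cur_samples, strands))
        chrom = key[0]
        for s, e, samples, strands in components:
            if len(samples) < min_support:
                continue
            strand = key[1] if strand_aware else sorted(strands)[0]
            merged.append(Peak(GenomicInterval(chrom, s, e, strand),
                               peak_id="", support=len(samples)))
    merged.sort(key=lambda p: (p.interval.chrom, p.interval.start,
                               p.interval.end, p.interval.strand))
    for i, p in enumerate(merged, 1):
        p.peak_id = f"peak_{i:06d}"
    return merged


def assign_host_gene(peaks: list[Peak], genes: list[GeneModel]
                     ) -> tuple[list[Peak], list[Peak]]:
    """Assign host genes by strand-aware gene-span overlap.

    Returns (all peaks with host_gene set where applicable, intragenic
    subset).  Ties are broken by maximal bp overlap, then lexicographic
    gene_id, so assignment is deterministic.
    """
    trees: dict[tuple[str, str], IntervalTree] = {}
    for g in genes:
        span = g.gene_span
        trees.setdefault((g.chrom, g.strand), IntervalTree()).addi(
            span.start, span.end, g)
    intragenic = []
    for p in peaks:
        tree = trees.get((p.interval.chrom, p.interval.strand))
        best = None
        if tree is not None:
            hits = tree.overlap(p.interval.start, p.interval.end)
            scored = sorted(
                ((-p.interval.overlap_length(h.data.gene_span),
                  h.data.gene_id) for h in hits))
            if scored:
                best = scored[0][1]
        p.host_gene = best
        if best is not None:
            intragenic.append(p)
    return peaks, intragenic


def input_enrichment_test(eprint_count: int, input_count: int,
                          lib_eprint: float, lib_input: float) -> float:
    """One-sided binomial test for enrichment over the size-matched input.

    With x = footprint count and n = footprint + input count, tests
    X ~ Binomial(n, p0) with p0 = lib_eprint / (lib_eprint + lib_input)
    against the upper tail: returns P[X >= x].  n = 0 gives p = 1.
    """
    if lib_eprint <= 0 or lib_input <= 0:
        raise ValueError("library sizes must be positive")
    x = int(eprint_count)
    n = x + int(input_count)
    if n == 0:
        return 1.0
    p0 = lib_eprint / (lib_eprint + lib_input)
    return float(stats.binom.sf(x - 1, n, p0))


def map_counts_to_merged(count_peaks: list[Peak], counts: CountTable,
                         merged: list[Peak]) -> CountTable:
    """Re-key a count table onto merged peaks: each merged peak receives the
    summed counts of the count-table peaks it overlaps (strand-aware).

    This is the counting step that would re-count reads inside merged
    intervals in a real experiment."""
    trees: dict = {}
    row_of = {p: i for i, p in enumerate(counts.peak_ids)}
    for p in count_peaks:
        iv = p.interval
        trees.setdefault((iv.chrom, iv.strand), IntervalTree()).addi(
            iv.start, iv.end, p.peak_id)
    mat = np.zeros((len(merged), len(counts.samples)), dtype=np.int64)
    for i, mp in enumerate(merged):
        iv = mp.interval
        tree = trees.get((iv.chrom, iv.strand))
        if tree is None:
            continue
        for hit in tree.overlap(iv.start, iv.end):
            mat[i] += counts.counts[row_of[hit.data]]
    return CountTable([p.peak_id for p in merged], counts.samples, mat)


def run_cascade(per_sample_peaks: list[list[Peak]],
                counts: CountTable,
                gene_expr: GeneExpressionTable,
                genes: list[GeneModel],
                config: CascadeConfig | None = None
                ) -> tuple[list[Peak], CascadeReport]:
    """Run merge -> intragenic -> input enrichment -> count filters.

    ``counts`` must cover both footprint and input samples and be indexed by
    the merged peak ids (peak_000001, ... in sorted genomic order, as produced
    by :func:`merge_replicate_peaks` on the same input).  Peaks whose host
    gene is missing from ``gene_expr`` fail the expression filter and are
    logged.
    """
    config = config or CascadeConfig()
    report = CascadeReport(thresholds={
        "min_support": config.min_support,
        "enrichment_p": config.enrichment_p,
        "min_peak_count": config.min_peak_count,
        "min_gene_count": config.min_gene_count,
    })
    report.n_initial = sum(len(s) for s in per_sample_peaks)

    merged = merge_replicate_peaks(per_sample_peaks, config.min_support,
                                   config.strand_aware_merge)
    report.n_merged = len(merged)

    _, intragenic = assign_host_gene(merged, genes)
    report.n_intragenic = len(intragenic)

    ep_cols = [j for j, s in enumerate(counts.samples) if s.assay == "eprint"]
    in_cols = [j for j, s in enumerate(counts.samples) if s.assay == "input"]
    lib_ep = sum(counts.samples[j].library_size for j in ep_cols)
    lib_in = sum(counts.samples[j].library_size for j in in_cols)
    row_of = {pid: i for i, pid in enumerate(counts.peak_ids)}

    enriched = []
    for p in intragenic:
        row = counts.counts[row_of[p.peak_id], :]
        x = int(row[ep_cols].sum())
        y = int(row[in_cols].sum())
        if input_enrichment_test(x, y, lib_ep, lib_in) < config.enrichment_p:
            enriched.append(p)
    report.n_input_enriched = len(enriched)

    count_ok = []
    for p in enriched:
        row = counts.counts[row_of[p.peak_id], :]
        if int(row[ep_cols].sum()) >= config.min_peak_count:
            count_ok.append(p)
    report.n_count_filtered = len(count_ok)

    gene_row = {g: i for i, g in enumerate(gene_expr.gene_ids)}
    final = []
    for p in count_ok:
        i = gene_row.get(p.host_gene)
        if i is None:
            logger.warning("peak %s: host gene %s missing from input "
                           "expression; fails expression filter",
                           p.peak_id, p.host_gene)
            continue
        if int(gene_expr.counts[i, :].sum()) >= config.min_gene_count:
            final.append(p)
    report.n_final = len(final)
    report.validate()
    return final, report
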