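"""Classify peaks by the gene features their start and end sites fall in,
compute per-feature peak densities, and draw matched random backgrounds.

"Start" and "end" sites are strand-orientated: the start is the 5' anchor
(where the exonuclease halted) and the end is the opposite extremity, so a
junction category like EX_IN (start in exon, end in intron) is meaningful on
the minus strand.  A site exactly on an exon/intron boundary is exonic
(half-open tiling); a site in UTR base pairs takes the more specific UTR
label over the plain exon label.
"""

from __future__ import annotations

from enum import Enum

import numpy as np

from .core import GeneModel, GenomicInterval, Peak


class FeatureCategory(str, Enum):
    __str__ = str.__str__

    UTR5 = "UTR5"
    EX = "EX"
    IN = "IN"
    UTR3 = "UTR3"
    EX_EX = "EX_EX"
    EX_IN = "EX_IN"
    IN_EX = "IN_EX"
    IN_IN = "IN_IN"
    INTERGENIC = "INTERGENIC"


#: within-one-feature categories used for density calculations
PURE_CATEGORIES = (FeatureCategory.UTR5, FeatureCategory.EX,
                   FeatureCategory.IN, FeatureCategory.UTR3)


def _site_location(pos: int, gene: GeneModel) -> tuple[str, int, bool, bool]:
    """(exon|intron, instance index, in_utr5, in_utr3) for a genomic bp.

    Positions outside the gene span are clamped to its terminal bases (a
    peak may overhang its host gene slightly)."""
    span = gene.gene_span
    pos = min(max(pos, span.start), span.end - 1)
    in5 = any(s <= pos < e for s, e in gene.utr5)
    in3 = any(s <= pos < e for s, e in gene.utr3)
    for i, (s, e) in enumerate(gene.exons):
        if s <= pos < e:
            return "exon", i, in5, in3
    for i, (s, e) in enumerate(gene.introns):
        if s <= pos < e:
            return "intron", i, False, False
    # unreachable for clamped positions (exons/introns tile the span)
    raise AssertionError(f"position {pos} not covered by gene {gene.gene_id}")


def classify_peak(peak: Peak, gene: GeneModel | None) -> FeatureCategory:
    """Assign the single feature category of a peak.

    Both sites in the same UTR -> UTR5/UTR3; both in the same exon/intron
    instance -> EX/IN; otherwise a junction/spanning category from the pair
    of site types (UTR bp count as exonic for the mixed categories)."""
    if gene is None:
        return FeatureCategory.INTERGENIC
    start = _site_location(peak.five_prime_anchor, gene)
    end = _site_location(peak.three_prime_end, gene)
    if start[2] and end[2]:
        return FeatureCategory.UTR5
    if start[3] and end[3]:
        return FeatureCategory.UTR3
    s_kind, s_idx = start[0], start[1]
    e_kind, e_idx = end[0], end[1]
    if s_kind == "exon" and e_kind == "exon":
        return FeatureCategory.EX if s_idx == e_idx else FeatureCategory.EX_EX
    if s_kind == "intron" and e_kind == "intron":
        return FeatureCategory.IN if s_idx == e_idx else FeatureCategory.IN_IN
    if s_kind == "exon":
        return FeatureCategory.EX_IN
    return FeatureCategory.IN_EX


def classify_peaks(peaks: list[Peak], genes: list[GeneModel]
                   ) -> dict[str, FeatureCategory]:
    by_id = {g.gene_id: g for g in genes}
    return {p.peak_id: classify_peak(p, by_id.get(p.host_gene))
            for p in peaks}


def feature_lengths(genes: list[GeneModel]) -> dict[FeatureCategory, int]:
    """Total bp per feature class, with UTR bp excluded from the exon class
    (the four classes are disjoint)."""
    totals = {c: 0 for c in PURE_CATEGORIES}
    for g in genes:
        utr_bp = sum(e - s for s, e in g.utr5) + sum(e - s for s, e in g.utr3)
        exon_bp = sum(e - s for s, e in g.exons)
        totals[FeatureCategory.UTR5] += sum(e - s for s, e in g.utr5)
        totals[FeatureCategory.UTR3] += sum(e - s for s, e in g.utr3)
        totals[FeatureCategory.EX] += exon_bp - utr_bp
        totals[FeatureCategory.IN] += sum(e - s for s, e in g.introns)
    return totals


def feature_density(peaks: list[Peak], genes: list[GeneModel]
                    ) -> dict[FeatureCategory, float]:
    """Peaks per 100 kb of each feature class across the given genes.

    Only peaks lying wholly within one feature (the four pure categories)
    are counted; classes with zero total length are omitted."""
    cats = classify_peaks(peaks, genes)
    lengths = feature_lengths(genes)
    density = {}
    for c in PURE_CATEGORIES:
        if lengths[c] <= 0:
            continue
        n = sum(1 for v in cats.values() if v == c)
        density[c] = 1e5 * n / lengths[c]
    return density


def _feature_intervals(genes: list[GeneModel]
                       ) -> dict[FeatureCategory, list[tuple[str, int, int, str]]]:
    """Disjoint genomic intervals per pure feature class."""
    out = {c: [] for c in PURE_CATEGORIES}
    for g in genes:
        utrs = sorted(g.utr5 + g.utr3)
        for s, e in g.utr5:
            out[FeatureCategory.UTR5].append((g.chrom, s, e, g.strand))
        for s, e in g.utr3:
            out[FeatureCategory.UTR3].append((g.chrom, s, e, g.strand))
        for s, e in g.introns:
            out[FeatureCategory.IN].append((g.chrom, s, e, g.strand))
        for s, e in g.exons:
            # exon minus UTR pieces
            pos = s
            for us, ue in utrs:
                if ue <= s or us >= e:
                    continue
                if us > pos:
                    out[FeatureCategory.EX].append((g.chrom, pos, us, g.strand))
                pos = max(pos, ue)
            if pos < e:
                out[FeatureCategory.EX].append((g.chrom, pos, e, g.strand))
    return out


def random_peak_background(genes: list[GeneModel], template_peaks: list[Peak],
                           multiplier: int = 10, seed: int = 0) -> list[Peak]:
    """Draw a matched random background: for each feature class, multiplier
    times the observed peak count, placed uniformly within that class's
    intervals with lengths resampled from the class's observed lengths.

    A draw landing in an interval shorter than its sampled length is redrawn
    (up to 100 attempts, then truncated to the interval)."""
    if multiplier < 1:
        raise ValueError("multiplier must be >= 1")
    rng = np.random.default_rng(seed)
    cats = classify_peaks(template_peaks, genes)
    by_cat_lengths: dict[FeatureCategory, list[int]] = {c: [] for c in
                                                        PURE_CATEGORIES}
    for p in template_peaks:
        c = cats[p.peak_id]
        if c in by_cat_lengths:
            by_cat_lengths[c].append(len(p.interval))
    intervals = _feature_intervals(genes)
    out: list[Peak] = []
    idx = 0
    for c in PURE_CATEGORIES:
        lengths = by_cat_lengths[c]
        pool = intervals[c]
        if not lengths or not pool:
            continue
        weights = np.array([e - s for _, s, e, _ in pool], dtype=float)
        weights /= weights.sum()
        n_draw = multiplier * len(lengths)
        for _ in range(n_draw):
            length = int(rng.choice(lengths))
            for attempt in range(100):
                chrom, s, e, strand = pool[rng.choice(len(pool), p=weights)]
                if e - s >= length:
                    break
            else:
                length = e - s
            start = int(rng.integers(s, e - length + 1))
            idx += 1
            out.append(Peak(GenomicInterval(chrom, start, start + length,
                                            strand),
                            peak_id=f"rand_{c.value}_{idx:06d}"))
    return out
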