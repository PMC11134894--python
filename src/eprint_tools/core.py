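"""Core genomic domain types and format readers/writers.

All coordinates are 0-based half-open (BED convention) internally.  GTF-style
annotation input, which is 1-based inclusive, is converted on read.  Overlap
between intervals means at least one shared base pair on the same chromosome;
strand-aware operations additionally require equal strand (footprint libraries
are stranded).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

VALID_STRANDS = ("+", "-")


class ParseError(ValueError):
    """Raised when an input file cannot be parsed; carries the line number."""


@dataclass(frozen=True)
class GenomicInterval:
    """A stranded genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self):
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(f"end must be > start, got [{self.start}, {self.end})")
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval", strand_aware: bool = True) -> bool:
        if self.chrom != other.chrom:
            return False
        if strand_aware and self.strand != other.strand:
            return False
        return self.start < other.end and other.start < self.end

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def gap_to(self, other: "GenomicInterval") -> int:
        """Distance between intervals: 0 when overlapping, 1 for book-ended
        intervals, else 1 + the number of bp strictly between them."""
        if self.chrom != other.chrom:
            raise ValueError("gap undefined across chromosomes")
        d = max(self.start, other.start) - min(self.end, other.end)
        return max(0, d + 1) if d >= 0 else 0


@dataclass
class Peak:
    """A footprint peak: a stranded interval whose 5' end marks where the
    5'->3' exonuclease halted, i.e. the bound protein's footprint start."""

    interval: GenomicInterval
    peak_id: str
    support: int = 1
    host_gene: str | None = None

    def __post_init__(self):
        if self.support < 1:
            raise ValueError("support must be >= 1")

    @property
    def five_prime_anchor(self) -> int:
        """Strand-aware peak start: interval.start on '+', end-1 on '-'."""
        if self.interval.strand == "+":
            return self.interval.start
        return self.interval.end - 1

    @property
    def three_prime_end(self) -> int:
        """The extremity opposite the 5' anchor, in transcription orientation."""
        if self.interval.strand == "+":
            return self.interval.end - 1
        return self.interval.start


@dataclass
class GeneModel:
    """Gene structure flattened to disjoint exon/intron/UTR interval lists.

    ``exons`` and ``introns`` tile ``gene_span`` without overlap; UTR lists
    are subsets of exonic space.  Interval lists are (start, end) tuples in
    genomic coordinates, sorted by start.
    """

    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    utr5: list[tuple[int, int]] = field(default_factory=list)
    utr3: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self):
        self.exons = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 < e1:
                raise ValueError(f"gene {self.gene_id}: overlapping exons "
                                 f"[{s1},{e1}) and [{s2},{e2})")
        if not self.exons:
            raise ValueError(f"gene {self.gene_id}: no exons")
        for name, utrs in (("utr5", self.utr5), ("utr3", self.utr3)):
            for s, e in utrs:
                if not any(es <= s and e <= ee for es, ee in self.exons):
                    raise ValueError(
                        f"gene {self.gene_id}: {name} [{s},{e}) outside exonic space")

    @property
    def introns(self) -> list[tuple[int, int]]:
        """Gaps between consecutive exons."""
        return [(e1, s2) for (_, e1), (s2, _) in zip(self.exons, self.exons[1:])
                if s2 > e1]

    @property
    def gene_span(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.exons[0][0], self.exons[-1][1],
                               self.strand)


@dataclass(frozen=True)
class SampleInfo:
    name: str
    assay: str  # "eprint" or "input"
    condition: str
    batch: str = "b1"
    library_size: int = 1_000_000

    def __post_init__(self):
        if self.assay not in ("eprint", "input"):
            raise ValueError(f"assay must be 'eprint' or 'input', got {self.assay!r}")
        if self.library_size <= 0:
            raise ValueError("library_size must be > 0")


@dataclass
class CountTable:
    """Peaks x samples non-negative integer counts with sample metadata."""

    peak_ids: list[str]
    samples: list[SampleInfo]
    counts: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.peak_ids), len(self.samples)):
            raise ValueError("counts shape does not match peak_ids x samples")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if len(set(self.peak_ids)) != len(self.peak_ids):
            raise ValueError("duplicate peak_ids")
        names = [s.name for s in self.samples]
        if len(set(names)) != len(names):
            raise ValueError("duplicate sample names")

    def subset(self, peak_ids: Sequence[str]) -> "CountTable":
        idx = {p: i for i, p in enumerate(self.peak_ids)}
        rows = [idx[p] for p in peak_ids]
        return CountTable(list(peak_ids), self.samples, self.counts[rows, :])

    def select_samples(self, keep: Iterable[str]) -> "CountTable":
        keep = set(keep)
        cols = [j for j, s in enumerate(self.samples) if s.name in keep]
        return CountTable(self.peak_ids, [self.samples[j] for j in cols],
                          self.counts[:, cols])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.peak_ids,
                            columns=[s.name for s in self.samples])


@dataclass
class GeneExpressionTable:
    """Genes x input-samples integer counts (host-gene expression)."""

    gene_ids: list[str]
    samples: list[SampleInfo]
    counts: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.gene_ids), len(self.samples)):
            raise ValueError("counts shape does not match gene_ids x samples")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    def row(self, gene_id: str) -> np.ndarray:
        return self.counts[self.gene_ids.index(gene_id), :]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.gene_ids,
                            columns=[s.name for s in self.samples])


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_bed(path) -> list[Peak]:
    """Read BED6 into Peak objects (0-based half-open, preserved exactly)."""
    peaks = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ParseError(f"{path}:{lineno}: expected 6 BED columns, "
                                 f"got {len(fields)}")
            chrom, start, end, name, _score, strand = fields[:6]
            try:
                iv = GenomicInterval(chrom, int(start), int(end), strand)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            peaks.append(Peak(iv, name))
    return peaks


def write_bed(peaks: Iterable[Peak], path, score_from_support: bool = True) -> None:
    with open(path, "w") as fh:
        for p in peaks:
            score = p.support if score_from_support else 0
            fh.write(f"{p.interval.chrom}\t{p.interval.start}\t{p.interval.end}\t"
                     f"{p.peak_id}\t{score}\t{p.interval.strand}\n")


def _parse_gtf_attributes(attr: str) -> dict:
    out = {}
    for chunk in attr.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        if " " in chunk:
            key, value = chunk.split(" ", 1)
            out[key] = value.strip().strip('"')
    return out


def read_annotation(path) -> list[GeneModel]:
    """Read a minimal GTF subset (gene/exon/five_prime_utr/three_prime_utr).

    GTF 1-based inclusive coordinates are converted to 0-based half-open.
    Introns are derived as inter-exon gaps, never read.
    """
    exons: dict[str, list] = {}
    utr5: dict[str, list] = {}
    utr3: dict[str, list] = {}
    meta: dict[str, tuple[str, str]] = {}
    spans: dict[str, tuple[int, int]] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise ParseError(f"{path}:{lineno}: expected 9 GTF columns")
            chrom, _src, feat, start, end, _score, strand, _frame, attr = fields[:9]
            if feat not in ("gene", "exon", "five_prime_utr", "three_prime_utr"):
                continue
            attrs = _parse_gtf_attributes(attr)
            gid = attrs.get("gene_id")
            if gid is None:
                raise ParseError(f"{path}:{lineno}: missing gene_id attribute")
            s, e = int(start) - 1, int(end)
            if gid not in meta:
                meta[gid] = (chrom, strand)
                order.append(gid)
            if feat == "gene":
                spans[gid] = (s, e)
            elif feat == "exon":
                exons.setdefault(gid, []).append((s, e))
            elif feat == "five_prime_utr":
                utr5.setdefault(gid, []).append((s, e))
            else:
                utr3.setdefault(gid, []).append((s, e))
    genes = []
    for gid in order:
        chrom, strand = meta[gid]
        if gid not in exons:
            continue
        if gid in spans:
            gs, ge = spans[gid]
            for s, e in exons[gid]:
                if s < gs or e > ge:
                    raise ParseError(f"gene {gid}: exon [{s},{e}) outside gene "
                                     f"span [{gs},{ge})")
        genes.append(GeneModel(gid, chrom, strand, exons[gid],
                               sorted(utr5.get(gid, [])),
                               sorted(utr3.get(gid, []))))
    return genes


def write_annotation(genes: Iterable[GeneModel], path) -> None:
    """Write GeneModels back out as the minimal GTF subset (1-based inclusive)."""
    with open(path, "w") as fh:
        for g in genes:
            span = g.gene_span
            rows = [("gene", span.start, span.end)]
            rows += [("exon", s, e) for s, e in g.exons]
            rows += [("five_prime_utr", s, e) for s, e in g.utr5]
            rows += [("three_prime_utr", s, e) for s, e in g.utr3]
            for feat, s, e in rows:
                fh.write(f"{g.chrom}\teprint_tools\t{feat}\t{s + 1}\t{e}\t.\t"
                         f"{g.strand}\t.\tgene_id \"{g.gene_id}\";\n")


def write_bedgraph(coverage, library_size: float, path) -> None:
    """Write depth-normalised bedgraph: values scaled by 1e6 / library_size.

    ``coverage`` is an iterable of (chrom, start, end, value) records (possibly
    overlapping; overlaps are summed per base).  Adjacent runs of equal value
    are merged; zero-coverage runs are omitted; records sorted by chrom, start.
    """
    if library_size <= 0:
        raise ValueError("library_size must be > 0")
    scale = 1e6 / library_size
    events: dict[str, dict[int, float]] = {}
    for chrom, start, end, value in coverage:
        d = events.setdefault(chrom, {})
        d[start] = d.get(start, 0.0) + value
        d[end] = d.get(end, 0.0) - value
    with open(path, "w") as fh:
        for chrom in sorted(events):
            pos = sorted(events[chrom])
            running = 0.0
            run_start = None
            run_value = 0.0
            for i, p in enumerate(pos):
                running += events[chrom][p]
                nxt = pos[i + 1] if i + 1 < len(pos) else None
                value = running * scale
                if run_start is not None and not np.isclose(value, run_value):
                    fh.write(f"{chrom}\t{run_start}\t{p}\t{run_value:g}\n")
                    run_start = None
                if run_start is None and nxt is not None and value != 0.0:
                    run_start, run_value = p, value
            if run_start is not None and run_value != 0.0:
                fh.write(f"{chrom}\t{run_start}\t{pos[-1]}\t{run_value:g}\n")


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into {name: sequence} (uppercased), via pyfaidx."""
    from pyfaidx import Fasta

    fa = Fasta(str(path), rebuild=False)
    try:
        return {name: str(fa[name][:]).upper() for name in fa.keys()}
    finally:
        fa.close()


def write_fasta(seqs: dict[str, str], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_count_table(path, samples: list[SampleInfo]) -> CountTable:
    """Read a TSV count table (header row = sample names, first column = ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    by_name = {s.name: s for s in samples}
    missing = [c for c in df.columns if c not in by_name]
    if missing:
        raise ParseError(f"{path}: samples without metadata: {missing}")
    ordered = [by_name[c] for c in df.columns]
    return CountTable(list(df.index.astype(str)), ordered,
                      df.to_numpy(dtype=np.int64))


def revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTUacgtuNn", "TGCAAtgcaaNn"))[::-1]


def anchored_window(peak: Peak, seqs: dict[str, str], half_window: int) -> str:
    """Sequence of the window centred on the peak's 5' anchor, in transcription
    orientation (reverse-complemented on '-'), padded with N at contig edges.

    Length is always 2*half_window + 1; offset ``half_window`` is the anchor.
    """
    chrom_seq = seqs[peak.interval.chrom]
    a = peak.five_prime_anchor
    lo, hi = a - half_window, a + half_window + 1
    left_pad = max(0, -lo)
    right_pad = max(0, hi - len(chrom_seq))
    window = ("N" * left_pad
              + chrom_seq[max(0, lo):min(hi, len(chrom_seq))]
              + "N" * right_pad)
    if peak.interval.strand == "-":
        window = revcomp(window)
    return window.upper().replace("U", "T")
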