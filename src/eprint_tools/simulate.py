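"""Seeded generator of complete synthetic footprinting experiments with
known ground truth.

The generator emulates the statistical structure the analysis assumes:
negative-binomial peak and gene counts whose means factor into sample size
factor x host-gene expression x binding activity, condition effects planted
on chosen peaks (binding) or genes (expression), per-sample peak calls
jittered and dropped out around the true peaks, and motif consensus
sequences written into the genome at peak anchors.  Everything is driven by
one RNG stream per bundle, so a seed reproduces a bundle byte for byte.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .core import (CountTable, GeneExpressionTable, GeneModel,
                   GenomicInterval, Peak, SampleInfo, revcomp, write_annotation,
                   write_bed, write_fasta)

BASES = np.array(list("ACGT"))


@dataclass
class SimConfig:
    """Study conditions for a simulated experiment.

    Defaults mirror a two-replicate, two-condition knockdown design: four
    footprint and four input libraries, moderate NB dispersion (0.1 for
    peaks, 0.05 for gene expression), peak means well above the cascade's
    count filters, and +-10 bp jitter with 10% dropout on the per-sample
    peak calls."""

    seed: int
    n_genes: int = 60
    exons_per_gene: tuple = (1, 4)
    exon_length: tuple = (150, 400)
    intron_length: tuple = (200, 800)
    utr5_length: tuple = (40, 120)
    utr3_length: tuple = (80, 200)
    intergenic_length: tuple = (300, 800)
    genes_per_chrom: int = 50
    peaks_per_gene: tuple = (1, 4)
    peak_length: tuple = (30, 80)
    conditions: tuple = ("ctrl", "treat")
    n_reps: int = 2
    n_batches: int = 1
    mean_peak_count: float = 150.0
    mean_gene_count: float = 200.0
    dispersion: float = 0.1
    gene_dispersion: float = 0.05
    binding_sd: float = 0.5
    expression_sd: float = 0.5
    frac_diff_peaks: float = 0.15
    diff_log2fc: float = 1.0
    frac_diff_down: float = 0.5
    frac_shifted_genes: float = 0.0
    gene_shift_fold: float = 2.0
    call_jitter: int = 10
    call_dropout: float = 0.1
    library_size: int = 1_000_000
    planted_motif: str | None = None
    motif_rate: float = 0.0
    motif_mutation_rate: float = 0.05
    with_sequence: bool = True


@dataclass
class GroundTruth:
    true_lfc: dict = field(default_factory=dict)      # peak_id -> log2FC
    shifted_genes: list = field(default_factory=list)
    motif_peaks: list = field(default_factory=list)   # peak_ids with motif
    peak_hosts: dict = field(default_factory=dict)    # peak_id -> gene_id
    base_mean: dict = field(default_factory=dict)     # peak_id -> mean count

    @property
    def differential_peaks(self) -> dict:
        return {p: f for p, f in self.true_lfc.items() if f != 0.0}


@dataclass
class Bundle:
    config: SimConfig
    genes: list
    sequences: dict
    true_peaks: list
    per_sample_calls: dict       # eprint sample name -> list[Peak]
    samples: list                # all SampleInfo (eprint + input)
    counts: CountTable           # true peaks x all samples
    gene_expr: GeneExpressionTable
    truth: GroundTruth

    def eprint_samples(self) -> list[SampleInfo]:
        return [s for s in self.samples if s.assay == "eprint"]

    def counts_for_merged(self, merged_peaks: list[Peak]) -> CountTable:
        """Counts re-keyed to merged peak intervals: each merged peak gets
        the summed counts of the true peaks it envelops (strand-aware
        overlap).  This is the counting step that in a real experiment would
        re-count reads inside the merged intervals."""
        row_of = {p: i for i, p in enumerate(self.counts.peak_ids)}
        mat = np.zeros((len(merged_peaks), len(self.samples)), dtype=np.int64)
        for i, mp in enumerate(merged_peaks):
            for tp in self.true_peaks:
                if mp.interval.overlaps(tp.interval):
                    mat[i] += self.counts.counts[row_of[tp.peak_id]]
        return CountTable([p.peak_id for p in merged_peaks], self.samples, mat)

    def truth_for_merged(self, merged_peaks: list[Peak]) -> dict:
        """Map merged peak ids to the ground-truth id of the true peak they
        envelop (None when they merge several true peaks)."""
        out = {}
        for mp in merged_peaks:
            hits = [tp.peak_id for tp in self.true_peaks
                    if mp.interval.overlaps(tp.interval)]
            out[mp.peak_id] = hits[0] if len(hits) == 1 else None
        return out

    def write(self, out_dir, force: bool = False) -> Path:
        out = Path(out_dir)
        if out.exists() and any(out.iterdir()) and not force:
            raise FileExistsError(f"{out} exists; pass force=True to overwrite")
        out.mkdir(parents=True, exist_ok=True)
        if self.config.with_sequence:
            write_fasta(self.sequences, out / "genome.fa")
        write_annotation(self.genes, out / "annotation.gtf")
        for name, calls in self.per_sample_calls.items():
            write_bed(calls, out / f"calls_{name}.bed")
        write_bed(self.true_peaks, out / "true_peaks.bed")
        self.counts.to_frame().to_csv(out / "peak_counts.tsv", sep="\t")
        self.gene_expr.to_frame().to_csv(out / "gene_counts.tsv", sep="\t")
        with open(out / "samples.tsv", "w") as fh:
            fh.write("name\tassay\tcondition\tbatch\tlibrary_size\n")
            for s in self.samples:
                fh.write(f"{s.name}\t{s.assay}\t{s.condition}\t{s.batch}\t"
                         f"{s.library_size}\n")
        truth = {"true_lfc": self.truth.true_lfc,
                 "shifted_genes": list(self.truth.shifted_genes),
                 "motif_peaks": list(self.truth.motif_peaks),
                 "peak_hosts": self.truth.peak_hosts,
                 "base_mean": self.truth.base_mean,
                 "seed": self.config.seed}
        with open(out / "truth.json", "w") as fh:
            json.dump(truth, fh, indent=1)
        with open(out / "config.json", "w") as fh:
            json.dump(asdict(self.config), fh, indent=1)
        return out


def _rand_range(rng, lo_hi) -> int:
    lo, hi = lo_hi
    return int(rng.integers(lo, hi + 1))


def nb_draw(rng: np.random.Generator, mean, dispersion: float) -> np.ndarray:
    """NB(mu, alpha) with Var = mu + alpha mu^2 (gamma-Poisson mixture)."""
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 1e-8:
        return rng.poisson(mean)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean / shape)
    return rng.poisson(lam)


def simulate_genome(config: SimConfig, rng: np.random.Generator | None = None
                    ) -> tuple[dict, list]:
    """Random gene structures on alternating strands with i.i.d. uniform
    background sequence.  Returns ({chrom: seq}, [GeneModel])."""
    rng = rng or np.random.default_rng(config.seed)
    if config.exon_length[0] < 30:
        raise ValueError("minimum exon length must be >= 30")
    genes = []
    chrom_len: dict[str, int] = {}
    for gi in range(config.n_genes):
        chrom = f"chr{gi // config.genes_per_chrom + 1}"
        pos = chrom_len.get(chrom, 0) + _rand_range(rng, config.intergenic_length)
        strand = "+" if rng.integers(2) == 0 else "-"
        n_ex = _rand_range(rng, config.exons_per_gene)
        exons = []
        for e in range(n_ex):
            length = _rand_range(rng, config.exon_length)
            exons.append((pos, pos + length))
            pos += length
            if e < n_ex - 1:
                pos += _rand_range(rng, config.intron_length)
        u5 = _rand_range(rng, config.utr5_length)
        u3 = _rand_range(rng, config.utr3_length)
        first, last = exons[0], exons[-1]
        u5_exon, u3_exon = (first, last) if strand == "+" else (last, first)
        # UTRs are carved out of the terminal exons; keep them inside, with
        # coding space left over when the gene is single-exon
        if len(exons) == 1:
            third = (first[1] - first[0]) // 3
            u5, u3 = min(u5, third), min(u3, third)
        else:
            u5 = min(u5, (u5_exon[1] - u5_exon[0]) - 10)
            u3 = min(u3, (u3_exon[1] - u3_exon[0]) - 10)
        if strand == "+":
            utr5 = [(u5_exon[0], u5_exon[0] + u5)]
            utr3 = [(u3_exon[1] - u3, u3_exon[1])]
        else:
            utr5 = [(u5_exon[1] - u5, u5_exon[1])]
            utr3 = [(u3_exon[0], u3_exon[0] + u3)]
        genes.append(GeneModel(f"gene_{gi + 1:05d}", chrom, strand, exons,
                               utr5, utr3))
        chrom_len[chrom] = pos
    seqs = {}
    if config.with_sequence:
        for chrom, ln in chrom_len.items():
            ln += _rand_range(rng, config.intergenic_length)
            seqs[chrom] = "".join(BASES[rng.integers(0, 4, size=ln)])
    return seqs, genes


def _plant_motif(seqs: dict, peak: Peak, motif: str, mutation_rate: float,
                 rng: np.random.Generator) -> None:
    """Write the motif into the genome so it starts at the peak's 5' anchor
    in transcription orientation, with per-base mutations."""
    bases = list(motif.upper().replace("U", "T"))
    for i in range(len(bases)):
        if rng.random() < mutation_rate:
            bases[i] = str(rng.choice(BASES))
    word = "".join(bases)
    chrom = peak.interval.chrom
    seq = seqs[chrom]
    a = peak.five_prime_anchor
    if peak.interval.strand == "+":
        s, insert = a, word
    else:
        s, insert = a - len(word) + 1, revcomp(word)
    if s < 0 or s + len(insert) > len(seq):
        return
    seqs[chrom] = seq[:s] + insert + seq[s + len(insert):]


def simulate_peaks_and_counts(seqs: dict, genes: list, config: SimConfig,
                              rng: np.random.Generator | None = None
                              ) -> Bundle:
    """Plant peaks in genes and draw NB counts for footprint and input
    libraries.

    Peak counts follow NB(mean = s_j x hostExpr_gj x binding_pj, alpha) where
    hostExpr tracks the (possibly condition-shifted) gene expression that
    also generates the input counts — so differential binding and
    differential expression are controlled independently."""
    rng = rng or np.random.default_rng(config.seed + 1)
    cond_a, cond_b = config.conditions
    samples: list[SampleInfo] = []
    for assay in ("eprint", "input"):
        for cond in config.conditions:
            for r in range(config.n_reps):
                batch = f"b{(r % config.n_batches) + 1}"
                samples.append(SampleInfo(f"{assay}_{cond}_{r + 1}", assay,
                                          cond, batch, config.library_size))
    # gene expression levels and condition shifts
    gene_ids = [g.gene_id for g in genes]
    expr_level = np.exp(rng.normal(0.0, config.expression_sd, len(genes)))
    shifted = rng.random(len(genes)) < config.frac_shifted_genes
    truth = GroundTruth(shifted_genes=[g for g, s in zip(gene_ids, shifted)
                                       if s])
    # peaks
    peaks: list[Peak] = []
    peak_gene_idx: list[int] = []
    for gi, g in enumerate(genes):
        span = g.gene_span
        for _ in range(_rand_range(rng, config.peaks_per_gene)):
            length = _rand_range(rng, config.peak_length)
            if len(span) <= length + 2:
                continue
            start = int(rng.integers(span.start, span.end - length))
            pid = f"tp_{len(peaks) + 1:06d}"
            p = Peak(GenomicInterval(g.chrom, start, start + length, g.strand),
                     pid, support=1, host_gene=g.gene_id)
            peaks.append(p)
            peak_gene_idx.append(gi)
            truth.peak_hosts[pid] = g.gene_id
    n_peaks = len(peaks)
    binding = np.exp(rng.normal(0.0, config.binding_sd, n_peaks))
    is_diff = rng.random(n_peaks) < config.frac_diff_peaks
    sign = np.where(rng.random(n_peaks) < config.frac_diff_down, -1.0, 1.0)
    lfc = np.where(is_diff, sign * config.diff_log2fc, 0.0)
    for p, f in zip(peaks, lfc):
        truth.true_lfc[p.peak_id] = float(f)
    # motif planting at anchors
    if config.planted_motif and config.with_sequence:
        carry = rng.random(n_peaks) < config.motif_rate
        for p, c in zip(peaks, carry):
            if c:
                _plant_motif(seqs, p, config.planted_motif,
                             config.motif_mutation_rate, rng)
                truth.motif_peaks.append(p.peak_id)
    # per-sample size factors (mild depth variation)
    sf = np.exp(rng.normal(0.0, 0.1, len(samples)))
    # counts
    peak_counts = np.zeros((n_peaks, len(samples)), dtype=np.int64)
    gene_counts = np.zeros((len(genes), len(samples)), dtype=np.int64)
    gidx = np.asarray(peak_gene_idx)
    for j, s in enumerate(samples):
        shift = np.where(shifted & (s.condition == cond_b),
                         config.gene_shift_fold, 1.0)
        gene_mean = config.mean_gene_count * expr_level * shift * sf[j]
        gene_counts[:, j] = nb_draw(rng, gene_mean, config.gene_dispersion)
        if s.assay == "eprint":
            cond_fc = np.where(s.condition == cond_b, 2.0 ** lfc, 1.0)
            peak_mean = (config.mean_peak_count * binding * cond_fc * sf[j]
                         * expr_level[gidx] * shift[gidx])
            peak_counts[:, j] = nb_draw(rng, peak_mean, config.dispersion)
    for p, b, gi in zip(peaks, binding, peak_gene_idx):
        truth.base_mean[p.peak_id] = float(config.mean_peak_count * b
                                           * expr_level[gi])
    # per-sample peak calls: jittered with dropout
    calls: dict[str, list[Peak]] = {}
    for s in samples:
        if s.assay != "eprint":
            continue
        sample_calls = []
        for p in peaks:
            if rng.random() < config.call_dropout:
                continue
            j1 = int(rng.integers(-config.call_jitter, config.call_jitter + 1))
            j2 = int(rng.integers(-config.call_jitter, config.call_jitter + 1))
            start = max(0, p.interval.start + j1)
            end = max(start + 1, p.interval.end + j2)
            sample_calls.append(Peak(
                GenomicInterval(p.interval.chrom, start, end,
                                p.interval.strand),
                f"{s.name}_{p.peak_id}"))
        calls[s.name] = sample_calls
    input_samples = [s for s in samples if s.assay == "input"]
    in_cols = [j for j, s in enumerate(samples) if s.assay == "input"]
    count_table = CountTable([p.peak_id for p in peaks], samples, peak_counts)
    gene_table = GeneExpressionTable(gene_ids, input_samples,
                                     gene_counts[:, in_cols])
    return Bundle(config, genes, seqs, peaks, calls, samples, count_table,
                  gene_table, truth)


def simulate_bundle(config: SimConfig) -> Bundle:
    rng = np.random.default_rng(config.seed)
    seqs, genes = simulate_genome(config, rng)
    return simulate_peaks_and_counts(seqs, genes, config, rng)


def simulate_motif_windows(n: int, motif: str, rate: float,
                           half_window: int = 100, seed: int = 0,
                           mutation_rate: float = 0.0) -> tuple[list, list]:
    """Anchor-centred window sequences with the motif planted so it starts
    exactly at the anchor in a ``rate`` fraction.  Returns (windows,
    carrier_flags); window length is 2*half_window + len(motif)."""
    rng = np.random.default_rng(seed)
    L = len(motif)
    windows, carriers = [], []
    for i in range(n):
        seq = "".join(BASES[rng.integers(0, 4, size=2 * half_window + L)])
        carry = bool(rng.random() < rate)
        if carry:
            bases = list(motif)
            for j in range(L):
                if rng.random() < mutation_rate:
                    bases[j] = str(rng.choice(BASES))
            seq = seq[:half_window] + "".join(bases) + seq[half_window + L:]
        windows.append(seq)
        carriers.append(carry)
    return windows, carriers


#: insertion blocks for the two planted k-mer families (G/U-rich vs control)
KMER_FAMILY_BLOCKS = ("GTGGTGGTGGTG", "TACATTGCATAC")


def simulate_kmer_families(n_per_family: int = 100, seq_len: int = 100,
                           n_insertions: int = 3,
                           blocks: tuple = KMER_FAMILY_BLOCKS,
                           seed: int = 0) -> tuple[dict, dict]:
    """Peak sequences from planted k-mer families: each sequence receives
    ``n_insertions`` copies of its family's block over a uniform background.

    Returns ({peak_id: sequence}, {peak_id: family index}).  The first
    block's 6-mers emulate a G-rich binding family; the second is a
    dissimilar control family."""
    rng = np.random.default_rng(seed)
    seqs, families = {}, {}
    for fam, block in enumerate(blocks):
        for i in range(n_per_family):
            seq = "".join(BASES[rng.integers(0, 4, size=seq_len)])
            for _ in range(n_insertions):
                pos = int(rng.integers(0, seq_len - len(block) + 1))
                seq = seq[:pos] + block + seq[pos + len(block):]
            pid = f"fam{fam}_{i:04d}"
            seqs[pid] = seq
            families[pid] = fam
    return seqs, families


@dataclass
class NetworkTruth:
    """A planted two-layer regulatory network with its inputs."""

    root: str
    universe: list
    root_clip_targets: set
    changed_rbps: list
    degs: set
    targets: dict                 # rbp -> set of target genes
    edges: set                    # planted (source, target) pairs


def planted_network_truth(seed: int = 0, n_rbps: int = 4, n_genes: int = 30,
                          universe_size: int = 200) -> NetworkTruth:
    """One root RBP, ``n_rbps`` downstream RBPs and ``n_genes``
    differentially expressed genes, with known edges.

    Each downstream RBP is a direct target of the root and targets a random
    subset of the gene universe; the DEGs are drawn half from targeted
    genes, half at random."""
    rng = np.random.default_rng(seed)
    root = "RBP_ROOT"
    rbps = [f"RBP_{i + 1}" for i in range(n_rbps)]
    genes = [f"g{i + 1:04d}" for i in range(universe_size)]
    targets = {}
    for r in rbps:
        k = int(rng.integers(20, 60))
        targets[r] = set(rng.choice(genes, size=k, replace=False))
    union = sorted(set().union(*targets.values()))
    n_hit = min(n_genes // 2, len(union))
    degs = set(rng.choice(union, size=n_hit, replace=False))
    rest = [g for g in genes if g not in degs]
    degs |= set(rng.choice(rest, size=n_genes - n_hit, replace=False))
    clip_extra = set(rng.choice(genes, size=20, replace=False))
    root_clip_targets = set(rbps) | clip_extra
    edges = {(root, r) for r in rbps}
    for r in rbps:
        edges |= {(r, g) for g in targets[r] & degs}
    return NetworkTruth(root, genes, root_clip_targets, rbps, degs, targets,
                        edges)


# ---------------------------------------------------------------------------
# Named fixture presets
# ---------------------------------------------------------------------------

#: canonical planted test motif (a G-rich 6-mer family anchor)
PLANTED_CONSENSUS = "TGTGGA"

PRESETS = {
    "tiny": dict(n_genes=12, peaks_per_gene=(2, 3), frac_diff_peaks=0.3,
                 planted_motif=PLANTED_CONSENSUS, motif_rate=0.5),
    "null": dict(n_genes=1250, peaks_per_gene=(4, 4), frac_diff_peaks=0.0,
                 with_sequence=False, exon_length=(150, 250),
                 intron_length=(200, 300)),
    "confounded": dict(n_genes=500, peaks_per_gene=(4, 4),
                       frac_diff_peaks=0.0, frac_shifted_genes=0.4,
                       gene_shift_fold=2.0, dispersion=0.05,
                       mean_peak_count=200.0, with_sequence=False,
                       exon_length=(150, 250), intron_length=(200, 300)),
    "planted_motif": dict(n_genes=125, peaks_per_gene=(4, 4),
                          exons_per_gene=(1, 2),
                          planted_motif=PLANTED_CONSENSUS, motif_rate=0.9,
                          motif_mutation_rate=0.0),
    "planted_network": dict(n_genes=40, peaks_per_gene=(1, 2),
                            frac_diff_peaks=0.3),
}


def fixture_suite(name: str, seed: int = 0, out_dir=None,
                  force: bool = False) -> Bundle:
    """Build one of the named fixture bundles (optionally written to disk).

    tiny: a complete minimal experiment for end-to-end runs.  null: no
    condition effects anywhere (calibration).  confounded: host expression
    doubled in the second condition for 40% of genes, binding unchanged
    (the offset-normalisation contrast).  planted_motif: consensus written
    at 90% of anchors.  planted_network: small bundle for network tests."""
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; choose from "
                         f"{sorted(PRESETS)}")
    config = SimConfig(seed=seed, **PRESETS[name])
    bundle = simulate_bundle(config)
    if out_dir is not None:
        bundle.write(out_dir, force=force)
    return bundle
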