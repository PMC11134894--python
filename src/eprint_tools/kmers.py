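"""Unbiased k-mer analysis of differential peak sequences.

A binary presence matrix (peak x all 4^k k-mers, exact substring match)
feeds average-linkage hierarchical clustering on Jaccard distance, so peaks
containing similar k-mers group together.  Per-cluster k-mer enrichment is
hypergeometric against all analysed peaks, with BH over the full
cluster x k-mer grid; enriched k-mers are split into "known" (attributable
to a database PWM by relative log-odds) and "unknown", and unknown k-mers
are re-assessed by directional GSEA over the ranked peak list.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist
from statsmodels.stats.multitest import multipletests

from .motifs import MotifModel, PeakSet, gsea_batch

logger = logging.getLogger(__name__)

BASES = "ACGT"


def all_kmers(k: int) -> list[str]:
    return ["".join(t) for t in itertools.product(BASES, repeat=k)]


@dataclass
class KmerMatrix:
    peak_ids: list[str]
    kmers: list[str]
    presence: np.ndarray  # bool, peaks x kmers

    def carriers(self, kmer: str) -> set:
        j = self.kmers.index(kmer)
        return {p for p, hit in zip(self.peak_ids, self.presence[:, j]) if hit}


def kmer_presence(peak_sequences: dict[str, str], k: int = 6) -> KmerMatrix:
    """Exact-substring presence of every k-mer in every peak sequence
    (U mapped to T; sequences shorter than k give all-zero rows)."""
    kmers = all_kmers(k)
    index = {m: j for j, m in enumerate(kmers)}
    peak_ids = list(peak_sequences)
    presence = np.zeros((len(peak_ids), len(kmers)), dtype=bool)
    for i, pid in enumerate(peak_ids):
        seq = peak_sequences[pid].upper().replace("U", "T")
        if len(seq) < k:
            logger.warning("sequence %s shorter than k=%d", pid, k)
            continue
        for s in range(len(seq) - k + 1):
            j = index.get(seq[s:s + k])
            if j is not None:
                presence[i, j] = True
    return KmerMatrix(peak_ids, kmers, presence)


def cluster_peaks(matrix: KmerMatrix, n_clusters: int = 12,
                  height: float | None = None) -> np.ndarray:
    """Average-linkage hierarchical clustering on Jaccard distance between
    presence rows.  Cut at ``n_clusters`` (or at dendrogram ``height`` when
    given).  Deterministic: no randomness enters the linkage."""
    n = len(matrix.peak_ids)
    if height is None and n < n_clusters:
        raise ValueError(f"{n} peaks < n_clusters={n_clusters}")
    X = matrix.presence.astype(float)
    with np.errstate(invalid="ignore"):
        d = pdist(X, metric="jaccard")
    d = np.nan_to_num(d, nan=0.0)  # two all-zero rows are identical
    Z = linkage(d, method="average")
    if height is not None:
        return fcluster(Z, t=height, criterion="distance")
    return fcluster(Z, t=n_clusters, criterion="maxclust")


def cluster_kmer_enrichment(matrix: KmerMatrix, labels: np.ndarray,
                            min_universe_count: int = 5) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of each k-mer in each cluster
    against all analysed peaks; BH over the whole cluster x k-mer grid.
    K-mers carried by fewer than ``min_universe_count`` peaks are skipped."""
    labels = np.asarray(labels)
    M = len(matrix.peak_ids)
    universe_counts = matrix.presence.sum(axis=0)
    keep = np.flatnonzero(universe_counts >= min_universe_count)
    rows = []
    for cl in np.unique(labels):
        in_cluster = labels == cl
        n = int(in_cluster.sum())
        cl_counts = matrix.presence[in_cluster][:, keep].sum(axis=0)
        K = universe_counts[keep]
        p = stats.hypergeom.sf(cl_counts - 1, M, K, n)
        for j, jj in enumerate(keep):
            rows.append({"cluster_id": int(cl), "kmer": matrix.kmers[jj],
                         "in_cluster_count": int(cl_counts[j]),
                         "cluster_size": n,
                         "universe_count": int(K[j]), "universe_size": M,
                         "p": float(p[j])})
    df = pd.DataFrame(rows, columns=["cluster_id", "kmer", "in_cluster_count",
                                     "cluster_size", "universe_count",
                                     "universe_size", "p"])
    df["padj"] = (multipletests(df["p"], method="fdr_bh")[1] if len(df)
                  else np.nan)
    return df


def _best_kmer_score(kmer: str, motif: MotifModel) -> float:
    """Best relative log-odds of a k-mer against a PWM over all full-overlap
    alignments: the shorter of the two slides along the longer, and the
    score is rescaled by the min/max of the covered PWM columns."""
    from .motifs import encode_sequence
    codes = encode_sequence(kmer)
    lo = motif.logodds
    L, k = lo.shape[0], len(kmer)
    best = 0.0
    if L >= k:
        for off in range(L - k + 1):
            sub = lo[off:off + k]
            raw = sub[np.arange(k), np.clip(codes, 0, 3)].sum()
            raw = float(raw) if (codes < 4).all() else 0.0
            lo_min, lo_max = sub.min(axis=1).sum(), sub.max(axis=1).sum()
            if lo_max > lo_min:
                best = max(best, (raw - lo_min) / (lo_max - lo_min))
    else:
        for off in range(k - L + 1):
            sub_codes = codes[off:off + L]
            raw = float(lo[np.arange(L), np.clip(sub_codes, 0, 3)].sum())
            lo_min, lo_max = lo.min(axis=1).sum(), lo.max(axis=1).sum()
            if lo_max > lo_min:
                best = max(best, (raw - lo_min) / (lo_max - lo_min))
    return best


def partition_known_unknown(enriched_kmers: list[str],
                            motif_db: list[MotifModel],
                            threshold: float = 0.8
                            ) -> tuple[dict[str, list[str]], list[str]]:
    """Split k-mers into known (best alignment against some database PWM
    scores >= threshold; labelled with that PWM's RBPs) and unknown."""
    if not motif_db:
        logger.warning("empty motif database: all k-mers unknown")
        return {}, list(enriched_kmers)
    known: dict[str, list[str]] = {}
    unknown: list[str] = []
    for kmer in enriched_kmers:
        rbps: list[str] = []
        for m in motif_db:
            if _best_kmer_score(kmer, m) >= threshold:
                rbps.extend(m.rbp_names or [m.motif_id])
        if rbps:
            known[kmer] = sorted(set(rbps))
        else:
            unknown.append(kmer)
    return known, unknown


def unknown_kmer_gsea(ranked: pd.Series, unknown_kmers: list[str],
                      matrix: KmerMatrix, n_perm: int = 1000,
                      seed: int = 0) -> pd.DataFrame:
    """Directional GSEA of each unknown k-mer's carrier peakset over the
    ranked peak list; BH across the k-mers; empty carrier sets skipped."""
    peaksets = []
    universe = set(ranked.index)
    for kmer in unknown_kmers:
        carriers = matrix.carriers(kmer) & universe
        if not carriers or len(carriers) >= len(universe):
            logger.warning("k-mer %s skipped (carriers=%d)", kmer,
                           len(carriers))
            continue
        peaksets.append(PeakSet(kmer, carriers, "kmer_cluster"))
    if not peaksets:
        return pd.DataFrame(columns=["set_id", "es", "nes", "p", "padj",
                                     "size", "leading_edge"])
    return gsea_batch(ranked, peaksets, n_perm=n_perm, seed=seed)
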