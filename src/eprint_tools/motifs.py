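"""PWM motif scanning, positional z-profiles, motif peaksets, directional
preranked GSEA, and per-feature hypergeometric enrichment.

Scores are relative log-odds: the PWM log2 likelihood ratio against the
background, rescaled so the best attainable match scores 1 and the worst 0.
A peak "carries" a motif when any placement inside the scan window around
its 5' anchor reaches the threshold (default 0.8).  Scanning is on the
peak's own strand in transcription orientation only — the footprinted RNA
is single-stranded — and U is mapped to T at load so RNA-alphabet motifs
work on DNA sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import Peak, anchored_window

BASES = "ACGT"
_BASE_CODE = {b: i for i, b in enumerate(BASES)}
PROB_FLOOR = 1e-3
DEFAULT_THRESHOLD = 0.8


@dataclass
class MotifModel:
    """A position weight matrix with RBP attribution.

    pwm is L x 4 (A, C, G, T/U) with rows summing to 1; background defaults
    to uniform."""

    motif_id: str
    rbp_names: list[str]
    pwm: np.ndarray
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))

    def __post_init__(self):
        self.pwm = np.asarray(self.pwm, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.pwm.ndim != 2 or self.pwm.shape[1] != 4:
            raise ValueError("pwm must be L x 4")
        if not np.allclose(self.pwm.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("pwm rows must sum to 1")

    def __len__(self) -> int:
        return self.pwm.shape[0]

    @property
    def logodds(self) -> np.ndarray:
        return np.log2(np.maximum(self.pwm, PROB_FLOOR)
                       / np.maximum(self.background, PROB_FLOOR))

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.pwm.argmax(axis=1))

    @classmethod
    def from_kmer(cls, kmer: str, motif_id: str | None = None,
                  rbp_names: list[str] | None = None,
                  major: float = 0.97) -> "MotifModel":
        """Degenerate PWM for a plain k-mer (major/minor columns), so k-mer
        motif lists share the PWM code path."""
        kmer = kmer.upper().replace("U", "T")
        minor = (1.0 - major) / 3.0
        pwm = np.full((len(kmer), 4), minor)
        for i, b in enumerate(kmer):
            pwm[i, _BASE_CODE[b]] = major
        return cls(motif_id or f"kmer_{kmer}", rbp_names or [], pwm)


def encode_sequence(seq: str) -> np.ndarray:
    """Integer-encode A/C/G/T as 0..3 and anything else (N, gaps) as 4."""
    seq = seq.upper().replace("U", "T")
    codes = np.full(len(seq), 4, dtype=np.int8)
    for b, i in _BASE_CODE.items():
        codes[np.frombuffer(seq.encode(), dtype=np.uint8)
              == ord(b)] = i
    return codes


def relative_logodds_score(motif: MotifModel, window_sequence: str,
                           position: int = 0) -> float:
    """Relative log-odds of the motif placed at ``position``: raw log-odds
    rescaled to [0, 1] between the minimal and maximal attainable scores.
    Ambiguous bases contribute 0 (score-neutral)."""
    L = len(motif)
    if position < 0 or position + L > len(window_sequence):
        raise ValueError("motif does not fit the window at this position")
    codes = encode_sequence(window_sequence[position:position + L])
    lo = np.column_stack([motif.logodds, np.zeros(L)])
    raw = float(lo[np.arange(L), codes].sum())
    lo_min = float(motif.logodds.min(axis=1).sum())
    lo_max = float(motif.logodds.max(axis=1).sum())
    return (raw - lo_min) / (lo_max - lo_min)


def scan_scores(motif: MotifModel, codes: np.ndarray) -> np.ndarray:
    """Relative log-odds at every placement of the motif along an encoded
    sequence (vectorised sliding window)."""
    L = len(motif)
    n = len(codes) - L + 1
    if n <= 0:
        return np.empty(0)
    lo = np.column_stack([motif.logodds, np.zeros(L)])
    windows = np.lib.stride_tricks.sliding_window_view(codes, L)
    raw = lo[np.arange(L)[None, :], windows[:n]].sum(axis=1)
    lo_min = motif.logodds.min(axis=1).sum()
    lo_max = motif.logodds.max(axis=1).sum()
    return (raw - lo_min) / (lo_max - lo_min)


@dataclass
class PositionalProfile:
    motif_id: str
    positions: np.ndarray  # motif start offsets relative to the 5' anchor
    mean_score: np.ndarray
    z: np.ndarray

    @property
    def peak_position(self) -> int:
        return int(self.positions[int(np.argmax(self.z))])


def positional_profile_from_windows(motif: MotifModel, windows: list[str],
                                    half_window: int = 100
                                    ) -> PositionalProfile:
    """Profile over motif start offsets -half_window..+half_window.

    Each window string must be centred on the anchor and long enough for the
    motif to fit at the rightmost offset (length 2*half_window + len(motif));
    shorter windows are N-padded (score-neutral).  Per-offset scores are
    averaged across windows and converted to z-scores across offsets."""
    L = len(motif)
    need = 2 * half_window + L
    n_pos = 2 * half_window + 1
    total = np.zeros(n_pos)
    if len(windows) < 10:
        import warnings
        warnings.warn(f"only {len(windows)} windows; z-profile is unstable")
    for w in windows:
        if len(w) < need:
            w = w + "N" * (need - len(w))
        total += scan_scores(motif, encode_sequence(w))[:n_pos]
    mean = total / max(len(windows), 1)
    sd = mean.std()
    z = (mean - mean.mean()) / sd if sd > 0 else np.zeros(n_pos)
    return PositionalProfile(motif.motif_id,
                             np.arange(-half_window, half_window + 1),
                             mean, z)


def positional_profile(motif: MotifModel, peaks: list[Peak],
                       sequences: dict[str, str], half_window: int = 100
                       ) -> PositionalProfile:
    """Positional scan in a window centred on each peak's 5' anchor
    (default 200 bp), in transcription orientation."""
    L = len(motif)
    windows = [anchored_window(p, sequences, half_window + L - 1)[L - 1:]
               for p in peaks]
    return positional_profile_from_windows(motif, windows, half_window)


@dataclass
class PeakSet:
    set_id: str
    peak_ids: set
    provenance: str = "motif"  # motif | clip_overlap | kmer_cluster


def motif_peakset(motif: MotifModel, peaks: list[Peak],
                  sequences: dict[str, str], half_window: int = 25,
                  threshold: float = DEFAULT_THRESHOLD) -> PeakSet:
    """Peaks carrying the motif: any placement whose start lies within the
    scan window around the anchor (default 50 bp) scores >= threshold."""
    L = len(motif)
    members = set()
    for p in peaks:
        w = anchored_window(p, sequences, half_window + L - 1)[L - 1:]
        scores = scan_scores(motif, encode_sequence(w))
        if len(scores) and scores[:2 * half_window + 1].max() >= threshold:
            members.add(p.peak_id)
    return PeakSet(motif.motif_id, members, "motif")


# ---------------------------------------------------------------------------
# Directional preranked GSEA
# ---------------------------------------------------------------------------

@dataclass
class GseaResult:
    set_id: str
    es: float
    nes: float
    p: float
    padj: float
    size: int
    leading_edge: list[str]


def _enrichment_score(stats_abs: np.ndarray, hit: np.ndarray
                      ) -> tuple[float, int]:
    """Weighted Kolmogorov-Smirnov running-sum enrichment score (weight =
    |ranking statistic|).  Returns (ES, extremum index)."""
    n = len(stats_abs)
    n_hit = int(hit.sum())
    hit_w = stats_abs * hit
    denom = hit_w.sum()
    if denom <= 0:  # all-zero stats in the set: equal weights
        hit_w = hit.astype(float)
        denom = hit_w.sum()
    step = hit_w / denom - (~hit.astype(bool)).astype(float) / (n - n_hit)
    running = np.cumsum(step)
    i_max, i_min = int(np.argmax(running)), int(np.argmin(running))
    if running[i_max] >= -running[i_min]:
        return float(running[i_max]), i_max
    return float(running[i_min]), i_min


def directional_gsea(ranked: pd.Series, peakset: PeakSet,
                     n_perm: int = 1000, seed: int = 0,
                     rng: np.random.Generator | None = None) -> GseaResult:
    """Directional GSEA of one peakset over a ranked peak list.

    ``ranked`` maps peak_id -> signed ranking statistic, sorted most
    enhanced first.  The null is peakset-membership permutation (random
    same-size sets); p is one-sided among same-sign null scores with a
    +1 floor, and NES divides ES by the mean |null ES| of the same sign.
    """
    ids = np.asarray(ranked.index)
    values = ranked.to_numpy(dtype=float)
    members = peakset.peak_ids & set(ids)
    if not members or len(members) >= len(ids):
        raise ValueError("peakset must be a non-empty proper subset of the "
                         "ranked universe")
    rng = rng or np.random.default_rng(seed)
    stats_abs = np.abs(values)
    hit = np.isin(ids, list(members)).astype(float)
    es, extremum = _enrichment_score(stats_abs, hit)

    n, k = len(ids), len(members)
    null = np.empty(n_perm)
    for b in range(n_perm):
        idx = rng.choice(n, size=k, replace=False)
        h = np.zeros(n)
        h[idx] = 1.0
        null[b], _ = _enrichment_score(stats_abs, h)
    same = null * np.sign(es) > 0
    n_same = int(same.sum())
    p = (1 + int((np.abs(null[same]) >= abs(es)).sum())) / (1 + n_same)
    mean_same = np.abs(null[same]).mean() if n_same else np.abs(null).mean()
    nes = es / mean_same if mean_same > 0 else 0.0

    hit_idx = np.flatnonzero(hit > 0)
    if es >= 0:
        leading = [str(ids[i]) for i in hit_idx if i <= extremum]
    else:
        leading = [str(ids[i]) for i in hit_idx if i >= extremum]
    return GseaResult(peakset.set_id, es, nes, p, np.nan, k, leading)


def gsea_batch(ranked: pd.Series, peaksets: list[PeakSet],
               n_perm: int = 1000, seed: int = 0) -> pd.DataFrame:
    """Run directional GSEA for every peakset and BH-adjust across them all
    (one family of tests).  Deterministic for a fixed seed."""
    rng = np.random.default_rng(seed)
    rows = []
    for ps in peaksets:
        r = directional_gsea(ranked, ps, n_perm=n_perm, rng=rng)
        rows.append({"set_id": r.set_id, "es": r.es, "nes": r.nes,
                     "p": r.p, "size": r.size,
                     "leading_edge": ",".join(r.leading_edge)})
    df = pd.DataFrame(rows)
    if len(df):
        df["padj"] = multipletests(df["p"], method="fdr_bh")[1]
    return df


# ---------------------------------------------------------------------------
# Hypergeometric feature enrichment
# ---------------------------------------------------------------------------

def motif_feature_enrichment(peakset: PeakSet, categories: dict) -> pd.DataFrame:
    """Per-category hypergeometric enrichment (upper tail) and depletion
    (lower tail) of a motif's peaks among the categorised universe."""
    universe = list(categories)
    M = len(universe)
    members = peakset.peak_ids & set(universe)
    n = len(members)
    rows = []
    cats = sorted({str(c) for c in categories.values()})
    for cat in cats:
        in_cat = {p for p, c in categories.items() if str(c) == cat}
        K = len(in_cat)
        k = len(members & in_cat)
        rows.append({
            "set_id": peakset.set_id, "category": cat,
            "n_set": n, "n_category": K, "n_overlap": k, "universe": M,
            "p_enrich": float(stats.hypergeom.sf(k - 1, M, K, n)),
            "p_deplete": float(stats.hypergeom.cdf(k, M, K, n)),
        })
    return pd.DataFrame(rows)


def feature_enrichment_batch(peaksets: list[PeakSet],
                             categories: dict) -> pd.DataFrame:
    """Enrichment/depletion over the motif x category grid, BH-adjusted
    within the whole grid."""
    parts = [motif_feature_enrichment(ps, categories) for ps in peaksets]
    df = pd.concat(parts, ignore_index=True)
    if len(df):
        df["padj_enrich"] = multipletests(df["p_enrich"], method="fdr_bh")[1]
        df["padj_deplete"] = multipletests(df["p_deplete"], method="fdr_bh")[1]
    return df


# ---------------------------------------------------------------------------
# Motif file formats
# ---------------------------------------------------------------------------

def read_meme_motifs(path) -> list[MotifModel]:
    """Minimal MEME-format reader (MOTIF blocks with letter-probability
    matrices; alphabet ACGT or ACGU)."""
    motifs = []
    name = None
    rows: list[list[float]] = []
    in_matrix = False

    def flush():
        if name is not None and rows:
            motifs.append(MotifModel(name, [], np.array(rows)))

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("MOTIF"):
                flush()
                parts = line.split()
                name = parts[1] if len(parts) > 1 else "motif"
                rows, in_matrix = [], False
            elif line.startswith("letter-probability"):
                in_matrix = True
            elif in_matrix and line:
                try:
                    vals = [float(x) for x in line.split()]
                except ValueError:
                    in_matrix = False
                    continue
                if len(vals) >= 4:
                    rows.append(vals[:4])
            elif in_matrix and not line:
                in_matrix = False
    flush()
    return motifs


def read_matrix_motifs(path) -> list[MotifModel]:
    """Matrix-text motif reader: header lines ``>motif_id RBP1,RBP2``
    followed by one line of 4 probabilities (A C G T/U) per position."""
    motifs = []
    name, rbps, rows = None, [], []

    def flush():
        if name is not None and rows:
            motifs.append(MotifModel(name, rbps, np.array(rows)))

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                parts = line[1:].split(None, 1)
                name = parts[0]
                rbps = parts[1].split(",") if len(parts) > 1 else []
                rows = []
            else:
                rows.append([float(x) for x in line.split()[:4]])
    flush()
    return motifs
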