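"""Negative-binomial differential binding with host-gene expression offsets.

The model for peak p in sample j is

    K_pj ~ NB(mu_pj, alpha_p),   log mu_pj = o_pj + x_j' beta_p

where the per-peak, per-sample offset o_pj carries both the sample size
factor and the (normalised) expression of the peak's host gene measured in
the condition-matched input library.  The condition coefficient therefore
estimates the change in peak amplitude *beyond* the change in host-gene
expression — differential binding, not differential expression.  Intergenic
peaks have no host gene and are excluded.

Testing is a two-sided normal Wald test on the condition coefficient with
Benjamini-Hochberg adjustment across all tested peaks; the signed Wald
statistic defines the ranked peak list consumed by the enrichment analyses.

The public surface is :class:`DifferentialBindingModel` (construct from a
:class:`~eprint_tools.core.CountTable`) whose ``fit()`` returns a
:class:`DifferentialBindingResults`.  ``deg_on_input`` runs the same
machinery on the input libraries with size-factor-only offsets: ordinary
differential gene expression.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import CountTable, GeneExpressionTable, SampleInfo

logger = logging.getLogger(__name__)

LOG2 = np.log(2.0)
MIN_DISPERSION = 1e-8
MAX_DISPERSION = 10.0
EXPRESSION_PSEUDOCOUNT = 0.5

#: (max adjusted p, min |log2 fold change|) significance presets
PRESETS = {"fus": (0.05, 1.0), "mn": (0.01, 1.0)}


def estimate_size_factors(counts: np.ndarray) -> np.ndarray:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    Falls back to column-sum ratios (with a warning) when no row is nonzero
    in every sample.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2:
        raise ValueError("counts must be 2-d")
    if counts.shape[1] == 1:
        return np.ones(1)
    all_pos = (counts > 0).all(axis=1)
    if not all_pos.any():
        warnings.warn("no feature nonzero in all samples; using library-size "
                      "ratios for size factors")
        totals = np.maximum(counts.sum(axis=0), 1.0)  # guard empty columns
        factors = totals / np.exp(np.mean(np.log(totals)))
        return factors
    sub = counts[all_pos, :]
    log_geomean = np.mean(np.log(sub), axis=1)
    factors = np.exp(np.median(np.log(sub) - log_geomean[:, None], axis=0))
    return factors / np.exp(np.mean(np.log(factors)))


def match_input_samples(eprint_samples: list[SampleInfo],
                        input_samples: list[SampleInfo]) -> list[int]:
    """Pair each footprint sample with its input by (condition, batch,
    replicate order of appearance).  Returns indices into input_samples."""
    pools: dict[tuple, list[int]] = {}
    for idx, s in enumerate(input_samples):
        pools.setdefault((s.condition, s.batch), []).append(idx)
    used: dict[tuple, int] = {}
    matches = []
    for s in eprint_samples:
        key = (s.condition, s.batch)
        pool = pools.get(key)
        if not pool:
            raise ValueError(f"no input sample for condition={s.condition!r} "
                             f"batch={s.batch!r}")
        k = used.get(key, 0)
        matches.append(pool[min(k, len(pool) - 1)])
        used[key] = k + 1
    return matches


def build_offsets(size_factors: np.ndarray,
                  gene_expr: GeneExpressionTable,
                  peak_hosts: list[str],
                  input_match: list[int]) -> np.ndarray:
    """Per-peak x per-sample log offsets: size factor plus host-gene input
    expression (normalised by input size factors, floored at pseudocount 0.5).
    """
    missing = sorted({h for h in peak_hosts if h not in set(gene_expr.gene_ids)})
    if missing:
        raise ValueError(f"host genes absent from input expression: {missing}")
    in_sf = estimate_size_factors(gene_expr.counts)
    norm_expr = gene_expr.counts / in_sf[None, :]
    gene_row = {g: i for i, g in enumerate(gene_expr.gene_ids)}
    rows = np.array([gene_row[h] for h in peak_hosts])
    expr = norm_expr[rows][:, input_match]
    expr = np.maximum(expr, EXPRESSION_PSEUDOCOUNT)
    return np.log(size_factors)[None, :] + np.log(expr)


def _fit_poisson_means(y: np.ndarray, X: np.ndarray,
                       offsets: np.ndarray) -> np.ndarray:
    """Fitted means from a Poisson GLM (log link, offsets); used for the
    moment dispersion estimator."""
    beta, _, converged = _irls(y, X, offsets, alpha=0.0)
    return np.exp(offsets + X @ beta)


def _pearson_dispersion(y: np.ndarray, mu: np.ndarray, df: int) -> float:
    """Method-of-moments dispersion: solve sum((y-mu)^2/(mu+a*mu^2)) = df.

    The left side is decreasing in a; a=0 corresponds to Poisson.  Returns 0
    when even Poisson over-fits (under-dispersion), MAX_DISPERSION when the
    equation cannot be met.
    """
    r2 = (y - mu) ** 2

    def pearson(a):
        return float(np.sum(r2 / (mu + a * mu ** 2)))

    if df <= 0 or pearson(0.0) <= df:
        return 0.0
    lo, hi = 0.0, MAX_DISPERSION
    if pearson(hi) > df:
        return MAX_DISPERSION
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if pearson(mid) > df:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def estimate_dispersion(counts: np.ndarray, design: np.ndarray,
                        offsets: np.ndarray) -> np.ndarray:
    """Per-peak NB dispersion: moment estimate shrunk 50/50 toward a fitted
    mean-dispersion trend a0 + a1/mu, clamped to [1e-8, 10].

    All-zero peaks take the trend value directly.
    """
    counts = np.asarray(counts, dtype=float)
    n_peaks, n_samples = counts.shape
    p = design.shape[1]
    df = n_samples - p
    raw = np.zeros(n_peaks)
    base_mean = np.zeros(n_peaks)
    all_zero = np.zeros(n_peaks, dtype=bool)
    for i in range(n_peaks):
        y = counts[i]
        base_mean[i] = float(np.mean(y / np.exp(offsets[i] - offsets[i].mean())))
        if not y.any():
            all_zero[i] = True
            continue
        mu = _fit_poisson_means(y, design, offsets[i])
        raw[i] = _pearson_dispersion(y, mu, df)
    # trend fit: raw ~ a0 + a1 / mu over informative peaks
    ok = (~all_zero) & (base_mean > 0)
    if ok.sum() >= 10:
        A = np.column_stack([np.ones(ok.sum()), 1.0 / base_mean[ok]])
        coef, *_ = np.linalg.lstsq(A, raw[ok], rcond=None)
        a0, a1 = max(coef[0], 0.0), max(coef[1], 0.0)
    else:
        a0, a1 = float(np.median(raw[ok])) if ok.any() else 0.1, 0.0
    trend = a0 + a1 / np.maximum(base_mean, 1e-8)
    alpha = 0.5 * raw + 0.5 * trend
    alpha[all_zero] = trend[all_zero]
    if all_zero.any():
        logger.warning("%d all-zero peaks set to trend dispersion",
                       int(all_zero.sum()))
    return np.clip(alpha, MIN_DISPERSION, MAX_DISPERSION)


def _irls(y: np.ndarray, X: np.ndarray, offsets: np.ndarray, alpha: float,
          tol: float = 1e-8, maxiter: int = 100
          ) -> tuple[np.ndarray, np.ndarray, bool]:
    """Fisher-scoring IRLS for the NB (or Poisson, alpha=0) log-link GLM with
    fixed dispersion.  Returns (beta, covariance, converged)."""
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        raise np.linalg.LinAlgError("design matrix is rank deficient")
    # init from log counts
    z0 = np.log(np.maximum(y, 0.5)) - offsets
    beta, *_ = np.linalg.lstsq(X, z0, rcond=None)
    converged = False
    XtWX = np.eye(p)
    for _ in range(maxiter):
        eta = offsets + X @ beta
        eta = np.clip(eta, -30, 30)
        mu = np.exp(eta)
        w = mu / (1.0 + alpha * mu)
        z = (eta - offsets) + (y - mu) / mu
        XtW = X.T * w
        XtWX = XtW @ X
        try:
            new_beta = np.linalg.solve(XtWX, XtW @ z)
        except np.linalg.LinAlgError:
            break
        step = new_beta - beta
        beta = new_beta
        if np.max(np.abs(step)) < tol:
            converged = True
            break
    try:
        cov = np.linalg.inv(XtWX)
    except np.linalg.LinAlgError:
        cov = np.full((p, p), np.nan)
    return beta, cov, converged


def fit_nb_glm(counts_row: np.ndarray, design: np.ndarray,
               offsets_row: np.ndarray, dispersion: float
               ) -> tuple[np.ndarray, np.ndarray, bool]:
    """Fit one peak's NB GLM at fixed dispersion; returns (beta, cov,
    converged)."""
    return _irls(np.asarray(counts_row, float), design,
                 np.asarray(offsets_row, float), float(dispersion))


def wald_and_adjust(frame: pd.DataFrame) -> pd.DataFrame:
    """Two-sided normal Wald p-values on log2FC/se and BH adjustment.

    Operates on a frame with columns log2FC and se; adds wald, p, padj and a
    ranking column ``stat`` (signed Wald, ties broken by peak id order)."""
    frame = frame.copy()
    with np.errstate(divide="ignore", invalid="ignore"):
        frame["wald"] = frame["log2FC"] / frame["se"]
    frame["p"] = 2.0 * stats.norm.sf(np.abs(frame["wald"]))
    valid = frame["p"].notna()
    padj = np.full(len(frame), np.nan)
    if valid.any():
        padj[valid.to_numpy()] = multipletests(
            frame.loc[valid, "p"], method="fdr_bh")[1]
    frame["padj"] = padj
    return frame


def build_design(samples: list[SampleInfo], reference: str | None = None,
                 include_batch: bool | None = None
                 ) -> tuple[np.ndarray, list[str], str]:
    """Intercept + condition indicator(s) + batch indicator(s).

    The reference condition is the lexicographically first level unless
    given.  Batch columns are added when more than one batch is present
    (or as forced by ``include_batch``)."""
    conditions = sorted({s.condition for s in samples})
    if len(conditions) != 2:
        raise ValueError(f"exactly two conditions required, got {conditions}")
    if reference is None:
        reference = conditions[0]
    elif reference not in conditions:
        raise ValueError(f"reference {reference!r} not among {conditions}")
    alt = [c for c in conditions if c != reference][0]
    batches = sorted({s.batch for s in samples})
    if include_batch is None:
        include_batch = len(batches) > 1
    cols = [np.ones(len(samples))]
    names = ["intercept"]
    cols.append(np.array([1.0 if s.condition == alt else 0.0 for s in samples]))
    names.append(f"condition[{alt}]")
    if include_batch:
        for b in batches[1:]:
            cols.append(np.array([1.0 if s.batch == b else 0.0
                                  for s in samples]))
            names.append(f"batch[{b}]")
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient (batch confounded "
                         "with condition?)")
    return X, names, alt


@dataclass
class DesignInfo:
    design: np.ndarray
    coef_names: list[str]
    condition_coef: int
    size_factors: np.ndarray
    offset_matrix: np.ndarray  # peaks x samples, log scale

    def __post_init__(self):
        if (self.size_factors <= 0).any():
            raise ValueError("size factors must be positive")
        if not np.isfinite(self.offset_matrix).all():
            raise ValueError("offset matrix must be finite")


class DifferentialBindingModel:
    """NB GLM for differential binding across two conditions.

    Parameters
    ----------
    counts : CountTable
        Peak counts; only samples with assay "eprint" enter the model.
    gene_expr : GeneExpressionTable, optional
        Host-gene expression from the input libraries.  When given (together
        with ``peak_hosts``) it enters the offsets, normalising each peak's
        amplitude to its host gene's expression.  When omitted, offsets are
        size factors only (plain differential amplitude).
    peak_hosts : dict, optional
        peak_id -> host gene id for every modelled peak.
    reference : str, optional
        Reference condition level (default: lexicographically first).
    """

    def __init__(self, counts: CountTable,
                 gene_expr: GeneExpressionTable | None = None,
                 peak_hosts: dict[str, str] | None = None,
                 reference: str | None = None,
                 include_batch: bool | None = None):
        ep_cols = [j for j, s in enumerate(counts.samples)
                   if s.assay == "eprint"]
        if len(ep_cols) < 4:
            raise ValueError("need >= 2 footprint samples per condition")
        self.samples = [counts.samples[j] for j in ep_cols]
        self.peak_ids = list(counts.peak_ids)
        self.counts = counts.counts[:, ep_cols].astype(float)
        self.gene_expr = gene_expr
        self.peak_hosts = peak_hosts
        X, names, alt = build_design(self.samples, reference, include_batch)
        sf = estimate_size_factors(self.counts)
        if gene_expr is not None:
            if peak_hosts is None:
                raise ValueError("peak_hosts required with gene_expr")
            hosts = [peak_hosts[p] for p in self.peak_ids]
            match = match_input_samples(self.samples, gene_expr.samples)
            offsets = build_offsets(sf, gene_expr, hosts, match)
        else:
            offsets = np.tile(np.log(sf), (len(self.peak_ids), 1))
        self.design_info = DesignInfo(X, names, names.index(f"condition[{alt}]"),
                                      sf, offsets)
        self.condition_label = alt

    def fit(self, dispersions: np.ndarray | None = None
            ) -> "DifferentialBindingResults":
        X = self.design_info.design
        off = self.design_info.offset_matrix
        ci = self.design_info.condition_coef
        if dispersions is None:
            dispersions = estimate_dispersion(self.counts, X, off)
        n = len(self.peak_ids)
        lfc = np.full(n, np.nan)
        se = np.full(n, np.nan)
        ok = np.zeros(n, dtype=bool)
        for i in range(n):
            y = self.counts[i]
            if not y.any():
                continue
            beta, cov, converged = fit_nb_glm(y, X, off[i], dispersions[i])
            if not converged or not np.isfinite(cov[ci, ci]) or cov[ci, ci] <= 0:
                continue
            lfc[i] = beta[ci] / LOG2
            se[i] = np.sqrt(cov[ci, ci]) / LOG2
            ok[i] = True
        frame = pd.DataFrame({
            "peak_id": self.peak_ids,
            "baseMean": self.counts.mean(axis=1),
            "log2FC": lfc,
            "se": se,
            "dispersion": dispersions,
            "converged": ok,
        })
        frame = wald_and_adjust(frame)
        return DifferentialBindingResults(self, frame)


class DifferentialBindingResults:
    """Fitted per-peak estimates: log2 fold change (condition vs reference),
    standard error, Wald statistic, p and BH-adjusted p."""

    def __init__(self, model: DifferentialBindingModel, frame: pd.DataFrame):
        self.model = model
        self.frame = frame.set_index(frame["peak_id"].rename(None),
                                     drop=False)

    def ranked(self) -> pd.DataFrame:
        """Peaks sorted most-enhanced-first by signed Wald statistic, with a
        deterministic peak_id tie-break (a strict total order)."""
        f = self.frame[self.frame["wald"].notna()]
        return f.sort_values(["wald", "peak_id"],
                             ascending=[False, True], kind="mergesort")

    def ranking(self) -> pd.Series:
        """Signed Wald statistic indexed by peak_id, most enhanced first."""
        return self.ranked()["wald"]

    def significant(self, preset: str | None = None,
                    max_padj: float = 0.05,
                    min_abs_log2fc: float = 1.0) -> pd.DataFrame:
        if preset is not None:
            max_padj, min_abs_log2fc = PRESETS[preset]
        f = self.frame
        return f[(f["padj"] < max_padj)
                 & (f["log2FC"].abs() > min_abs_log2fc)]

    def summary(self) -> str:
        f = self.frame
        n_tested = int(f["p"].notna().sum())
        n_sig = int((f["padj"] < 0.05).sum())
        n_up = int(((f["padj"] < 0.05) & (f["log2FC"] > 0)).sum())
        n_dn = n_sig - n_up
        lines = [
            "Differential binding (NB GLM, Wald test)",
            "=" * 44,
            f"condition:          {self.model.condition_label} vs reference",
            f"samples:            {len(self.model.samples)}",
            f"peaks tested:       {n_tested} / {len(f)}",
            f"padj < 0.05:        {n_sig} ({n_up} enhanced, {n_dn} reduced)",
            f"median dispersion:  {np.median(f['dispersion']):.4g}",
            "host-gene offsets:  "
            + ("yes" if self.model.gene_expr is not None else "no"),
        ]
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)


def deg_on_input(gene_expr: GeneExpressionTable,
                 reference: str | None = None,
                 include_batch: bool | None = None
                 ) -> DifferentialBindingResults:
    """Conventional differential expression on the input libraries: the same
    NB machinery with size-factor-only offsets.  Zero-count genes are
    excluded (reported in the result frame as non-converged rows)."""
    ct = CountTable(list(gene_expr.gene_ids), list(gene_expr.samples),
                    gene_expr.counts)
    model = DifferentialBindingModel(
        CountTable(ct.peak_ids,
                   [SampleInfo(s.name, "eprint", s.condition, s.batch,
                               s.library_size) for s in ct.samples],
                   ct.counts),
        reference=reference, include_batch=include_batch)
    return model.fit()
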