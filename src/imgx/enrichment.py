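"""Cell-type enrichment: specificity bootstrap (EWCE-style) and
hypergeometric overlap of differentially-expressed gene lists.

The specificity of a gene for a cell type is its mean expression in that type
divided by its summed mean expression across types, so each gene's profile
sums to one.  A target list's summed specificity per type is compared with
random lists matched to the target's transcript-length and GC-content
composition; the empirical p uses the (1+k)/(1+n) estimator and
Benjamini-Hochberg adjustment across cell types.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "SpecificityMatrix",
    "EWCEResult",
    "OverlapResult",
    "compute_specificity",
    "matched_bins",
    "ewce_test",
    "hypergeom_overlap",
    "bh_adjust",
]


@dataclass
class SpecificityMatrix:
    """Gene x cell-type specificity proportions (rows sum to 1), plus the
    per-gene transcript length (bp) and GC fraction used for matched nulls."""

    values: pd.DataFrame  # genes (index) x cell types
    length_bp: pd.Series | None = None
    gc: pd.Series | None = None
    dropped_genes: tuple[str, ...] = ()

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def cell_types(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class EWCEResult:
    table: pd.DataFrame  # per cell type: observed, null_mean, null_sd, sd_from_mean, fold_change, p, p_adj
    n_perm: int
    seed: int
    n_target_dropped: int = 0


@dataclass
class OverlapResult:
    k: int
    K: int
    n: int
    N: int
    p: float


def compute_specificity(
    mean_expr: pd.DataFrame,
    length_bp: pd.Series | None = None,
    gc: pd.Series | None = None,
) -> SpecificityMatrix:
    """s[g, c] = mean_expr[g, c] / sum_c' mean_expr[g, c'].

    All-zero genes cannot be normalized; they are dropped and listed on the
    result.  Negative entries are rejected.
    """
    X = mean_expr.to_numpy(dtype=float)
    if np.any(X < 0):
        raise ValueError("mean expression must be nonnegative")
    totals = X.sum(axis=1)
    zero = totals == 0
    dropped = tuple(mean_expr.index[zero])
    keep = ~zero
    values = pd.DataFrame(
        X[keep] / totals[keep, None],
        index=mean_expr.index[keep],
        columns=mean_expr.columns,
    )
    if length_bp is not None:
        length_bp = length_bp.reindex(values.index)
    if gc is not None:
        gc = gc.reindex(values.index)
    return SpecificityMatrix(values=values, length_bp=length_bp, gc=gc, dropped_genes=dropped)


def matched_bins(
    genes: list[str],
    length_bp: pd.Series,
    gc: pd.Series,
    n_bins: int = 10,
) -> pd.Series:
    """Joint quantile bins over (transcript length, GC content).

    Marginal ``n_bins``-quantile cuts on each covariate form an
    n_bins x n_bins grid; every gene gets one bin id.  ``n_bins=1`` is
    unmatched sampling.  Null gene draws within bins hold the target list's
    length/GC composition fixed.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if n_bins**2 > len(genes):
        raise ValueError(
            f"{n_bins}x{n_bins} bins exceed {len(genes)} genes; use fewer bins"
        )
    ln = length_bp.reindex(genes).to_numpy(dtype=float)
    g = gc.reindex(genes).to_numpy(dtype=float)
    if not (np.all(np.isfinite(ln)) and np.all(np.isfinite(g))):
        raise ValueError("length and GC must be finite for all genes")
    if n_bins == 1:
        return pd.Series(0, index=genes)
    lbin = pd.qcut(ln, n_bins, labels=False, duplicates="drop")
    gbin = pd.qcut(g, n_bins, labels=False, duplicates="drop")
    return pd.Series(lbin * n_bins + gbin, index=genes)


def _sample_without_replacement(
    rng: np.random.Generator, pool: np.ndarray, m: int, n_draws: int
) -> np.ndarray:
    """(n_draws, m) indices into ``pool``, distinct within each draw."""
    n_pool = len(pool)
    if m > n_pool:
        raise ValueError("cannot draw more genes than the bin holds")
    if m == 1:
        return pool[rng.integers(0, n_pool, size=(n_draws, 1))]
    # chunked argpartition of random keys keeps memory bounded
    out = np.empty((n_draws, m), dtype=pool.dtype)
    chunk = max(1, int(2e7) // max(n_pool, 1))
    for start in range(0, n_draws, chunk):
        stop = min(start + chunk, n_draws)
        keys = rng.random((stop - start, n_pool))
        sel = np.argpartition(keys, m - 1, axis=1)[:, :m]
        out[start:stop] = pool[sel]
    return out


def ewce_test(
    target: list[str],
    S: SpecificityMatrix,
    n_perm: int = 100_000,
    seed: int = 0,
    n_bins: int = 10,
) -> EWCEResult:
    """Expression-weighted cell-type enrichment bootstrap.

    Per cell type the statistic is the summed specificity of the target list;
    the null resamples gene lists of the same size respecting the target's
    joint transcript-length/GC bin composition (``n_bins=1`` disables
    matching).  p = (1 + #{null >= observed}) / (1 + n_perm), upper tail
    (enrichment); results are BH-adjusted across cell types and reported with
    the standard-deviations-from-the-null-mean effect size.
    """
    genes_in = [g for g in target if g in set(S.genes)]
    n_dropped = len(target) - len(genes_in)
    if not genes_in:
        raise ValueError("no target genes present in the specificity matrix")
    if n_perm < 1:
        raise ValueError("n_perm must be positive")
    rng = np.random.default_rng(seed)
    V = S.values.to_numpy()
    row_of = {g: i for i, g in enumerate(S.genes)}
    t_rows = np.array([row_of[g] for g in genes_in])
    observed = V[t_rows].sum(axis=0)

    if n_bins > 1:
        if S.length_bp is None or S.gc is None:
            raise ValueError("length/GC annotations required for matched sampling")
        bins = matched_bins(S.genes, S.length_bp, S.gc, n_bins=n_bins)
    else:
        bins = pd.Series(0, index=S.genes)
    target_bins = bins.loc[genes_in]

    null = np.zeros((n_perm, V.shape[1]))
    for b, m in target_bins.value_counts().items():
        pool = np.flatnonzero((bins == b).to_numpy())
        draws = _sample_without_replacement(rng, pool, int(m), n_perm)
        null += V[draws].sum(axis=1)

    null_mean = null.mean(axis=0)
    null_sd = null.std(axis=0, ddof=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        sd_from_mean = np.where(null_sd > 0, (observed - null_mean) / null_sd, 0.0)
        fold = np.where(null_mean > 0, observed / null_mean, np.nan)
    p = (1 + (null >= observed[None, :]).sum(axis=0)) / (1 + n_perm)
    p_adj = bh_adjust(p)
    table = pd.DataFrame(
        {
            "observed": observed,
            "null_mean": null_mean,
            "null_sd": null_sd,
            "sd_from_mean": sd_from_mean,
            "fold_change": fold,
            "p": p,
            "p_adj": p_adj,
        },
        index=S.cell_types,
    )
    return EWCEResult(table=table, n_perm=n_perm, seed=seed, n_target_dropped=n_dropped)


def hypergeom_overlap(
    target: list[str] | set[str], deg: list[str] | set[str], universe: list[str] | set[str]
) -> OverlapResult:
    """Inclusive upper-tail hypergeometric p for the overlap of two gene lists.

    With universe size N, |deg| = K successes, |target| = n draws and overlap
    k, p = P(X >= k) for X ~ Hypergeom(N, K, n).
    """
    uni = set(universe)
    t = set(target)
    d = set(deg)
    bad = sorted((t | d) - uni)
    if bad:
        raise ValueError(f"genes outside the universe: {bad[:10]}")
    N, K, n = len(uni), len(d), len(t)
    k = len(t & d)
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    return OverlapResult(k=k, K=K, n=n, N=N, p=min(max(p, np.finfo(float).tiny), 1.0))


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (original order kept)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
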