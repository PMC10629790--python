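"""Spatially-adjusted gene-map association.

The central inference chain: each donor's expression samples are matched to
the t-map voxel they fall in; for every probe a *partial Spearman* correlation
between expression and t-value is computed with Moran eigenvector maps (MEMs)
as spatial covariates, absorbing shared spatial autocorrelation that would
otherwise inflate significance; per-donor signed z-scores are combined across
donors with a weighted-Z (Stouffer) rule; probe statistics are averaged to
gene level and ranked into top-fraction gene lists.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .images import VolumeImage, world_to_voxel
from .glm import TMap
from .spatial import inverse_distance_weights

__all__ = [
    "MEMBasis",
    "DonorAssociationResult",
    "CombinedGeneTable",
    "match_samples_to_map",
    "build_mem_basis",
    "adjusted_spearman",
    "combine_donors",
    "donor_association",
    "combine_probe_results",
    "gene_level",
    "top_fraction_lists",
]

#: largest |z| representable through Phi^-1 near 1 in double precision
Z_MAX = 8.21


@dataclass
class MEMBasis:
    """Moran eigenvector maps: orthonormal spatial patterns ordered by
    eigenvalue (descending), i.e. by spatial scale from broadest down."""

    vectors: np.ndarray  # samples x k
    eigenvalues: np.ndarray
    rule: str

    @property
    def k(self) -> int:
        return 0 if self.vectors.size == 0 else self.vectors.shape[1]


@dataclass
class DonorAssociationResult:
    donor_id: str
    table: pd.DataFrame  # per probe: probe_id, gene_symbol, rho, t_stat, z, n
    n_dropped_samples: int = 0


@dataclass
class CombinedGeneTable:
    """Per gene: mean association T, combined Z, two-tailed p, provenance."""

    table: pd.DataFrame  # index gene; columns T, Z, p, n_probes, n_donors


def match_samples_to_map(
    tmap: TMap, samples: pd.DataFrame
) -> tuple[np.ndarray, np.ndarray, int]:
    """t-value of the nearest voxel for each sample.

    Returns ``(t_values, kept_mask, n_dropped)``; samples whose nearest voxel
    is outside the map mask are dropped and counted.
    """
    xyz = samples[["x_mm", "y_mm", "z_mm"]].to_numpy(dtype=float)
    _, nearest, inside = world_to_voxel(tmap.image, xyz)
    tvals = np.full(len(samples), np.nan)
    if inside.any():
        nb = nearest[inside]
        tvals[inside] = tmap.image.data[nb[:, 0], nb[:, 1], nb[:, 2]]
    kept = inside & np.isfinite(tvals)
    if not kept.any():
        raise ValueError("no samples fall inside the t-map mask")
    return tvals, kept, int((~kept).sum())


def build_mem_basis(
    coords: np.ndarray,
    k: int | None = None,
    rule: str = "half",
) -> MEMBasis:
    """Moran eigenvector maps from inverse-distance weights.

    W = 1/d_ij (zero diagonal) is doubly centred (H W H, H the centering
    matrix) and eigendecomposed.  Eigenvectors with positive eigenvalue
    represent positively autocorrelated patterns; their Moran's I is
    proportional to the eigenvalue.  Retention:

    * ``k`` given — the top-k eigenvectors by eigenvalue;
    * ``rule="half"`` (default) — the broadest half of the spectrum
      (k = n // 2).  A Gaussian random field's energy extends well past the
      positive-eigenvalue block of the inverse-distance operator, so the
      aggressive default is what keeps residuals close to exchangeable; the
      cost is absorbed signal, compensated by the t-statistic's df term.
    * ``rule="positive-moran"`` — positive-eigenvalue vectors, i.e. those
      whose Moran's I exceeds the expectation -1/(n-1) under no
      autocorrelation.
    """
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    if n < 3:
        raise ValueError("need at least 3 samples for a MEM basis")
    W = inverse_distance_weights(coords)
    H = np.eye(n) - np.ones((n, n)) / n
    M = H @ W @ H
    M = (M + M.T) / 2
    evals, evecs = np.linalg.eigh(M)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    if k is not None:
        if k < 0:
            raise ValueError("k must be nonnegative")
        keep = np.arange(min(k, n))
    elif rule == "half":
        keep = np.arange(n // 2)
    elif rule == "positive-moran":
        keep = np.flatnonzero(evals > 1e-10)
    else:
        raise ValueError(f"unknown retention rule {rule!r}")
    return MEMBasis(vectors=evecs[:, keep], eigenvalues=evals[keep], rule=rule if k is None else f"top-{k}")


def _residualize(x: np.ndarray, Q: np.ndarray) -> np.ndarray:
    return x - Q @ (Q.T @ x)


def adjusted_spearman(
    values_a: np.ndarray,
    values_b: np.ndarray,
    basis: MEMBasis | None = None,
) -> tuple[float, float, float, int]:
    """Partial Spearman correlation given a MEM basis.

    Both variables are rank-transformed (average ranks for ties), each rank
    vector is residualized on [1, basis] and the Pearson correlation of the
    residuals is the adjusted rho.  t = rho * sqrt((n-2-k) / (1-rho^2)),
    z = signed normal quantile of the two-tailed p (|z| capped at Z_MAX).
    With an empty basis this is exactly the classical Spearman rho.

    Returns ``(rho, t_stat, z, n)``.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("inputs must be equal-length 1-D arrays")
    n = len(a)
    if n < 10:
        raise ValueError("need at least 10 paired samples")
    ra = stats.rankdata(a)
    rb = stats.rankdata(b)
    if np.ptp(ra) == 0 or np.ptp(rb) == 0:
        raise ValueError("correlation undefined: constant variable after ranking")
    k = 0 if basis is None else basis.k
    design = np.ones((n, 1)) if k == 0 else np.column_stack([np.ones(n), basis.vectors])
    Q, _ = np.linalg.qr(design)
    res_a = _residualize(ra, Q)
    res_b = _residualize(rb, Q)
    denom = np.sqrt(res_a @ res_a) * np.sqrt(res_b @ res_b)
    if denom == 0:
        raise ValueError("correlation undefined: residual variance is zero")
    rho = float(np.clip((res_a @ res_b) / denom, -1.0, 1.0))
    df = n - 2 - k
    if df <= 0:
        raise ValueError(f"non-positive degrees of freedom (n={n}, k={k})")
    if abs(rho) >= 1.0:
        t = np.inf * np.sign(rho)
        z = Z_MAX * np.sign(rho)
    else:
        t = rho * np.sqrt(df / (1.0 - rho**2))
        p_two = 2.0 * stats.t.sf(abs(t), df)
        z = float(np.sign(rho) * min(stats.norm.isf(p_two / 2), Z_MAX)) if p_two > 0 else Z_MAX * np.sign(rho)
    return rho, float(t), float(z), n


def combine_donors(
    z_scores: np.ndarray, weights: np.ndarray | None = None
) -> tuple[float, float]:
    """Weighted-Z (Stouffer) combination: Z = sum(w z) / sqrt(sum(w^2)).

    Two-tailed p = 2 (1 - Phi(|Z|)).  With equal weights this reduces to the
    classic unweighted Stouffer statistic.
    """
    z = np.asarray(z_scores, dtype=float)
    if z.size == 0:
        raise ValueError("need at least one donor")
    w = np.ones_like(z) if weights is None else np.asarray(weights, dtype=float)
    if w.shape != z.shape:
        raise ValueError("weights must match z-scores")
    denom = np.sqrt(float(w @ w))
    if denom == 0:
        raise ValueError("all combination weights are zero")
    Z = float(w @ z) / denom
    p = float(2.0 * stats.norm.sf(abs(Z)))
    return Z, max(p, np.finfo(float).tiny)


def donor_association(
    donor,
    tmap: TMap,
    basis: MEMBasis | None = None,
    mem_k: int | None = None,
    mem_rule: str = "half",
) -> DonorAssociationResult:
    """Per-probe adjusted Spearman between one donor's expression and a t-map.

    Samples are matched to nearest voxels (off-mask samples dropped); a MEM
    basis is built from the retained sample coordinates unless one is given.
    """
    tvals, kept, n_drop = match_samples_to_map(tmap, donor.samples)
    sub = donor.take_samples(np.flatnonzero(kept))
    t_kept = tvals[kept]
    if basis is None:
        coords = sub.samples[["x_mm", "y_mm", "z_mm"]].to_numpy(dtype=float)
        basis = build_mem_basis(coords, k=mem_k, rule=mem_rule)
    rows = []
    for i in range(sub.n_probes):
        rho, t, z, n = adjusted_spearman(sub.expression[i], t_kept, basis)
        rows.append((rho, t, z, n))
    table = pd.DataFrame(rows, columns=["rho", "t_stat", "z", "n_samples"])
    table.insert(0, "gene_symbol", sub.probes["gene_symbol"].to_numpy())
    table.insert(0, "probe_id", sub.probes["probe_id"].to_numpy())
    return DonorAssociationResult(
        donor_id=donor.donor_id, table=table, n_dropped_samples=n_drop
    )


def combine_probe_results(
    results: list[DonorAssociationResult], weight_scheme: str = "n"
) -> pd.DataFrame:
    """Combine per-donor probe statistics into probe-level Z/p.

    Donor weights: ``"n"`` (sample count, default), ``"sqrt-n"``, or
    ``"equal"``.  Probe T is the weighted mean of per-donor t-statistics with
    the same weights.
    """
    if not results:
        raise ValueError("no donor results to combine")
    schemes = {"n": lambda n: n, "sqrt-n": np.sqrt, "equal": lambda n: np.ones_like(n, dtype=float)}
    if weight_scheme not in schemes:
        raise ValueError(f"unknown weight scheme {weight_scheme!r}")
    long = pd.concat([r.table.assign(donor_id=r.donor_id) for r in results])
    rows = []
    for (probe_id, gene), g in long.groupby(["probe_id", "gene_symbol"], sort=True):
        w = schemes[weight_scheme](g["n_samples"].to_numpy(dtype=float))
        Z, p = combine_donors(g["z"].to_numpy(), w)
        T = float(np.average(g["t_stat"], weights=w))
        rows.append((probe_id, gene, T, Z, p, len(g)))
    return pd.DataFrame(
        rows, columns=["probe_id", "gene_symbol", "T", "Z", "p", "n_donors"]
    )


def gene_level(probe_table: pd.DataFrame) -> CombinedGeneTable:
    """Average probe statistics to gene level.

    Gene T is the mean of its probes' T; the gene Z is the mean of probe Z's
    treated as perfectly correlated (so the mean keeps unit variance — a
    conservative choice for probes measuring the same transcript), and p is
    its two-tailed normal transform.  Probes disagreeing in sign are retained.
    """
    rows = []
    for gene, g in probe_table.groupby("gene_symbol", sort=True):
        T = float(g["T"].mean())
        Z = float(g["Z"].mean())
        p = float(2.0 * stats.norm.sf(abs(Z)))
        rows.append((gene, T, Z, max(p, np.finfo(float).tiny), len(g), int(g["n_donors"].max())))
    table = pd.DataFrame(
        rows, columns=["gene", "T", "Z", "p", "n_probes", "n_donors"]
    ).set_index("gene")
    return CombinedGeneTable(table=table)


def top_fraction_lists(
    genes: CombinedGeneTable, frac: float = 0.1
) -> tuple[list[str], list[str]]:
    """Top-fraction positively and negatively associated gene lists.

    ``ceil(frac * N)`` genes with the largest T form the positive list and
    the same count with the smallest T the negative list; ties break by gene
    symbol so the lists are deterministic, and the two lists are disjoint.
    """
    if not 0 < frac <= 0.5:
        raise ValueError("frac must be in (0, 0.5]")
    t = genes.table
    if len(t) < 10:
        raise ValueError("need at least 10 genes")
    m = int(np.ceil(frac * len(t)))
    symbols = t.index.to_numpy()
    T = t["T"].to_numpy()
    # pos: T desc, symbol asc; neg: T asc, symbol desc — the reverse order,
    # so equal-T ties fill the two lists from opposite alphabetical ends
    pos_order = np.lexsort((symbols, -T))
    pos = list(t.index[pos_order[:m]])
    neg = list(t.index[pos_order[::-1][:m]])
    if set(pos) & set(neg):
        raise ValueError("positive and negative lists overlap; frac too large for N")
    return pos, neg
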