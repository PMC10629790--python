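"""Microarray-style probe filtering, probe selection, normalization and
ROI-level aggregation of donor expression tables.

Two distinct preparation arms exist, mirroring how voxel-level association and
ROI-level topographic analyses consume expression differently:

* the *voxel arm* keeps every probe surviving :func:`filter_probes` (annotation
  + background filters) and correlates each probe with the map;
* the *ROI arm* additionally keeps only probes above background in over half
  of samples (:func:`background_filter`), picks one max-intensity probe per
  gene, assigns samples to parcels within a distance threshold, normalizes
  each gene with a scaled robust sigmoid and averages within then across
  donors.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .images import VolumeImage, voxel_to_world

__all__ = [
    "ProbeTable",
    "DonorExpression",
    "ROIExpressionMatrix",
    "filter_samples",
    "pool_donors",
    "filter_probes",
    "select_probe_max_intensity",
    "background_filter",
    "robust_sigmoid_normalize",
    "assign_samples_to_rois",
    "aggregate_roi_expression",
]

PROBE_COLUMNS = ["probe_id", "gene_symbol", "n_genes_mapped", "intergenic"]


@dataclass
class ProbeTable:
    """Probe annotation + probe x sample expression for one donor (or pooled).

    ``probes`` carries probe_id, gene_symbol (empty string if unmapped),
    n_genes_mapped and an intergenic flag; ``samples`` carries sample_id,
    optional world coordinates (x_mm, y_mm, z_mm), a boolean ``cortical``
    column and a ``hemisphere`` label.  ``above_background`` is a boolean
    matrix aligned with ``expression``.
    """

    probes: pd.DataFrame
    samples: pd.DataFrame
    expression: np.ndarray
    above_background: np.ndarray | None = None
    donor_id: str = ""

    def __post_init__(self) -> None:
        self.expression = np.asarray(self.expression, dtype=float)
        if self.expression.shape != (len(self.probes), len(self.samples)):
            raise ValueError(
                "expression must be (n_probes, n_samples) = "
                f"({len(self.probes)}, {len(self.samples)}), got {self.expression.shape}"
            )
        if self.above_background is not None:
            self.above_background = np.asarray(self.above_background, dtype=bool)
            if self.above_background.shape != self.expression.shape:
                raise ValueError("above_background shape must match expression")

    @property
    def n_probes(self) -> int:
        return len(self.probes)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def take_probes(self, index: np.ndarray) -> "ProbeTable":
        return replace(
            self,
            probes=self.probes.iloc[index].reset_index(drop=True),
            expression=self.expression[index],
            above_background=None
            if self.above_background is None
            else self.above_background[index],
        )

    def take_samples(self, index: np.ndarray) -> "ProbeTable":
        return replace(
            self,
            samples=self.samples.iloc[index].reset_index(drop=True),
            expression=self.expression[:, index],
            above_background=None
            if self.above_background is None
            else self.above_background[:, index],
        )


DonorExpression = ProbeTable


@dataclass
class ROIExpressionMatrix:
    """Gene x ROI expression, donor-averaged; values in [0, 1] if normalized."""

    values: pd.DataFrame  # genes (index) x ROI ids (columns)
    n_donors_per_roi: pd.Series = field(default=None)  # type: ignore[assignment]

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def roi_ids(self) -> list:
        return list(self.values.columns)


def filter_samples(
    t: ProbeTable, hemisphere: str | None = None, cortical: bool | None = None
) -> ProbeTable:
    """Restrict to samples with the given structure labels (applied first)."""
    keep = np.ones(t.n_samples, dtype=bool)
    if hemisphere is not None:
        keep &= (t.samples["hemisphere"] == hemisphere).to_numpy()
    if cortical is not None:
        keep &= t.samples["cortical"].to_numpy(dtype=bool) == cortical
    return t.take_samples(np.flatnonzero(keep))


def pool_donors(donors: list[ProbeTable]) -> ProbeTable:
    """Concatenate donors sample-wise (shared probe annotation required)."""
    if not donors:
        raise ValueError("no donors to pool")
    ref = donors[0].probes["probe_id"]
    for d in donors[1:]:
        if not d.probes["probe_id"].equals(ref):
            raise ValueError("donors must share an identical probe annotation")
    samples = pd.concat(
        [d.samples.assign(donor_id=d.donor_id) for d in donors], ignore_index=True
    )
    expr = np.concatenate([d.expression for d in donors], axis=1)
    ab = None
    if all(d.above_background is not None for d in donors):
        ab = np.concatenate([d.above_background for d in donors], axis=1)
    return ProbeTable(
        probes=donors[0].probes.copy(),
        samples=samples,
        expression=expr,
        above_background=ab,
        donor_id="pooled",
    )


def filter_probes(
    t: ProbeTable, min_cortical_samples: int = 300
) -> tuple[ProbeTable, dict[str, int]]:
    """Sequential annotation/background probe exclusion with per-rule counts.

    Rules, applied in order (a probe failing several is counted under the
    first): (1) maps to more than one gene; (2) intergenic; (3) no gene
    mapping; (4) above background in fewer than ``min_cortical_samples``
    cortical samples.  Survivors all map to exactly one gene.
    """
    p = t.probes
    alive = np.ones(t.n_probes, dtype=bool)
    counts: dict[str, int] = {}

    multi = alive & (p["n_genes_mapped"].to_numpy() > 1)
    counts["multi_gene"] = int(multi.sum())
    alive &= ~multi

    inter = alive & p["intergenic"].to_numpy(dtype=bool)
    counts["intergenic"] = int(inter.sum())
    alive &= ~inter

    gene = p["gene_symbol"].fillna("").astype(str)
    unmapped = alive & (gene == "").to_numpy()
    counts["unmapped"] = int(unmapped.sum())
    alive &= ~unmapped

    if min_cortical_samples > 0:
        if t.above_background is None:
            raise ValueError(
                "above-background flags required for the cortical-sample rule"
            )
        cortical = t.samples["cortical"].to_numpy(dtype=bool)
        n_above = t.above_background[:, cortical].sum(axis=1)
        low = alive & (n_above < min_cortical_samples)
    else:
        low = np.zeros(t.n_probes, dtype=bool)
    counts["low_expression"] = int(low.sum())
    alive &= ~low

    return t.take_probes(np.flatnonzero(alive)), counts


def select_probe_max_intensity(t: ProbeTable) -> ProbeTable:
    """One probe per gene: the one with the highest mean expression.

    Ties break to the lexicographically smallest probe_id, so selection is
    stable across runs.
    """
    mean_expr = t.expression.mean(axis=1)
    df = pd.DataFrame(
        {
            "gene": t.probes["gene_symbol"].to_numpy(),
            "probe_id": t.probes["probe_id"].astype(str).to_numpy(),
            "mean": mean_expr,
            "row": np.arange(t.n_probes),
        }
    )
    df = df.sort_values(["gene", "mean", "probe_id"], ascending=[True, False, True])
    best = df.groupby("gene", sort=True).first()
    return t.take_probes(best["row"].to_numpy())


def background_filter(t: ProbeTable, frac: float = 0.5) -> ProbeTable:
    """Keep probes above background in strictly more than ``frac`` of samples."""
    if t.above_background is None:
        raise ValueError("above-background flags required")
    prop = t.above_background.mean(axis=1)
    return t.take_probes(np.flatnonzero(prop > frac))


def robust_sigmoid_normalize(values: np.ndarray) -> np.ndarray:
    """Scaled robust sigmoid per gene (row): sigmoid(median/IQR) then min-max.

    x -> 1 / (1 + exp(-(x - median) / (IQR / 1.35))), rescaled to [0, 1].
    The 1.35 factor makes IQR/1.35 a normal-consistent scale estimate.
    Monotone in x; raises for genes with zero IQR (degenerate distribution).
    """
    x = np.asarray(values, dtype=float)
    one_d = x.ndim == 1
    x = np.atleast_2d(x)
    if x.shape[1] < 2:
        raise ValueError("need at least 2 values per gene")
    med = np.nanmedian(x, axis=1, keepdims=True)
    q75 = np.nanpercentile(x, 75, axis=1, keepdims=True)
    q25 = np.nanpercentile(x, 25, axis=1, keepdims=True)
    iqr = q75 - q25
    if np.any(iqr == 0):
        bad = np.flatnonzero(iqr.ravel() == 0)
        raise ValueError(f"zero IQR (degenerate distribution) for rows {bad.tolist()}")
    s = 1.0 / (1.0 + np.exp(-(x - med) / (iqr / 1.35)))
    lo = np.nanmin(s, axis=1, keepdims=True)
    hi = np.nanmax(s, axis=1, keepdims=True)
    out = (s - lo) / (hi - lo)
    return out[0] if one_d else out


def assign_samples_to_rois(
    samples: pd.DataFrame, parcellation: VolumeImage, max_dist_mm: float = 2.0
) -> np.ndarray:
    """Assign each sample to the ROI whose parcel contains it, else the
    nearest parcel within ``max_dist_mm`` (distance to nearest labelled voxel
    centre), else -1 (unassigned).

    The parcellation image holds integer labels, 0 = unlabelled.
    """
    labels = np.rint(parcellation.data).astype(int)
    xyz = samples[["x_mm", "y_mm", "z_mm"]].to_numpy(dtype=float)
    inv = np.linalg.inv(parcellation.affine)
    cont = xyz @ inv[:3, :3].T + inv[:3, 3]
    nearest = np.rint(cont).astype(int)
    shape = np.asarray(labels.shape)
    out = np.full(len(samples), -1, dtype=int)
    in_bounds = np.all((nearest >= 0) & (nearest < shape), axis=1)
    nb = nearest[in_bounds]
    direct = labels[nb[:, 0], nb[:, 1], nb[:, 2]]
    out_in = np.where(direct > 0, direct, -1)
    out[in_bounds] = out_in
    todo = np.flatnonzero(out == -1)
    if len(todo):
        lab_idx = np.argwhere(labels > 0)
        lab_world = voxel_to_world(parcellation, lab_idx.astype(float))
        tree = cKDTree(lab_world)
        dist, j = tree.query(xyz[todo])
        ok = dist <= max_dist_mm
        hit = lab_idx[j[ok]]
        out[todo[ok]] = labels[hit[:, 0], hit[:, 1], hit[:, 2]]
    return out


def aggregate_roi_expression(
    donors: list[ProbeTable],
    parcellation: VolumeImage,
    max_dist_mm: float = 2.0,
    background_frac: float = 0.5,
    normalize: bool = True,
) -> ROIExpressionMatrix:
    """ROI-arm pipeline: background filter, max-intensity probe per gene,
    sample-to-ROI assignment, within-donor ROI means, per-gene robust-sigmoid
    normalization across ROIs, then the across-donor mean (two-stage average:
    an ROI missing in one donor takes the mean of donors that have it).
    """
    roi_ids = sorted(int(v) for v in np.unique(np.rint(parcellation.data)) if v > 0)
    per_donor: list[pd.DataFrame] = []
    for d in donors:
        t = background_filter(d, frac=background_frac) if background_frac is not None else d
        mapped = t.probes["gene_symbol"].fillna("").astype(str) != ""
        t = t.take_probes(np.flatnonzero(mapped.to_numpy()))
        t = select_probe_max_intensity(t)
        assign = assign_samples_to_rois(t.samples, parcellation, max_dist_mm)
        genes = t.probes["gene_symbol"].to_numpy()
        mat = pd.DataFrame(np.nan, index=genes, columns=roi_ids, dtype=float)
        for roi in roi_ids:
            cols = np.flatnonzero(assign == roi)
            if len(cols):
                mat[roi] = t.expression[:, cols].mean(axis=1)
        if normalize:
            present = mat.columns[mat.notna().all(axis=0)]
            mat.loc[:, present] = robust_sigmoid_normalize(
                mat[present].to_numpy()
            )
        per_donor.append(mat)
    all_genes = sorted(set().union(*[set(m.index) for m in per_donor]))
    stacked = [m.reindex(index=all_genes) for m in per_donor]
    arr = np.stack([m.to_numpy() for m in stacked])
    have = ~np.isnan(arr)
    counts = have.sum(axis=0)
    sums = np.where(have, arr, 0.0).sum(axis=0)
    mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    n_donors = have[:, 0, :].sum(axis=0)
    values = pd.DataFrame(mean, index=all_genes, columns=roi_ids)
    if values.isna().all(axis=None):
        raise ValueError("no ROI received any donor data")
    return ROIExpressionMatrix(
        values=values,
        n_donors_per_roi=pd.Series(n_donors, index=roi_ids),
    )
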