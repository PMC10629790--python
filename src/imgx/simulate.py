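"""Synthetic inputs with the statistical structure the pipeline assumes.

Every generator is seeded through a single :class:`numpy.random.SeedSequence`
that fans out to per-purpose substreams in a fixed, documented order, so runs
are bit-reproducible and adding a new consumer does not perturb earlier
streams.  Spatial autocorrelation is induced by Gaussian-kernel smoothing of
white noise (the FWHM parameter sets the correlation scale), the simplest
controllable Gaussian-random-field surrogate for the anatomical smoothness of
real maps.

Generated pieces:

* a two-group imaging cohort with a planted voxel-wise group effect and
  covariate contributions (:func:`gen_cohort_images`);
* multi-donor expression tables with planted positively/negatively
  map-coupled gene sets and probe annotations exercising every filter class
  (:func:`gen_donor_expression`);
* a contiguous ROI parcellation with unit-sphere centroids for spin testing
  (:func:`gen_parcellation`);
* a marker-structured cell-type reference with transcript length/GC
  annotations and marker-derived DEG lists (:func:`gen_celltype_reference`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .expression import DonorExpression, ProbeTable
from .glm import TMap
from .images import VolumeImage, voxel_to_world

__all__ = [
    "CohortSpec",
    "ExpressionSpec",
    "CellTypeSpec",
    "SyntheticExpressionSet",
    "smooth_noise_field",
    "gen_cohort_images",
    "gen_donor_expression",
    "gen_parcellation",
    "gen_celltype_reference",
]

#: expression level separating "above background" from background
BACKGROUND_LEVEL = 5.0

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def _substream(seed: int, index: int) -> np.random.Generator:
    """Independent generator #index spawned from the global seed.

    Substream order (fixed contract): cohort covariates = 0, cohort noise = 1,
    expression layout = 2, expression noise = 3, parcellation = 4,
    cell-type reference = 5.
    """
    return np.random.default_rng(np.random.SeedSequence(seed).spawn(index + 1)[index])


def smooth_noise_field(
    shape: tuple[int, int, int],
    fwhm_mm: float,
    voxel_size_mm: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Unit-variance Gaussian white noise smoothed to the given FWHM."""
    x = rng.standard_normal(shape)
    if fwhm_mm > 0:
        sigma_vox = fwhm_mm * _FWHM_TO_SIGMA / voxel_size_mm
        x = gaussian_filter(x, sigma=sigma_vox, mode="nearest")
        sd = x.std()
        if sd > 0:
            x = x / sd
    return x


@dataclass
class CohortSpec:
    """Design of a synthetic two-group imaging cohort.

    ``effect_map`` is the planted per-voxel group effect (case minus
    control); ``covariate_effects`` maps covariate names (age, sex, site,
    tiv) to per-voxel effect images of the standardized covariate.
    """

    n_control: int
    n_case: int
    grid_shape: tuple[int, int, int] = (16, 16, 16)
    voxel_size_mm: float = 2.0
    smooth_fwhm_mm: float = 6.0
    effect_map: np.ndarray | None = None
    covariate_effects: dict[str, np.ndarray] = field(default_factory=dict)
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.grid_shape) < 4:
            raise ValueError("grid dims must be >= 4")
        if self.n_control < 2 or self.n_case < 2:
            raise ValueError("need at least 2 subjects per group")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel_size_mm must be positive")
        if self.effect_map is None:
            self.effect_map = np.zeros(self.grid_shape)
        self.effect_map = np.asarray(self.effect_map, dtype=float)
        if self.effect_map.shape != tuple(self.grid_shape):
            raise ValueError("effect_map shape must equal grid_shape")
        for name, m in self.covariate_effects.items():
            if np.asarray(m).shape != tuple(self.grid_shape):
                raise ValueError(f"covariate effect {name!r} shape mismatch")

    @property
    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[0, 0] = aff[1, 1] = aff[2, 2] = self.voxel_size_mm
        return aff


def gen_cohort_images(spec: CohortSpec) -> tuple[list[VolumeImage], pd.DataFrame]:
    """One image per subject: baseline + group effect + covariates + smooth noise.

    The covariate table has columns subject_id, group ("control"/"case"),
    age, sex ("F"/"M"), site (four categorical sites), tiv.  Numeric
    covariate contributions use the standardized covariate value so effect
    images are in intensity units per SD.
    """
    rng_cov = _substream(spec.seed, 0)
    rng_noise = _substream(spec.seed, 1)
    n = spec.n_control + spec.n_case
    group = np.r_[np.zeros(spec.n_control), np.ones(spec.n_case)]
    age = rng_cov.normal(45.0, 10.0, n)
    sex = rng_cov.choice(["F", "M"], n)
    site = rng_cov.choice(["leiden", "london", "paris", "vancouver"], n)
    tiv = rng_cov.normal(1500.0, 100.0, n)
    cov = pd.DataFrame(
        {
            "subject_id": [f"sub{i:03d}" for i in range(n)],
            "group": np.where(group == 0, "control", "case"),
            "age": age,
            "sex": sex,
            "site": site,
            "tiv": tiv,
        }
    )
    baseline = 100.0
    numeric = {
        "age": (age - age.mean()) / max(age.std(), 1e-12),
        "tiv": (tiv - tiv.mean()) / max(tiv.std(), 1e-12),
        "sex": (sex == "M").astype(float),
        "group": group,
    }
    site_levels = ["leiden", "london", "paris", "vancouver"]
    images = []
    for i in range(n):
        data = baseline + group[i] * spec.effect_map
        for name, m in spec.covariate_effects.items():
            if name.startswith("site_"):
                val = float(site[i] == name.removeprefix("site_"))
            elif name == "site":
                val = float(site_levels.index(site[i]))
            else:
                val = numeric[name][i]
            data = data + val * np.asarray(m, dtype=float)
        noise = smooth_noise_field(
            tuple(spec.grid_shape), spec.smooth_fwhm_mm, spec.voxel_size_mm, rng_noise
        )
        data = data + spec.noise_sd * noise
        images.append(VolumeImage(data=data, affine=spec.affine))
    return images, cov


@dataclass
class ExpressionSpec:
    """Layout of synthetic multi-donor expression coupled to a target map."""

    n_donors: int = 2
    samples_per_donor: int = 200
    n_genes: int = 200
    probes_per_gene_dist: dict[int, float] = field(
        default_factory=lambda: {1: 0.7, 2: 0.2, 3: 0.1}
    )
    pos_gene_frac: float = 0.1
    neg_gene_frac: float = 0.1
    coupling_beta: float = 2.0
    spatial_noise_fwhm_mm: float = 12.0
    noise_sd: float = 1.0
    iid_noise_sd: float = 1.0
    n_bad_probes: dict[str, int] = field(
        default_factory=lambda: {
            "multi_gene": 5,
            "intergenic": 5,
            "unmapped": 5,
            "low_expression": 5,
        }
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.samples_per_donor < 10:
            raise ValueError("samples_per_donor must be >= 10 (rank correlation unstable)")
        if self.pos_gene_frac + self.neg_gene_frac > 1:
            raise ValueError("pos_gene_frac + neg_gene_frac must be <= 1")
        if abs(sum(self.probes_per_gene_dist.values()) - 1.0) > 1e-9:
            raise ValueError("probes_per_gene_dist must sum to 1")


@dataclass
class SyntheticExpressionSet:
    """Donor tables plus the planted ground truth (+1 / -1 / 0 per gene)."""

    donors: list[DonorExpression]
    gene_truth: pd.Series

    @property
    def genes(self) -> list[str]:
        return list(self.gene_truth.index)

    def planted(self, sign: int) -> list[str]:
        return list(self.gene_truth.index[self.gene_truth == sign])


def gen_donor_expression(
    spec: ExpressionSpec, target: TMap
) -> SyntheticExpressionSet:
    """Multi-donor expression with planted map-coupled gene sets.

    Per sample, a planted-positive gene's expression rises with the target
    t-value at its location (slope ``coupling_beta`` per SD of t);
    planted-negative genes fall; null genes carry only spatially smooth noise
    (FWHM ``spatial_noise_fwhm_mm``, amplitude ``noise_sd``).  The probe
    table adds the requested counts of multi-gene, intergenic, unmapped and
    low-expression probes; the last are constructed to sit below the
    background level in well over half of samples.  Sample structure labels
    mark a non-cortical bottom slab and a left/right hemisphere split.
    """
    rng_layout = _substream(spec.seed, 2)
    rng_noise = _substream(spec.seed, 3)
    img = target.image
    mask_idx = np.argwhere(img.mask)
    if len(mask_idx) < spec.samples_per_donor:
        raise ValueError("target mask smaller than samples_per_donor")
    voxel = float(abs(img.affine[0, 0]))

    genes = [f"G{i:04d}" for i in range(spec.n_genes)]
    n_pos = int(round(spec.pos_gene_frac * spec.n_genes))
    n_neg = int(round(spec.neg_gene_frac * spec.n_genes))
    order = rng_layout.permutation(spec.n_genes)
    truth = np.zeros(spec.n_genes, dtype=int)
    truth[order[:n_pos]] = 1
    truth[order[n_pos : n_pos + n_neg]] = -1
    gene_truth = pd.Series(truth, index=genes)

    ks = sorted(spec.probes_per_gene_dist)
    probs = np.array([spec.probes_per_gene_dist[k] for k in ks])
    n_probes_per_gene = rng_layout.choice(ks, size=spec.n_genes, p=probs)

    probe_rows: list[tuple[str, str, int, bool, str]] = []  # id, gene, n_map, intergenic, class
    pid = 0
    for g, npr in zip(genes, n_probes_per_gene):
        for _ in range(int(npr)):
            probe_rows.append((f"P{pid:05d}", g, 1, False, "clean"))
            pid += 1
    bad = spec.n_bad_probes
    for _ in range(bad.get("multi_gene", 0)):
        g = genes[int(rng_layout.integers(spec.n_genes))]
        probe_rows.append((f"P{pid:05d}", g, 2, False, "multi_gene"))
        pid += 1
    for _ in range(bad.get("intergenic", 0)):
        probe_rows.append((f"P{pid:05d}", "", 0, True, "intergenic"))
        pid += 1
    for _ in range(bad.get("unmapped", 0)):
        probe_rows.append((f"P{pid:05d}", "", 0, False, "unmapped"))
        pid += 1
    for j in range(bad.get("low_expression", 0)):
        probe_rows.append((f"P{pid:05d}", f"GLOW{j:03d}", 1, False, "low_expression"))
        pid += 1
    probes = pd.DataFrame(
        probe_rows,
        columns=["probe_id", "gene_symbol", "n_genes_mapped", "intergenic", "probe_class"],
    )

    gene_base = rng_layout.normal(7.5, 0.3, spec.n_genes)
    probe_offset = rng_noise.normal(0.0, 0.1, len(probes))

    # standardized t over the masked map, indexed by voxel
    tvox = img.data[img.mask]
    t_mean, t_sd = tvox.mean(), max(tvox.std(), 1e-12)

    x_mid = img.shape[0] / 2.0
    z_cut = img.shape[2] / 4.0  # bottom slab = non-cortical

    donors = []
    for d in range(spec.n_donors):
        pick = rng_layout.choice(len(mask_idx), spec.samples_per_donor, replace=False)
        vox = mask_idx[pick]
        jitter = rng_layout.uniform(-0.3, 0.3, size=vox.shape)
        xyz = voxel_to_world(img, vox + jitter)
        t_here = (img.data[vox[:, 0], vox[:, 1], vox[:, 2]] - t_mean) / t_sd
        samples = pd.DataFrame(
            {
                "sample_id": [f"d{d}s{j:04d}" for j in range(len(vox))],
                "x_mm": xyz[:, 0],
                "y_mm": xyz[:, 1],
                "z_mm": xyz[:, 2],
                "cortical": vox[:, 2] >= z_cut,
                "hemisphere": np.where(vox[:, 0] < x_mid, "L", "R"),
            }
        )
        # per-gene spatially smooth noise fields evaluated at the samples
        gene_noise = np.empty((spec.n_genes, len(vox)))
        for gi in range(spec.n_genes):
            f = smooth_noise_field(
                img.shape, spec.spatial_noise_fwhm_mm, voxel, rng_noise
            )
            gene_noise[gi] = f[vox[:, 0], vox[:, 1], vox[:, 2]]
        gene_expr = (
            gene_base[:, None]
            + spec.coupling_beta * truth[:, None] * t_here[None, :]
            + spec.noise_sd * gene_noise
            + spec.iid_noise_sd * rng_noise.standard_normal((spec.n_genes, len(vox)))
        )
        expr = np.empty((len(probes), len(vox)))
        for pi, row in enumerate(probes.itertuples(index=False)):
            if row.probe_class == "low_expression":
                base = BACKGROUND_LEVEL - 0.5 + rng_noise.normal(0, 0.8, len(vox))
                expr[pi] = base
            elif row.gene_symbol in gene_truth.index:
                gi = genes.index(row.gene_symbol)
                expr[pi] = gene_expr[gi] + probe_offset[pi] + rng_noise.normal(
                    0, 0.05, len(vox)
                )
            else:  # intergenic / unmapped background signal
                expr[pi] = 6.0 + rng_noise.normal(0, 0.5, len(vox))
        above = expr > BACKGROUND_LEVEL
        donors.append(
            ProbeTable(
                probes=probes.copy(),
                samples=samples,
                expression=expr,
                above_background=above,
                donor_id=f"donor{d}",
            )
        )
    return SyntheticExpressionSet(donors=donors, gene_truth=gene_truth)


def gen_parcellation(
    mask: np.ndarray,
    affine: np.ndarray,
    n_rois: int,
    seed: int = 0,
) -> tuple[VolumeImage, pd.DataFrame]:
    """Voronoi parcellation of the mask with unit-sphere ROI centroids.

    ``n_rois`` seed voxels are drawn at random; every masked voxel takes the
    label of its nearest seed (labels 1..n_rois; Voronoi cells on a lattice
    are contiguous).  Each ROI's world-space centroid, re-centred on the grid
    centre, is projected to the unit sphere for spin testing.
    """
    mask = np.asarray(mask, dtype=bool)
    if n_rois < 10:
        raise ValueError("need at least 10 ROIs")
    idx = np.argwhere(mask)
    if n_rois > len(idx):
        raise ValueError("n_rois exceeds the number of masked voxels")
    rng = _substream(seed, 4)
    seeds = idx[rng.choice(len(idx), n_rois, replace=False)]
    d2 = ((idx[:, None, :] - seeds[None, :, :]) ** 2).sum(axis=2)
    label_of = np.argmin(d2, axis=1) + 1
    labels = np.zeros(mask.shape)
    labels[idx[:, 0], idx[:, 1], idx[:, 2]] = label_of
    img = VolumeImage(data=labels, affine=np.asarray(affine, dtype=float), mask=mask)
    centre = voxel_to_world(img, (np.asarray(mask.shape, dtype=float) - 1) / 2)
    rows = []
    for roi in range(1, n_rois + 1):
        vox = idx[label_of == roi]
        world = voxel_to_world(img, vox.astype(float)).mean(axis=0)
        v = world - centre
        norm = np.linalg.norm(v)
        if norm == 0:  # centroid exactly at grid centre: push along +x
            v, norm = np.array([1.0, 0.0, 0.0]), 1.0
        rows.append((roi, *(v / norm)))
    centroids = pd.DataFrame(rows, columns=["roi", "cx", "cy", "cz"]).set_index("roi")
    return img, centroids


_DEFAULT_CELLTYPES = [
    "astrocyte",
    "neuron",
    "endothelial",
    "microglia",
    "oligodendrocyte",
    "OPC",
]


@dataclass
class CellTypeSpec:
    """Marker-structured cell-type reference design."""

    n_celltypes: int = 4
    markers_per_celltype: int = 10
    marker_fold: float = 4.0
    length_range_bp: tuple[float, float] = (500.0, 10_000.0)
    gc_range: tuple[float, float] = (0.35, 0.65)
    deg_size: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.marker_fold <= 1:
            raise ValueError("marker_fold must exceed 1")
        if self.deg_size > self.markers_per_celltype:
            raise ValueError("deg_size cannot exceed markers_per_celltype")


def gen_celltype_reference(
    spec: CellTypeSpec,
    genes: list[str],
    marker_sets: dict[str, list[str]] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, list[str]]]:
    """Mean-expression reference, gene length/GC table and DEG lists.

    Markers of cell type c have expression ``marker_fold`` in c and 1
    elsewhere, all other genes 1 everywhere, so a marker's specificity is
    fold / (fold + n_celltypes - 1).  DEG lists are ``deg_size`` samples of
    each type's markers.  ``marker_sets`` may pin markers to chosen genes
    (disjointness enforced); otherwise disjoint marker sets are drawn at
    random.
    """
    rng = _substream(spec.seed, 5)
    names = (
        list(marker_sets)
        if marker_sets is not None
        else (_DEFAULT_CELLTYPES * ((spec.n_celltypes // 6) + 1))[: spec.n_celltypes]
    )
    if marker_sets is None:
        need = spec.markers_per_celltype * spec.n_celltypes
        if need > len(genes):
            raise ValueError("marker demand exceeds available genes")
        chosen = rng.choice(len(genes), need, replace=False)
        marker_sets = {
            names[c]: [genes[i] for i in chosen[c * spec.markers_per_celltype : (c + 1) * spec.markers_per_celltype]]
            for c in range(spec.n_celltypes)
        }
    else:
        flat = [g for ms in marker_sets.values() for g in ms]
        if len(flat) != len(set(flat)):
            raise ValueError("marker sets must be disjoint")
        missing = [g for g in flat if g not in set(genes)]
        if missing:
            raise ValueError(f"markers not in gene list: {missing[:10]}")
    mean_expr = pd.DataFrame(1.0, index=genes, columns=list(marker_sets))
    for ct, ms in marker_sets.items():
        mean_expr.loc[ms, ct] = spec.marker_fold
    annot = pd.DataFrame(
        {
            "length_bp": rng.uniform(*spec.length_range_bp, len(genes)),
            "gc": rng.uniform(*spec.gc_range, len(genes)),
        },
        index=genes,
    )
    deg_lists = {
        ct: sorted(rng.choice(ms, spec.deg_size, replace=False))
        for ct, ms in marker_sets.items()
    }
    return mean_expr, annot, deg_lists
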