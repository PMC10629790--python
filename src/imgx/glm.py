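"""Mass-univariate group-difference t-maps with covariates.

Each masked voxel gets an ordinary-least-squares fit of subject intensities on
a shared design matrix; the map stores the contrast t-statistic per voxel.
The unthresholded map is the product — downstream association uses every
cortical voxel, not just suprathreshold ones.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .images import VolumeImage

__all__ = ["DesignMatrix", "TMap", "build_design", "fit_tmap", "correlate_tmaps"]


@dataclass
class DesignMatrix:
    """Subjects x predictors design with a named contrast vector."""

    X: np.ndarray
    names: list[str]
    contrast: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.contrast = np.asarray(self.contrast, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("design must be 2-D (subjects x predictors)")
        if len(self.names) != self.X.shape[1]:
            raise ValueError("one name per predictor required")
        if self.contrast.shape != (self.X.shape[1],):
            raise ValueError("contrast length must equal number of predictors")
        rank = np.linalg.matrix_rank(self.X)
        if rank < self.X.shape[1]:
            collinear = _collinear_columns(self.X, self.names)
            raise ValueError(
                f"rank-deficient design (rank {rank} < {self.X.shape[1]}); "
                f"collinear columns: {collinear}"
            )

    @property
    def n_subjects(self) -> int:
        return self.X.shape[0]

    @property
    def df_resid(self) -> int:
        return self.X.shape[0] - self.X.shape[1]


def _collinear_columns(X: np.ndarray, names: list[str]) -> list[str]:
    """Names of columns that do not increase rank when added left to right."""
    out, cols = [], []
    for j, name in enumerate(names):
        trial = cols + [X[:, j]]
        if np.linalg.matrix_rank(np.column_stack(trial)) == len(cols):
            out.append(name)
        else:
            cols = trial
    return out


@dataclass
class TMap:
    """Per-voxel t-statistics for one contrast.

    ``direction`` records which group difference is coded positive (e.g.
    "control > case" for volume loss, "case > control" for diffusivity).
    Voxels where the t is undefined (zero residual variance) are NaN in
    ``image.data`` and flagged in ``undefined``.
    """

    image: VolumeImage
    df: int
    direction: str = ""
    undefined: np.ndarray | None = None


def build_design(
    covariates: pd.DataFrame,
    contrast: str = "group",
    covars: tuple[str, ...] = ("age", "sex", "site"),
    contrast_positive: str | None = None,
) -> DesignMatrix:
    """Build intercept + contrast column + covariates, one-hot coding factors.

    Categorical covariates (``sex``, ``site`` or any non-numeric column) are
    expanded to indicator columns with the first level dropped.  A
    categorical contrast column becomes a single indicator of the level coded
    positive (``contrast_positive``; defaults to the alphabetically first
    level, e.g. "case" against "control"), so the t-map's direction
    convention is explicit.
    """
    cols: list[np.ndarray] = [np.ones(len(covariates))]
    names = ["intercept"]
    for name in (contrast, *covars):
        col = covariates[name]
        if col.dtype.kind in "OUSb" or isinstance(col.dtype, pd.CategoricalDtype):
            if name == contrast:
                levels = sorted(col.unique())
                if len(levels) != 2:
                    raise ValueError(
                        f"categorical contrast {name!r} must have exactly 2 levels"
                    )
                pos = contrast_positive if contrast_positive is not None else levels[0]
                if pos not in levels:
                    raise ValueError(f"{pos!r} is not a level of {name!r}")
                cols.append((col == pos).to_numpy(dtype=float))
                names.append(name)
                continue
            dummies = pd.get_dummies(col, prefix=name, drop_first=True)
            for c in dummies.columns:
                cols.append(dummies[c].to_numpy(dtype=float))
                names.append(str(c))
        else:
            cols.append(col.to_numpy(dtype=float))
            names.append(name)
    X = np.column_stack(cols)
    cvec = np.zeros(X.shape[1])
    idx = [i for i, n in enumerate(names) if n == contrast or n.startswith(contrast + "_")]
    if not idx:
        raise ValueError(f"contrast column {contrast!r} not found in design")
    cvec[idx[0]] = 1.0
    return DesignMatrix(X=X, names=names, contrast=cvec)


def fit_tmap(
    images: list[VolumeImage], design: DesignMatrix, direction: str = ""
) -> TMap:
    """OLS per masked voxel; t = c'b / sqrt(s2 * c'(X'X)^-1 c), df = n - p.

    Voxels with zero residual variance get NaN and are flagged in
    ``TMap.undefined`` rather than silently zeroed.
    """
    if not images:
        raise ValueError("need at least one image")
    ref = images[0]
    for img in images[1:]:
        if not img.same_grid(ref):
            raise ValueError("all images must share shape and affine")
    mask = np.logical_and.reduce([img.mask for img in images])
    X = design.X
    n, p = X.shape
    if len(images) != n:
        raise ValueError("number of images must equal design rows")
    if n <= p:
        raise ValueError("more predictors than subjects")
    Y = np.stack([img.data[mask] for img in images])  # n x v
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ X.T @ Y
    resid = Y - X @ beta
    df = n - p
    sigma2 = np.einsum("ij,ij->j", resid, resid) / df
    c = design.contrast
    denom2 = sigma2 * float(c @ XtX_inv @ c)
    effect = c @ beta
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = np.where(denom2 > 0, effect / np.sqrt(denom2), np.nan)
    tdata = np.full(ref.shape, np.nan)
    tdata[mask] = tvals
    undef = np.zeros(ref.shape, dtype=bool)
    undef[mask] = ~(denom2 > 0)
    timg = VolumeImage(data=tdata, affine=ref.affine.copy(), mask=mask & ~undef)
    return TMap(image=timg, df=df, direction=direction, undefined=undef)


def correlate_tmaps(a: TMap, b: TMap) -> tuple[float, float]:
    """Pearson r between two t-maps over their shared mask, with two-tailed p."""
    mask = a.image.mask & b.image.mask
    if not a.image.same_grid(b.image):
        raise ValueError("t-maps are not on the same grid")
    x = a.image.data[mask]
    y = b.image.data[mask]
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if len(x) < 3:
        raise ValueError("need at least 3 shared masked voxels")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant map")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
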