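"""Volumetric image container, NIfTI I/O and voxel/world coordinate maps.

A :class:`VolumeImage` bundles a 3-D scalar lattice with the 4x4 affine that
maps 0-based voxel indices to world coordinates in millimetres, plus a boolean
analysis mask of the same shape.  All coordinate math is affine-driven; axis
names (RAS etc.) are display conventions only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "VolumeImage",
    "read_volume",
    "write_volume",
    "voxel_to_world",
    "world_to_voxel",
    "read_coordinate_table",
    "write_coordinate_table",
]


@dataclass
class VolumeImage:
    """3-D scalar lattice + affine (voxel index -> world mm) + analysis mask."""

    data: np.ndarray
    affine: np.ndarray
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"data must be 3-D, got shape {self.data.shape}")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine is not invertible")
        if self.mask is None:
            self.mask = np.ones(self.data.shape, dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.data.shape:
            raise ValueError("mask shape must equal data shape")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def same_grid(self, other: "VolumeImage", atol: float = 1e-8) -> bool:
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=atol
        )


def read_volume(path: str | Path) -> VolumeImage:
    """Read a NIfTI-1 image; mask defaults to finite, nonzero-header-free all-True."""
    path = Path(path)
    try:
        img = nib.load(str(path))
    except Exception as exc:  # pragma: no cover - nibabel error text varies
        raise ValueError(f"cannot read NIfTI file {path}: {exc}") from exc
    data = np.asanyarray(img.dataobj, dtype=float)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D image, got {data.ndim}-D")
    affine = np.asarray(img.affine, dtype=float)
    if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
        raise ValueError(f"{path}: affine is not invertible")
    return VolumeImage(data=data, affine=affine)


def write_volume(img: VolumeImage, path: str | Path) -> None:
    """Write as NIfTI-1 (.nii or .nii.gz); data stored float32, affine exact."""
    out = nib.Nifti1Image(img.data.astype(np.float32), img.affine)
    nib.save(out, str(path))


def voxel_to_world(img: VolumeImage, ijk: np.ndarray) -> np.ndarray:
    """Map (continuous) voxel indices, shape (..., 3), to world mm."""
    ijk = np.asarray(ijk, dtype=float)
    return ijk @ img.affine[:3, :3].T + img.affine[:3, 3]


def world_to_voxel(
    img: VolumeImage, xyz_mm: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Map world mm to voxel space.

    Returns ``(continuous index, nearest index, inside_mask)`` where the
    nearest index is componentwise rounding (ties to even) of the continuous
    index and ``inside_mask`` is False for points off the grid or where the
    image mask is False.
    """
    xyz = np.atleast_2d(np.asarray(xyz_mm, dtype=float))
    inv = np.linalg.inv(img.affine)
    cont = xyz @ inv[:3, :3].T + inv[:3, 3]
    nearest = np.rint(cont).astype(int)
    shape = np.asarray(img.shape)
    in_bounds = np.all((nearest >= 0) & (nearest < shape), axis=1)
    inside = np.zeros(len(nearest), dtype=bool)
    if in_bounds.any():
        nb = nearest[in_bounds]
        inside[in_bounds] = img.mask[nb[:, 0], nb[:, 1], nb[:, 2]]
    if np.asarray(xyz_mm).ndim == 1:
        return cont[0], nearest[0], inside[0]
    return cont, nearest, inside


_COORD_COLUMNS = ["id", "x_mm", "y_mm", "z_mm"]


def read_coordinate_table(path: str | Path) -> pd.DataFrame:
    """Read a TSV coordinate table with columns id, x_mm, y_mm, z_mm, ..."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _COORD_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing coordinate columns {missing}")
    xyz = df[["x_mm", "y_mm", "z_mm"]].to_numpy(dtype=float)
    if not np.all(np.isfinite(xyz)):
        raise ValueError(f"{path}: non-finite coordinates")
    return df


def write_coordinate_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)
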