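"""Volume containers, NIfTI I/O, and grid resampling.

Conventions: RAS+ world space in millimetres, 0-based voxel indices, and a
voxel's world position given by ``affine @ (i, j, k, 1)``.  Images are
assumed brain-extracted with a zero background, so out-of-field voxels
introduced by resampling are filled with 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
from scipy import ndimage


class VolumeError(ValueError):
    """Raised for invalid volume data, headers, or grid mismatches."""


@dataclass
class Volume:
    """A 3D scalar grid with voxel-to-world affine geometry.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Scalar values; must be finite everywhere.
    affine : ndarray, shape (4, 4)
        Voxel-to-world transform in mm (RAS+).
    """

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise VolumeError(
                f"expected a 3D volume, got {self.data.ndim}D data"
            )
        if self.affine.shape != (4, 4):
            raise VolumeError("affine must be 4x4")
        if not np.all(np.isfinite(self.data)):
            raise VolumeError("volume data contains NaN/Inf")

    @property
    def voxel_size(self) -> np.ndarray:
        """Per-axis voxel size in mm (column norms of the affine 3x3 block)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def shape(self) -> tuple:
        return self.data.shape

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        """Map voxel indices (..., 3) to world coordinates in mm."""
        ijk = np.asarray(ijk, dtype=float)
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    def world_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        xyz = np.asarray(xyz, dtype=float)
        inv = np.linalg.inv(self.affine)
        return xyz @ inv[:3, :3].T + inv[:3, 3]

    def world_grid(self) -> np.ndarray:
        """World coordinates of all voxel centers, shape (nx, ny, nz, 3)."""
        idx = np.stack(
            np.meshgrid(*[np.arange(n) for n in self.shape], indexing="ij"),
            axis=-1,
        )
        return self.voxel_to_world(idx)

    def copy_with(self, data: np.ndarray) -> "Volume":
        return Volume(np.asarray(data), self.affine.copy())

    def same_grid(self, other: "Volume", atol: float = 1e-5) -> bool:
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=atol
        )


def _check_same_grid(a: Volume, b: Volume) -> None:
    if not a.same_grid(b):
        raise VolumeError("volumes are not on the same grid")


class BinaryMask(Volume):
    """A label volume with values exactly 0 or 1."""

    def __post_init__(self) -> None:
        super().__post_init__()
        vals = np.unique(self.data)
        if not np.all(np.isin(vals, (0, 1))):
            raise VolumeError("binary mask values must be exactly 0 or 1")
        self.data = self.data.astype(np.uint8)

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())


class SoftMask(Volume):
    """A label volume with values in [0, 1]."""

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.data.min() < 0 or self.data.max() > 1:
            raise VolumeError("soft mask values must lie in [0, 1]")
        self.data = self.data.astype(float)


def read_volume(path) -> Volume:
    """Read a 3D NIfTI-1 volume (.nii or .nii.gz).

    Data is cast to floating point; affine and voxel size come from the
    header (sform/qform as resolved by nibabel).
    """
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several distinct types
        raise IOError(f"cannot read NIfTI volume at {path!r}: {exc}") from exc
    if img.ndim != 3:
        raise VolumeError(
            f"{path!r} is {img.ndim}D; only 3D volumes are supported"
        )
    data = np.asarray(img.get_fdata(dtype=np.float64))
    if not np.all(np.isfinite(data)):
        raise VolumeError(f"{path!r} contains non-finite voxels")
    return Volume(data, np.asarray(img.affine, dtype=float))


def read_mask(path, soft: bool = False):
    """Read a mask volume; binarity is validated unless ``soft``."""
    v = read_volume(path)
    if soft:
        return SoftMask(np.clip(v.data, 0.0, 1.0), v.affine)
    return BinaryMask((v.data > 0.5).astype(np.uint8), v.affine)


def write_volume(v: Volume, path) -> None:
    """Write a Volume as NIfTI-1, setting both qform and sform."""
    img = nib.Nifti1Image(np.asarray(v.data), v.affine)
    img.header.set_qform(v.affine, code=1)
    img.header.set_sform(v.affine, code=1)
    nib.save(img, str(path))


def resample(v: Volume, target_voxel, mode: str = "linear") -> Volume:
    """Resample onto a grid with the given voxel size, covering the same
    world-space extent.

    ``linear`` uses trilinear interpolation, ``nearest`` preserves the value
    set of the input.  Out-of-field voxels fill with 0.
    """
    target_voxel = np.asarray(target_voxel, dtype=float)
    if target_voxel.shape != (3,) or np.any(target_voxel <= 0):
        raise ValueError("target voxel size must be 3 positive values (mm)")
    if mode not in ("linear", "nearest"):
        raise ValueError(f"unknown resampling mode {mode!r}")

    src = v.voxel_size
    shape = np.asarray(v.shape)
    # Direction cosines (unit columns) are preserved; spacing changes.
    directions = v.affine[:3, :3] / src
    new_shape = np.maximum(1, np.round(shape * src / target_voxel)).astype(int)
    new_affine = np.eye(4)
    new_affine[:3, :3] = directions * target_voxel
    # Keep the world-space field-of-view edge fixed: the edge sits half a
    # voxel before the first voxel center along each grid axis.
    edge = v.affine[:3, 3] - directions @ (0.5 * src)
    new_affine[:3, 3] = edge + directions @ (0.5 * target_voxel)

    # Source voxel coordinate of each target voxel center.
    transform = np.linalg.inv(v.affine) @ new_affine
    order = 1 if mode == "linear" else 0
    data = ndimage.affine_transform(
        np.asarray(v.data, dtype=float),
        transform[:3, :3],
        offset=transform[:3, 3],
        output_shape=tuple(new_shape),
        order=order,
        mode="constant",
        cval=0.0,
    )
    return Volume(data, new_affine)


def resample_mask(m: Volume, target_voxel, threshold: float = 0.5):
    """Resample a mask: linear interpolation then threshold (binary input)
    or clip to [0, 1] (soft input)."""
    out = resample(Volume(np.asarray(m.data, dtype=float), m.affine),
                   target_voxel, mode="linear")
    if isinstance(m, BinaryMask) or np.all(np.isin(np.unique(m.data), (0, 1))):
        return BinaryMask((out.data > threshold).astype(np.uint8), out.affine)
    return SoftMask(np.clip(out.data, 0.0, 1.0), out.affine)


def resample_to_grid(v: Volume, target: Volume, mode: str = "linear") -> Volume:
    """Resample ``v`` onto the exact grid (shape + affine) of ``target``."""
    if mode not in ("linear", "nearest"):
        raise ValueError(f"unknown resampling mode {mode!r}")
    transform = np.linalg.inv(v.affine) @ target.affine
    data = ndimage.affine_transform(
        np.asarray(v.data, dtype=float),
        transform[:3, :3],
        offset=transform[:3, 3],
        output_shape=target.shape,
        order=1 if mode == "linear" else 0,
        mode="constant",
        cval=0.0,
    )
    return Volume(data, target.affine.copy())
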