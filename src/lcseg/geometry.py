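"""Landmark-driven construction of the presumptive LC mask.

The locus coeruleus shows no contrast on T1-weighted images, so its
neighbourhood is located purely from dimensional landmarks: ~3 mm lateral
of the midline, ~1 mm rostral of the fourth-ventricle floor, and 16-20 mm
above the pontomedullary junction (PMJ).  This module codifies that manual
protocol as an analytic, rigid-equivariant mask construction, plus the
morphology and Dice-cap arithmetic that go with an intentionally inflated
region.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage

from .io_core import BinaryMask, Volume


class GeometryError(ValueError):
    """Raised when landmarks place the mask outside the image grid."""


@dataclass
class Plane:
    """World-space plane given by a point on it and a unit normal."""

    point: np.ndarray
    normal: np.ndarray

    def __post_init__(self):
        self.point = np.asarray(self.point, dtype=float)
        n = np.asarray(self.normal, dtype=float)
        self.normal = n / np.linalg.norm(n)

    def signed_distance(self, xyz) -> np.ndarray:
        return (np.asarray(xyz, dtype=float) - self.point) @ self.normal


@dataclass
class LandmarkSet:
    """Midline plane, fourth-ventricle floor reference point, and PMJ plane.

    Sign conventions: ``midline_plane.normal`` points toward the subject's
    right, ``pmj_plane.normal`` points rostrally (superior).  The anterior
    direction is derived as ``pmj_normal x midline_normal``.
    """

    midline_plane: Plane
    ventricle_ref: np.ndarray
    pmj_plane: Plane

    def __post_init__(self):
        self.ventricle_ref = np.asarray(self.ventricle_ref, dtype=float)
        cosang = abs(float(self.midline_plane.normal @ self.pmj_plane.normal))
        if cosang > np.sin(np.deg2rad(5.0)):
            raise GeometryError(
                "midline and PMJ plane normals must be perpendicular "
                f"within 5 degrees (|cos|={cosang:.3f})"
            )
        if self.pmj_plane.signed_distance(self.ventricle_ref) <= 0:
            raise GeometryError("ventricle_ref must lie above the PMJ plane")

    def frame(self):
        """Right-handed (lateral, anterior, superior) unit frame."""
        e_sup = self.pmj_plane.normal
        e_lat = self.midline_plane.normal
        # Orthogonalize lateral against superior (they are near-perpendicular
        # by the invariant) and complete the frame.
        e_lat = e_lat - (e_lat @ e_sup) * e_sup
        e_lat = e_lat / np.linalg.norm(e_lat)
        e_ant = np.cross(e_sup, e_lat)
        return e_lat, e_ant, e_sup

    def to_dict(self) -> dict:
        return {
            "midline_plane": {
                "point": self.midline_plane.point.tolist(),
                "normal": self.midline_plane.normal.tolist(),
            },
            "ventricle_ref": self.ventricle_ref.tolist(),
            "pmj_plane": {
                "point": self.pmj_plane.point.tolist(),
                "normal": self.pmj_plane.normal.tolist(),
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LandmarkSet":
        return cls(
            midline_plane=Plane(**d["midline_plane"]),
            ventricle_ref=np.asarray(d["ventricle_ref"], dtype=float),
            pmj_plane=Plane(**d["pmj_plane"]),
        )


@dataclass
class GeometryParams:
    """Parameters of the landmark rule.

    ``mask_length`` defaults to the height of the PMJ band (4 mm) and the
    mask diameter is solved from ``target_volume`` (the mean volume of the
    manually drawn presumptive regions, 19.7 mm^3).  ``rostral_sign`` flips
    the direction of the 1 mm fourth-ventricle offset, which anatomical
    protocols describe loosely.
    """

    lateral_offset: float = 3.0
    rostral_offset: float = 1.0
    pmj_band: tuple = (16.0, 20.0)
    mask_length: Optional[float] = None
    mask_diameter: Optional[float] = None
    target_volume: float = 19.7
    taper_exponent: float = 0.25
    rostral_sign: float = 1.0

    def __post_init__(self):
        if self.lateral_offset < 0 or self.rostral_offset < 0:
            raise ValueError("offsets must be non-negative")
        lo, hi = self.pmj_band
        if not lo < hi:
            raise ValueError("pmj_band must be an increasing interval")


def _taper_integral(q: float, n: int = 2001) -> float:
    # \int_{-1}^{1} (1-u^2)^q du via Simpson on a fine grid.
    u = np.linspace(-1.0, 1.0, n)
    from scipy.integrate import simpson

    return float(simpson((1.0 - u**2) ** q, x=u))


def geometric_lc_mask(
    landmarks: LandmarkSet,
    side: str,
    grid: Volume,
    params: GeometryParams = None,
) -> BinaryMask:
    """Construct the presumptive LC mask for one side from landmarks.

    The mask is an axis-aligned tapered cylinder (radius profile
    ``r0 * (1-u^2)^taper``) centred 3 mm lateral of the midline on the
    requested side, 1 mm along the anterior normal from the ventricle
    reference, spanning the 16-20 mm band above the PMJ plane.  A voxel
    belongs to the mask iff its center lies inside the analytic shape.
    """
    if params is None:
        params = GeometryParams()
    if side not in ("left", "right"):
        raise ValueError(f"side must be 'left' or 'right', got {side!r}")
    e_lat, e_ant, e_sup = landmarks.frame()
    sign = 1.0 if side == "right" else -1.0

    lo, hi = params.pmj_band
    length = params.mask_length if params.mask_length else (hi - lo)
    q = 2.0 * params.taper_exponent
    if params.mask_diameter:
        r0 = 0.5 * params.mask_diameter
    else:
        # Solve pi r0^2 (L/2) \int (1-u^2)^{2t} du = target_volume.
        r0 = float(
            np.sqrt(
                params.target_volume
                / (np.pi * (length / 2.0) * _taper_integral(q))
            )
        )

    # Center: ventricle reference projected onto the midline plane, offset
    # laterally/anteriorly, then pinned to the middle of the PMJ band.
    p0 = landmarks.ventricle_ref - landmarks.midline_plane.signed_distance(
        landmarks.ventricle_ref
    ) * landmarks.midline_plane.normal
    c = (
        p0
        + sign * params.lateral_offset * e_lat
        + params.rostral_sign * params.rostral_offset * e_ant
    )
    c = c + (0.5 * (lo + hi) - landmarks.pmj_plane.signed_distance(c)) * e_sup

    def rasterize(r0_: float) -> np.ndarray:
        xyz = grid.world_grid()
        d = xyz - c
        w = d @ e_sup
        rho2 = np.einsum("...i,...i->...", d, d) - w**2
        u = np.clip(2.0 * w / length, -1.0, 1.0)
        rad = r0_ * (1.0 - (2.0 * w / length) ** 2).clip(min=0.0) ** (
            params.taper_exponent
        )
        return (np.abs(w) <= length / 2.0) & (rho2 <= rad**2)

    inside = rasterize(r0)
    # Refine the radius so the discrete volume honours the target within
    # voxelization noise (deterministic fixed-point, two passes).
    vox_vol = float(np.prod(grid.voxel_size))
    if params.mask_diameter is None:
        for _ in range(2):
            count = int(inside.sum())
            if count == 0:
                break
            factor = np.sqrt(params.target_volume / (count * vox_vol))
            if abs(1.0 - factor) < 0.02:
                break
            r0 *= factor
            inside = rasterize(r0)

    if not inside.any():
        raise GeometryError(
            "landmark-defined slab does not intersect the image grid"
        )
    return BinaryMask(inside.astype(np.uint8), grid.affine.copy())


def ball_structure(radius_mm: float, voxel_size) -> np.ndarray:
    """Boolean ball footprint of a given physical radius on a voxel grid."""
    voxel_size = np.asarray(voxel_size, dtype=float)
    r = np.maximum(0, np.floor(radius_mm / voxel_size)).astype(int)
    grids = np.meshgrid(
        *[np.arange(-n, n + 1) * s for n, s in zip(r, voxel_size)],
        indexing="ij",
    )
    dist2 = sum(g**2 for g in grids)
    return dist2 <= radius_mm**2 + 1e-9


def erode_mask(m: BinaryMask, radius_mm: float) -> BinaryMask:
    """Morphological erosion with a ball of the given physical radius.

    Radius 0 is the identity; the result is always a subset of the input.
    """
    if radius_mm < 0:
        raise ValueError("erosion radius must be non-negative")
    if radius_mm == 0:
        return BinaryMask(m.data.copy(), m.affine.copy())
    struct = ball_structure(radius_mm, m.voxel_size)
    out = ndimage.binary_erosion(m.data.astype(bool), structure=struct)
    return BinaryMask(out.astype(np.uint8), m.affine.copy())


def mask_volume(m: Volume) -> float:
    """Mask volume in mm^3 (voxel count x voxel volume; sums soft values)."""
    return float(np.sum(m.data) * np.prod(m.voxel_size))


def dice_cap(alpha: float) -> float:
    """Maximal attainable Dice between a region and a contained label whose
    volume is ``alpha`` times smaller: 2 / (1 + alpha)."""
    if alpha <= 0:
        raise ValueError("volume ratio alpha must be positive")
    return 2.0 / (1.0 + alpha)
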