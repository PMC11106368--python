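"""Seeded synthetic brainstem phantom with ground-truth LC labels.

Each phantom emulates, at (0.7 mm)^3 resolution, the anatomy the landmark
protocol relies on: a brainstem column that narrows below the
pontomedullary junction, a fourth-ventricle CSF wedge dorsal to the pons,
and a bilateral locus coeruleus truth label — a thin spindle ~14.5 mm long
whose diameter peaks at 2-2.5 mm near its center, with a per-side volume
around 7 mm^3.  Crucially the LC itself is painted with *pons* intensity:
T1-weighted images carry no LC contrast, so localizers must work from the
surrounding geometry alone.  An enlarged "presumptive" mask (dilated truth,
~19.7 mm^3 per side) plays the role of the manually drawn region.

A ``site`` knob emulates acquisition domain shift (3T vs 7T): site B applies
a monotone gamma remap of the intensities and increases the noise, while
the truth geometry for a given seed is bit-identical across sites.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List

import numpy as np
from scipy import ndimage

from .geometry import LandmarkSet, Plane
from .io_core import BinaryMask, Volume


class PhantomError(ValueError):
    """Raised for phantom specifications the grid cannot accommodate."""


# Tissue means in arbitrary T1w-like units.
PONS_INTENSITY = 100.0
CSF_INTENSITY = 30.0

# LC truth shape (mm): thin filament with a fusiform mid bulge.  The base
# radius and bulge were calibrated once against the literature label scale
# (~7 mm^3 per side) on the default grid.
LC_LENGTH = 14.5
LC_BASE_RADIUS = 0.26
LC_PEAK_RADIUS = 0.95
LC_BULGE_SIGMA = 1.3
# Margin (mm) added around the truth for the enlarged presumptive mask,
# calibrated so the per-side mask volume lands near 19.7 mm^3.
MASK_MARGIN = 0.22
MASK_EXTRA_LENGTH = 1.0

# Geometry of the background anatomy (world mm, grid-centred coordinates).
PMJ_Z = -22.0          # pontomedullary junction plane
VENTRICLE_FLOOR_Y = -8.0
LC_BAND_CENTER = 18.0  # mm above the PMJ plane
LATERAL_OFFSET = 3.0   # mm lateral of the midline


@dataclass
class PhantomSpec:
    """Generation parameters; the seed fully determines the output."""

    grid_shape: tuple = (64, 64, 96)
    voxel_size: float = 0.7
    seed: int = 0
    site: str = "A"
    noise_sigma: float = 5.0
    bias_amplitude: float = 0.10
    jitter_mm: float = 1.0
    shape_jitter: float = 0.10
    site_b_gamma: float = 0.8
    site_b_noise_factor: float = 1.5

    def __post_init__(self):
        if self.site not in ("A", "B"):
            raise PhantomError(f"site must be 'A' or 'B', got {self.site!r}")
        extent = np.asarray(self.grid_shape) * self.voxel_size
        if extent[2] < 60.0 or extent[0] < 30.0 or extent[1] < 30.0:
            raise PhantomError(
                "grid too small to contain a 60 mm brainstem segment: "
                f"extent {extent.round(1).tolist()} mm"
            )


@dataclass
class TrainingCase:
    """One phantom subject: image, truth labels, enlarged masks, landmarks."""

    image: Volume
    lc_left: BinaryMask
    lc_right: BinaryMask
    mask_left: BinaryMask
    mask_right: BinaryMask
    landmarks: LandmarkSet
    subject_id: str = ""

    def truth(self, side: str) -> BinaryMask:
        return self.lc_left if side == "left" else self.lc_right

    def mask(self, side: str) -> BinaryMask:
        if side == "left":
            return self.mask_left
        if side == "right":
            return self.mask_right
        raise ValueError(f"side must be 'left' or 'right', got {side!r}")


def _centered_affine(shape, voxel) -> np.ndarray:
    aff = np.diag([voxel, voxel, voxel, 1.0])
    aff[:3, 3] = -(np.asarray(shape) - 1) / 2.0 * voxel
    return aff


def _lc_radius_profile(z, length, r_base, r_peak, sigma):
    """Radius (mm) at signed axial position z (mm from center)."""
    u = np.clip(2.0 * z / length, -1.0, 1.0)
    taper = (1.0 - u**2).clip(min=0.0) ** 0.25
    return r_base * taper + (r_peak - r_base) * np.exp(
        -(z**2) / (2.0 * sigma**2)
    )


def _rasterize_spindle(xyz, center, length, r_base, r_peak, sigma,
                       supersample=3):
    """Coverage-fraction voxelization of a z-axis spindle.

    A voxel is inside when >= 50% of a supersampled set of points within it
    falls inside the analytic surface.  Monotone in the radius profile, so
    a dilated profile always contains the original voxel set.
    """
    nx, ny, nz, _ = xyz.shape
    # Bounding box in voxel space to keep the supersampling local.
    vox = xyz[1, 0, 0, 0] - xyz[0, 0, 0, 0] if nx > 1 else 0.7
    lo_w = np.asarray(center) - np.asarray(
        [r_peak + 2 * vox, r_peak + 2 * vox, length / 2 + 2 * vox])
    hi_w = np.asarray(center) + np.asarray(
        [r_peak + 2 * vox, r_peak + 2 * vox, length / 2 + 2 * vox])
    origin = xyz[0, 0, 0]
    lo = np.maximum(0, np.floor((lo_w - origin) / vox)).astype(int)
    hi = np.minimum([nx - 1, ny - 1, nz - 1],
                    np.ceil((hi_w - origin) / vox)).astype(int)
    out = np.zeros((nx, ny, nz), dtype=bool)
    if np.any(hi < lo):
        return out

    s = supersample
    offs = (np.arange(s) + 0.5) / s - 0.5  # sub-voxel offsets in voxel units
    sub = np.stack(np.meshgrid(offs, offs, offs, indexing="ij"),
                   axis=-1).reshape(-1, 3) * vox

    box = xyz[lo[0]:hi[0] + 1, lo[1]:hi[1] + 1, lo[2]:hi[2] + 1]
    pts = box[..., None, :] + sub  # (bx, by, bz, s^3, 3)
    d = pts - np.asarray(center)
    rad = _lc_radius_profile(d[..., 2], length, r_base, r_peak, sigma)
    inside = (np.abs(d[..., 2]) <= length / 2.0) & (
        d[..., 0] ** 2 + d[..., 1] ** 2 <= rad**2
    )
    frac = inside.mean(axis=-1)
    out[lo[0]:hi[0] + 1, lo[1]:hi[1] + 1, lo[2]:hi[2] + 1] = frac >= 0.5
    return out


def _smooth_bias(shape, amplitude, rng):
    """Smooth multiplicative bias field in [1-a, 1+a]."""
    coarse = rng.standard_normal((4, 4, 6))
    fine = ndimage.zoom(coarse, np.asarray(shape) / np.asarray(coarse.shape),
                        order=3)
    fine = fine[: shape[0], : shape[1], : shape[2]]
    span = np.abs(fine).max()
    if span > 0:
        fine = fine / span
    return 1.0 + amplitude * fine


def make_phantom(spec: PhantomSpec) -> TrainingCase:
    """Generate one phantom subject from a spec (fully seed-determined)."""
    shape = tuple(int(n) for n in spec.grid_shape)
    affine = _centered_affine(shape, spec.voxel_size)
    grid = Volume(np.zeros(shape), affine)
    xyz = grid.world_grid()
    X, Y, Z = xyz[..., 0], xyz[..., 1], xyz[..., 2]

    rng_geom = np.random.default_rng([int(spec.seed), 11])
    rng_int = np.random.default_rng([int(spec.seed), 13])

    j = spec.jitter_mm
    # Shared landmark jitter (bounded uniform so symmetry bounds hold
    # deterministically): midline shift is kept small relative to the
    # per-landmark jitter of the ventricle/PMJ references.
    mid_x = rng_geom.uniform(-0.25 * j, 0.25 * j)
    vent = np.array([mid_x,
                     VENTRICLE_FLOOR_Y + rng_geom.uniform(-j, j),
                     LC_BAND_CENTER + PMJ_Z + rng_geom.uniform(-j, j)])
    pmj_z = PMJ_Z + rng_geom.uniform(-j, j)

    landmarks = LandmarkSet(
        midline_plane=Plane(point=[mid_x, 0.0, 0.0], normal=[1.0, 0.0, 0.0]),
        ventricle_ref=vent,
        pmj_plane=Plane(point=[0.0, 0.0, pmj_z], normal=[0.0, 0.0, 1.0]),
    )

    # Per-side LC placement: the landmark rule plus bounded per-side jitter.
    scale = 1.0 + rng_geom.uniform(-spec.shape_jitter, spec.shape_jitter)
    length = LC_LENGTH * scale
    r_base = LC_BASE_RADIUS * scale
    r_peak = LC_PEAK_RADIUS * scale
    centers = {}
    for side, sgn in (("left", -1.0), ("right", 1.0)):
        delta = rng_geom.uniform(-0.4 * j, 0.4 * j, size=3)
        centers[side] = np.array([
            mid_x + sgn * LATERAL_OFFSET + delta[0],
            vent[1] + 1.0 + delta[1],
            pmj_z + LC_BAND_CENTER + delta[2],
        ])

    truth = {}
    enlarged = {}
    for side in ("left", "right"):
        c = centers[side]
        if np.any(np.abs(c[:2]) > np.asarray(shape[:2]) * spec.voxel_size / 2
                  - 4) or abs(c[2]) > shape[2] * spec.voxel_size / 2 - 10:
            raise PhantomError("grid too small for the LC geometry")
        truth[side] = _rasterize_spindle(
            xyz, c, length, r_base, r_peak, LC_BULGE_SIGMA)
        enlarged[side] = _rasterize_spindle(
            xyz, c, length + 2 * MASK_EXTRA_LENGTH,
            r_base + MASK_MARGIN, r_peak + MASK_MARGIN,
            LC_BULGE_SIGMA + 0.4 * MASK_EXTRA_LENGTH)

    # --- anatomy ---------------------------------------------------------
    # Brainstem column (pons + medulla), narrowing below the PMJ plane.
    narrow = 1.0 - 0.35 / (1.0 + np.exp((Z - pmj_z) / 1.5))
    col = ((X - mid_x) / (13.0 * narrow)) ** 2 + (Y / (10.0 * narrow)) ** 2 \
        + ((Z + 4.0) / 31.0) ** 4
    brainstem = col <= 1.0
    # Fourth-ventricle CSF wedge, dorsal to the pons tegmentum.  The real
    # ventricle is diamond-shaped in the axial-width profile: widest near
    # its middle, narrowing caudally (obex) and rostrally (aqueduct), so
    # the local width encodes rostro-caudal position.
    v_lo, v_hi = pmj_z + 8.0, pmj_z + 34.0
    v_mid = 0.5 * (v_lo + v_hi)
    v_half = 0.5 * (v_hi - v_lo)
    width = 6.5 * (1.0 - np.abs(Z - v_mid) / v_half).clip(min=0.0)
    ventricle = (
        brainstem
        & (Y < vent[1])
        & (Y > vent[1] - 5.0)
        & (np.abs(X - mid_x) < width)
        & (Z > v_lo)
        & (Z < v_hi)
    )

    img = np.zeros(shape)
    img[brainstem] = PONS_INTENSITY
    img[ventricle] = CSF_INTENSITY
    # No LC contrast: truth voxels keep pons intensity.

    img *= _smooth_bias(shape, spec.bias_amplitude, rng_int)
    noise_sigma = spec.noise_sigma
    if spec.site == "B":
        peak = img.max()
        if peak > 0:
            img = peak * (img / peak) ** spec.site_b_gamma
        noise_sigma = spec.noise_sigma * spec.site_b_noise_factor
    img = img + noise_sigma * rng_int.standard_normal(shape)
    img[~brainstem] = np.maximum(img[~brainstem], 0.0) * 0.0  # brain-extracted

    def _bm(arr):
        return BinaryMask(arr.astype(np.uint8), affine.copy())

    return TrainingCase(
        image=Volume(img, affine.copy()),
        lc_left=_bm(truth["left"]),
        lc_right=_bm(truth["right"]),
        mask_left=_bm(enlarged["left"]),
        mask_right=_bm(enlarged["right"]),
        landmarks=landmarks,
        subject_id=f"phantom-{spec.site}-{spec.seed:05d}",
    )


def make_cohort(n: int, base_seed: int = 0, site: str = "A",
                spec: PhantomSpec = None) -> List[TrainingCase]:
    """Generate ``n`` phantom subjects with per-case jitter.

    Case ``i`` uses seed ``base_seed * 1000 + i`` so that cohorts of
    different sites share truth geometry case-by-case.
    """
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    template = spec if spec is not None else PhantomSpec()
    cases = []
    for i in range(int(n)):
        s = replace(template, seed=int(base_seed) * 1000 + i, site=site)
        case = make_phantom(s)
        case.subject_id = f"phantom-{site}-{base_seed:04d}-{i:03d}"
        cases.append(case)
    return cases
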