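"""Expected-Label-Value (ELV) supervised localization.

ELV accumulates, for every atlas and every candidate atlas-to-image
transformation, the transformed atlas label weighted by a transformation
validity score — no deformable registration involved.  This instantiation
uses a grid of 3D voxel translations as the transform family and a softmax
of windowed normalized cross-correlation as the validity measure:

    w_a(T) ∝ exp(sim(T(image_a), test) / kernel_width),   Σ_T w_a(T) = 1
    ELV(x) = (1/|A|) Σ_a Σ_T w_a(T) · [T(label_a)](x)

Similarity over all translations is computed exactly with FFT circular
cross-correlation, identical (to floating-point) to direct sliding-window
dot products.  By default inputs are whitened with the phase transform,
whose near-flat spectrum makes the correlation peak sharp.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
from sklearn.base import BaseEstimator

from .io_core import SoftMask, Volume
from .phase import PhaseParams, normalize_std, phase_image


class ELVLocalizer(BaseEstimator):
    """ELV-style label-fusion localizer (sklearn-style estimator).

    Parameters
    ----------
    side : 'left' or 'right'
        Which enlarged presumptive mask to fuse.
    translation_radius : int or None
        Half-width of the cubic translation grid, in voxels; the family is
        all integer shifts with max-norm <= radius.  ``None`` means the
        full circular family (every integer shift), for which the fused
        map is exactly translation-equivariant; finite families break
        equivariance only by weight truncation at the family boundary.
    kernel_width : float
        Softmax temperature applied to the similarity scores; smaller is
        closer to picking the single best translation.
    window_margin_mm : float
        The similarity window is the union bounding box of the atlas masks
        dilated by this margin.
    use_phase : bool
        Whiten images with the phase transform before matching (default).
    use_intensity_prior : bool
        Multiply the fused map by a Gaussian intensity prior pooled from
        in-mask atlas intensities (the "phase + image" variant).
    """

    def __init__(self, side: str = "left", translation_radius: int = 5,
                 kernel_width: float = 0.01, window_margin_mm: float = 8.0,
                 threshold: float = 0.5, use_phase: bool = True,
                 use_normalize: bool = False,
                 use_intensity_prior: bool = False,
                 epsilon_frac: float = 0.001):
        self.side = side
        self.translation_radius = translation_radius
        self.kernel_width = kernel_width
        self.window_margin_mm = window_margin_mm
        self.threshold = threshold
        self.use_phase = use_phase
        self.use_normalize = use_normalize
        self.use_intensity_prior = use_intensity_prior
        self.epsilon_frac = epsilon_frac

    # -- preprocessing -----------------------------------------------------
    def _preprocess(self, v: Volume) -> np.ndarray:
        out = v
        if self.use_normalize:
            out = normalize_std(out)
        if self.use_phase:
            out = phase_image(out, PhaseParams(self.epsilon_frac))
        return np.asarray(out.data, dtype=float)

    # -- fitting -----------------------------------------------------------
    def fit(self, cases, y=None):
        cases = list(cases)
        if not cases:
            raise ValueError("ELV requires at least one atlas case")
        if not 0 < self.threshold < 1:
            raise ValueError("threshold must lie in (0, 1)")
        if self.translation_radius is not None \
                and self.translation_radius < 0:
            raise ValueError("translation_radius must be >= 0 or None")
        self.atlas_images_ = [self._preprocess(c.image) for c in cases]
        self.atlas_masks_ = [
            np.asarray(c.mask(self.side).data, dtype=float) for c in cases
        ]
        self.affine_ = cases[0].image.affine.copy()
        self.shape_ = cases[0].image.shape
        # Window: union bounding box of atlas masks + margin (voxels).
        union = np.zeros(self.shape_, dtype=bool)
        for m in self.atlas_masks_:
            union |= m > 0
        if not union.any():
            raise ValueError("atlas masks are empty")
        margin = np.ceil(
            self.window_margin_mm / cases[0].image.voxel_size
        ).astype(int)
        idx = np.argwhere(union)
        lo = np.maximum(0, idx.min(axis=0) - margin)
        hi = np.minimum(np.asarray(self.shape_) - 1, idx.max(axis=0) + margin)
        self.window_ = np.zeros(self.shape_, dtype=bool)
        self.window_[lo[0]:hi[0] + 1, lo[1]:hi[1] + 1, lo[2]:hi[2] + 1] = True
        # Raw (unwhitened) data for the intensity prior.
        if self.use_intensity_prior:
            pooled = np.concatenate([
                np.asarray(c.image.data)[c.mask(self.side).data > 0]
                for c in cases
            ])
            self.prior_mean_ = float(pooled.mean())
            self.prior_std_ = float(pooled.std())
            if self.prior_std_ == 0:
                raise ValueError("pooled in-mask intensity std is zero")
        return self

    # -- scoring -----------------------------------------------------------
    def _shift_mask(self) -> np.ndarray:
        """Boolean mask over FFT shift indices belonging to the family."""
        if self.translation_radius is None:
            return np.ones(self.shape_, dtype=bool)
        r = int(self.translation_radius)
        keep = np.zeros(self.shape_, dtype=bool)
        sl = [np.r_[0:min(r, d - 1) + 1, max(d - r, 1):d] if r > 0
              else np.r_[0:1] for d in self.shape_]
        keep[np.ix_(sl[0], sl[1], sl[2])] = True
        return keep

    def similarity_profile(self, test_data: np.ndarray, atlas_data: np.ndarray
                           ) -> np.ndarray:
        """Circular cross-correlation scores for every integer shift t:

        ``score[t] = Σ_x test(x) wa(x - t)``

        where ``wa`` is the atlas image restricted to the scoring window
        (zero-meaned within it, unit-normalized) and the test image is
        zero-meaned and unit-normalized globally.  Windowing the *atlas*
        side keeps the profile exactly translation-equivariant in the test
        image: shifting the test circularly shifts the scores.
        """
        t = test_data - test_data.mean()
        nt = np.linalg.norm(t)
        if nt > 0:
            t = t / nt
        a_in = atlas_data[self.window_]
        wa = np.where(self.window_, atlas_data - a_in.mean(), 0.0)
        na = np.linalg.norm(wa)
        if na > 0:
            wa = wa / na
        # score[t] = Σ_x t(x) wa(x - t), all shifts at once (circular).
        return np.real(
            np.fft.ifftn(np.fft.fftn(t) * np.conj(np.fft.fftn(wa)))
        )

    def transform_weights(self, test_data: np.ndarray, atlas_idx: int
                          ) -> np.ndarray:
        """Per-translation validity weights for one atlas (sum to 1)."""
        score = self.similarity_profile(test_data,
                                        self.atlas_images_[atlas_idx])
        keep = self._shift_mask()
        w = np.zeros(self.shape_)
        s = score[keep]
        s = np.exp((s - s.max()) / self.kernel_width)
        w[keep] = s / s.sum()
        return w

    def predict(self, test: Volume) -> SoftMask:
        """Fuse atlas labels into the expected-label-value soft map."""
        if test.shape != self.shape_:
            raise ValueError(
                f"test grid {test.shape} differs from atlas grid "
                f"{self.shape_}"
            )
        test_data = self._preprocess(test)
        acc = np.zeros(self.shape_)
        for i, mask in enumerate(self.atlas_masks_):
            w = self.transform_weights(test_data, i)
            # Σ_t w(t) mask(x - t) is a circular convolution.
            acc += np.real(np.fft.ifftn(np.fft.fftn(w) * np.fft.fftn(mask)))
        acc /= len(self.atlas_masks_)
        acc = np.clip(acc, 0.0, 1.0)
        if self.use_intensity_prior:
            prior = np.exp(
                -((np.asarray(test.data) - self.prior_mean_) ** 2)
                / (2.0 * self.prior_std_**2)
            )
            acc = acc * prior
        return SoftMask(acc, self.affine_.copy())


def elv_map(test: Volume, atlases, side: str = "left",
            config: Optional[dict] = None) -> SoftMask:
    """Functional wrapper: fit an :class:`ELVLocalizer` and predict."""
    est = ELVLocalizer(side=side, **(config or {}))
    return est.fit(list(atlases)).predict(test)


def intensity_prior(test: Volume, atlases, side: str = "left") -> Volume:
    """Voxelwise Gaussian likelihood of the test intensity under the pooled
    in-mask atlas intensity distribution, rescaled to peak 1."""
    atlases = list(atlases)
    if not atlases:
        raise ValueError("intensity prior requires at least one atlas")
    pooled = np.concatenate([
        np.asarray(c.image.data)[c.mask(side).data > 0] for c in atlases
    ])
    mu, sd = float(pooled.mean()), float(pooled.std())
    if sd == 0:
        raise ValueError("pooled in-mask intensity std is zero")
    field = np.exp(-((np.asarray(test.data) - mu) ** 2) / (2.0 * sd**2))
    return test.copy_with(field)
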