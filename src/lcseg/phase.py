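"""Spectral-whitening "phase image" and intensity normalization.

The phase image is the real part of the inverse Fourier transform of an
image's spectrum divided by its magnitude: it discards the Fourier
magnitude (which carries most inter-scanner intensity variation) while
keeping spatial structure as enhanced edges.  Division is regularized by a
constant equal to ``epsilon_frac`` times the norm of the Fourier transform.
This is a whitening transform of the magnitude image, not scanner phase
data.

Both transforms are exposed as sklearn-style transformers so they compose
with pipelines; the module-level functions are thin wrappers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .io_core import Volume


@dataclass
class PhaseParams:
    epsilon_frac: float = 0.001
    norm: str = "l2"  # 'l2' (Frobenius over all coefficients) or 'linf'

    def __post_init__(self):
        if self.epsilon_frac < 0:
            raise ValueError("epsilon_frac must be non-negative")
        if self.norm not in ("l2", "linf"):
            raise ValueError("norm must be 'l2' or 'linf'")


def _phase_array(data: np.ndarray, epsilon_frac: float, norm: str
                 ) -> np.ndarray:
    data = np.asarray(data, dtype=float)
    F = np.fft.fftn(data)
    mag = np.abs(F)
    if norm == "l2":
        scale = np.sqrt(np.sum(mag**2))
    else:
        scale = mag.max()
    if scale == 0:
        raise ValueError("phase image undefined for an all-zero input")
    out = np.fft.ifftn(F / (mag + epsilon_frac * scale))
    return np.real(out)


def phase_image(v: Volume, params: PhaseParams = None) -> Volume:
    """Whole-volume 3D phase image (see module docstring).

    Invariant to global positive rescaling of the input: scaling the input
    by c scales the spectrum, its magnitude, and the regularizer equally.
    """
    if params is None:
        params = PhaseParams()
    return v.copy_with(_phase_array(v.data, params.epsilon_frac, params.norm))


def normalize_std(v: Volume, foreground_only: bool = True) -> Volume:
    """Divide by the intensity standard deviation.

    With ``foreground_only`` (default) the std is computed over nonzero
    voxels, matching brain-extracted inputs with a zero background.
    """
    data = np.asarray(v.data, dtype=float)
    sel = data[data != 0] if foreground_only else data.ravel()
    if sel.size == 0:
        raise ValueError("no foreground voxels to normalize by")
    s = float(np.std(sel))
    if s == 0:
        raise ValueError("zero intensity standard deviation")
    return v.copy_with(data / s)


class PhaseTransform(BaseEstimator, TransformerMixin):
    """Transformer computing the phase image of each volume."""

    def __init__(self, epsilon_frac: float = 0.001, norm: str = "l2"):
        self.epsilon_frac = epsilon_frac
        self.norm = norm

    def fit(self, X, y=None):
        return self

    def transform(self, X):
        params = PhaseParams(self.epsilon_frac, self.norm)
        if isinstance(X, Volume):
            return phase_image(X, params)
        return [phase_image(v, params) for v in X]


class StdNormalizer(BaseEstimator, TransformerMixin):
    """Transformer dividing each volume by its (foreground) intensity std."""

    def __init__(self, foreground_only: bool = True):
        self.foreground_only = foreground_only

    def fit(self, X, y=None):
        return self

    def transform(self, X):
        if isinstance(X, Volume):
            return normalize_std(X, self.foreground_only)
        return [normalize_std(v, self.foreground_only) for v in X]
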