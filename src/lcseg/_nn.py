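"""Minimal NumPy building blocks for the 3D U-Net.

All layers operate on batched tensors (B, C, D, H, W) in float32.
Convolutions are im2col + BLAS matmul with zero-padded "same" output;
backward passes are exact analytic gradients.  Everything is
single-threaded-deterministic: the only randomness is the seeded
initializer and patch sampler held by the caller.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import as_strided


def _im2col(x: np.ndarray) -> np.ndarray:
    """(B, C, D, H, W) -> (B*D*H*W, C*27) patch matrix for a 3^3 kernel,
    zero padding 1."""
    b, c, d, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1), (1, 1)))
    s = xp.strides
    windows = as_strided(
        xp,
        shape=(b, c, d, h, w, 3, 3, 3),
        strides=(s[0], s[1], s[2], s[3], s[4], s[2], s[3], s[4]),
    )
    cols = np.ascontiguousarray(windows.transpose(0, 2, 3, 4, 1, 5, 6, 7))
    return cols.reshape(b * d * h * w, c * 27)


class Conv3x3:
    """3x3x3 'same' convolution with bias."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        fan_in = c_in * 27
        self.W = (rng.standard_normal((fan_in, c_out))
                  * np.sqrt(2.0 / fan_in)).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        self._cols = _im2col(x)
        b, c, d, h, w = x.shape
        out = self._cols @ self.W + self.b
        return np.ascontiguousarray(
            out.reshape(b, d, h, w, -1).transpose(0, 4, 1, 2, 3))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        b, co, d, h, w = dout.shape
        c_in = self._shape[1]
        dflat = np.ascontiguousarray(
            dout.transpose(0, 2, 3, 4, 1)).reshape(-1, co)
        self.dW += self._cols.T @ dflat
        self.db += dflat.sum(axis=0)
        self._cols = None
        # Input gradient = 'same' convolution of dout with flipped kernels.
        wr = self.W.reshape(c_in, 3, 3, 3, co)[:, ::-1, ::-1, ::-1, :]
        wr = np.ascontiguousarray(
            wr.transpose(4, 1, 2, 3, 0)).reshape(co * 27, c_in)
        dx = _im2col(np.ascontiguousarray(dout)) @ wr
        return np.ascontiguousarray(
            dx.reshape(b, d, h, w, c_in).transpose(0, 4, 1, 2, 3))

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]


class Conv1x1:
    """1x1x1 convolution (channel mixing)."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        self.W = (rng.standard_normal((c_in, c_out))
                  * np.sqrt(2.0 / c_in)).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        out = np.einsum("bcdhw,ck->bkdhw", x, self.W,
                        optimize=True) + self.b[None, :, None, None, None]
        return out.astype(np.float32)

    def backward(self, dout: np.ndarray):
        self.dW += np.einsum("bcdhw,bkdhw->ck", self._x, dout,
                             optimize=True)
        self.db += dout.sum(axis=(0, 2, 3, 4))
        dx = np.einsum("bkdhw,ck->bcdhw", dout, self.W, optimize=True)
        self._x = None
        return dx.astype(np.float32)

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]


class InstanceNorm:
    """Per-sample, per-channel spatial normalization with learned scale and
    shift.  Keeps activations in a fixed range regardless of depth, which
    is what makes small-batch 3D segmentation networks trainable."""

    EPS = 1e-5

    def __init__(self, channels: int):
        self.gamma = np.ones(channels, dtype=np.float32)
        self.beta = np.zeros(channels, dtype=np.float32)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, c = x.shape[:2]
        flat = x.reshape(b, c, -1)
        mu = flat.mean(axis=2, keepdims=True)
        var = flat.var(axis=2, keepdims=True)
        self._inv = (1.0 / np.sqrt(var + self.EPS)).astype(np.float32)
        self._xhat = ((flat - mu) * self._inv).astype(np.float32)
        out = self.gamma[None, :, None] * self._xhat + \
            self.beta[None, :, None]
        return out.reshape(x.shape).astype(np.float32)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        b, c = dout.shape[:2]
        dflat = dout.reshape(b, c, -1)
        n = dflat.shape[2]
        self.dgamma += (dflat * self._xhat).sum(axis=(0, 2))
        self.dbeta += dflat.sum(axis=(0, 2))
        dxhat = dflat * self.gamma[None, :, None]
        dx = (self._inv / n) * (
            n * dxhat
            - dxhat.sum(axis=2, keepdims=True)
            - self._xhat * (dxhat * self._xhat).sum(axis=2, keepdims=True)
        )
        out = dx.reshape(dout.shape).astype(np.float32)
        self._xhat = None
        return out

    def params(self):
        return [(self.gamma, self.dgamma), (self.beta, self.dbeta)]


class ReLU:
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        out = dout * self._mask
        self._mask = None
        return out

    def params(self):
        return []


class MaxPool2:
    """2x max pooling with exact argmax gradient routing."""

    def forward(self, x):
        b, c, d, h, w = x.shape
        assert d % 2 == 0 and h % 2 == 0 and w % 2 == 0, "odd pooling input"
        xr = x.reshape(b, c, d // 2, 2, h // 2, 2, w // 2, 2)
        xr = xr.transpose(0, 1, 2, 4, 6, 3, 5, 7).reshape(
            b, c, d // 2, h // 2, w // 2, 8)
        self._arg = xr.argmax(axis=-1)
        self._shape = (b, c, d, h, w)
        return np.take_along_axis(xr, self._arg[..., None], axis=-1)[..., 0]

    def backward(self, dout):
        b, c, d, h, w = self._shape
        dr = np.zeros((b, c, d // 2, h // 2, w // 2, 8), dtype=dout.dtype)
        np.put_along_axis(dr, self._arg[..., None], dout[..., None], axis=-1)
        dr = dr.reshape(b, c, d // 2, h // 2, w // 2, 2, 2, 2)
        dr = dr.transpose(0, 1, 2, 5, 3, 6, 4, 7).reshape(b, c, d, h, w)
        self._arg = None
        return dr

    def params(self):
        return []


class Upsample2:
    """Nearest-neighbour 2x upsampling; backward is sum pooling."""

    def forward(self, x):
        return x.repeat(2, axis=2).repeat(2, axis=3).repeat(2, axis=4)

    def backward(self, dout):
        b, c, d, h, w = dout.shape
        return dout.reshape(b, c, d // 2, 2, h // 2, 2, w // 2, 2).sum(
            axis=(3, 5, 7))

    def params(self):
        return []


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def dice_loss_grad(pred: np.ndarray, target: np.ndarray,
                   smooth: float = 1.0):
    """Soft Dice loss 1 - (2 Σ p t + s) / (Σ p + Σ t + s) and its gradient
    with respect to ``pred``."""
    p = pred.astype(np.float64)
    t = target.astype(np.float64)
    num = 2.0 * np.sum(p * t) + smooth
    den = np.sum(p) + np.sum(t) + smooth
    loss = 1.0 - num / den
    grad = -(2.0 * t * den - num) / den**2
    return float(loss), grad.astype(np.float32)


def generalized_dice_loss_grad(pred: np.ndarray, target: np.ndarray,
                               smooth: float = 1.0):
    """Two-class generalized Dice loss with inverse-squared-volume class
    weights, and its gradient with respect to ``pred``.

    Weighting foreground and background by 1/|class|^2 keeps a tiny target
    from being washed out by the background term — the reason many
    segmentation toolboxes implement their "Dice objective" this way.
    Computed over whatever array is passed in: calling it on a whole
    stacked mini-batch yields the "batch Dice" objective.
    """
    p = pred.astype(np.float64)
    t = target.astype(np.float64)
    nf = np.sum(t)
    nb = np.sum(1.0 - t)
    if nf == 0:
        # Empty-target input: fall back to the plain soft Dice, whose
        # gradient actively suppresses false positives.  (The 1/n^2 weight
        # of an empty foreground class would otherwise either blow up or,
        # if zeroed, leave false positives nearly free.)
        return dice_loss_grad(pred, target, smooth)
    wf = 1.0 / (nf + smooth) ** 2
    wb = 1.0 / (nb + smooth) ** 2 if nb > 0 else 0.0
    num = wf * np.sum(p * t) + wb * np.sum((1 - p) * (1 - t))
    den = wf * (np.sum(p) + np.sum(t)) + wb * (np.sum(1 - p)
                                               + np.sum(1 - t))
    den += 1e-30
    loss = 1.0 - 2.0 * num / den
    dnum = wf * t - wb * (1.0 - t)
    dden = wf - wb
    grad = -2.0 * (dnum * den - num * dden) / den**2
    return float(loss), grad.astype(np.float32)


class Adam:
    """Adam optimizer with global gradient-norm clipping."""

    def __init__(self, params, lr: float = 2e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8,
                 max_grad_norm: float = 1.0):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.max_grad_norm = max_grad_norm
        self.m = [np.zeros_like(p) for p, _ in params]
        self.v = [np.zeros_like(p) for p, _ in params]
        self.t = 0

    def step(self):
        self.t += 1
        if self.max_grad_norm:
            total = np.sqrt(sum(float(np.sum(g.astype(np.float64) ** 2))
                                for _, g in self.params))
            if total > self.max_grad_norm:
                scale = np.float32(self.max_grad_norm / total)
                for _, g in self.params:
                    g *= scale
        b1, b2 = self.beta1, self.beta2
        for i, (p, g) in enumerate(self.params):
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for _, g in self.params:
            g[...] = 0.0
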