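"""Patch-based 3D U-Net localizer.

Architecture: a contracting path with two down-sampling stages, a symmetric
expanding path with skip connections, 16 initial filters by default, soft
Dice loss, Adam, and a learning rate that starts at 0.002 and drops by 95%
every five epochs.  Inference averages the label scores of overlapping
sliding-window patches (stride 10 by default).

The network is pure NumPy (see ``_nn``): convolutions are im2col + BLAS
matmuls, gradients are exact, and a seed fully determines initialization
and patch sampling, so training is reproducible on a single thread.

Five input variants mirror the domain-shift experiment: ``image`` (raw
intensities), ``nmz`` (volume divided by its foreground std, plus
patch-wise zero-meaning and unit normalization at the input layer),
``phase`` (spectral-whitening phase image), ``image+phase`` and
``nmz+phase`` (two-channel stacks; the nmz variant keeps the patch-wise
input normalization).
"""

from __future__ import annotations

from typing import Callable

import numpy as np
from sklearn.base import BaseEstimator

from ._nn import (Adam, Conv1x1, Conv3x3, InstanceNorm, MaxPool2, ReLU,
                  Upsample2, dice_loss_grad, generalized_dice_loss_grad,
                  sigmoid)
from .io_core import SoftMask, Volume
from .phase import PhaseParams, normalize_std, phase_image

VARIANTS = ("image", "nmz", "phase", "image+phase", "nmz+phase")


def dice_loss(pred, target, smooth: float = 1.0) -> float:
    """Soft Dice loss between a predicted soft patch and a binary target."""
    p = np.asarray(pred, dtype=float)
    t = np.asarray(target, dtype=float)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch {p.shape} vs {t.shape}")
    loss, _ = dice_loss_grad(p, t, smooth)
    return loss


def learning_rate(epoch: int, lr0: float = 0.002, drop: float = 0.05,
                  every: int = 5) -> float:
    """Learning rate at a 1-based epoch: lr0 dropped by 95% every 5 epochs."""
    if epoch < 1:
        raise ValueError("epoch is 1-based")
    return lr0 * drop ** ((epoch - 1) // every)


class _ConvBlock:
    """Conv -> InstanceNorm -> ReLU, twice."""

    def __init__(self, c_in, c_out, rng):
        self.layers = [Conv3x3(c_in, c_out, rng), InstanceNorm(c_out),
                       ReLU(),
                       Conv3x3(c_out, c_out, rng), InstanceNorm(c_out),
                       ReLU()]

    def forward(self, x):
        for l in self.layers:
            x = l.forward(x)
        return x

    def backward(self, d):
        for l in reversed(self.layers):
            d = l.backward(d)
        return d

    def params(self):
        return [p for l in self.layers for p in l.params()]


class UNet3D:
    """3D U-Net with ``depth`` down-sampling stages (zero-padded 'same'
    convolutions, so the output grid equals the input grid)."""

    def __init__(self, in_channels: int = 1, base_filters: int = 16,
                 depth: int = 2, seed: int = 0):
        rng = np.random.default_rng([int(seed), 101])
        self.depth = depth
        self.enc = []
        c = in_channels
        for l in range(depth):
            f = base_filters * 2**l
            self.enc.append(_ConvBlock(c, f, rng))
            c = f
        self.pools = [MaxPool2() for _ in range(depth)]
        self.bottleneck = _ConvBlock(c, base_filters * 2**depth, rng)
        self.ups = [Upsample2() for _ in range(depth)]
        self.dec = []
        for l in reversed(range(depth)):
            f = base_filters * 2**l
            self.dec.append(_ConvBlock(base_filters * 2 ** (l + 1) + f, f,
                                       rng))
        self.head = Conv1x1(base_filters, 1, rng)
        # Prior-probability bias init: start near "mostly background"
        # without saturating, which stabilizes the first optimizer steps on
        # a heavily imbalanced target.
        self.head.b[:] = -2.0

    def forward(self, x: np.ndarray) -> np.ndarray:
        """(B, C, D, H, W) float32 -> (B, D, H, W) soft scores in [0, 1].

        A 4D input is treated as a single-sample batch and returns
        (D, H, W).
        """
        squeeze = x.ndim == 4
        if squeeze:
            x = x[None]
        skips = []
        for l in range(self.depth):
            x = self.enc[l].forward(x)
            skips.append(x)
            x = self.pools[l].forward(x)
        x = self.bottleneck.forward(x)
        self._splits = []
        for i, l in enumerate(reversed(range(self.depth))):
            x = self.ups[i].forward(x)
            skip = skips[l]
            self._splits.append((x.shape[1], skip.shape[1]))
            x = np.concatenate([x, skip], axis=1)
            x = self.dec[i].forward(x)
        logits = self.head.forward(x)[:, 0]
        self._pred = sigmoid(logits.astype(np.float64)).astype(np.float32)
        self._squeezed = squeeze
        return self._pred[0] if squeeze else self._pred

    def backward(self, dpred: np.ndarray) -> None:
        if self._squeezed and dpred.ndim == 3:
            dpred = dpred[None]
        p = self._pred
        dlogits = (dpred * p * (1.0 - p)).astype(np.float32)[:, None]
        d = self.head.backward(dlogits)
        dskips = {}
        for i in reversed(range(self.depth)):
            d = self.dec[i].backward(d)
            n_up, _ = self._splits[i]
            d_up, d_skip = d[:, :n_up], d[:, n_up:]
            dskips[self.depth - 1 - i] = d_skip
            d = self.ups[i].backward(np.ascontiguousarray(d_up))
        d = self.bottleneck.backward(d)
        for l in reversed(range(self.depth)):
            d = self.pools[l].backward(d)
            d = d + dskips[l]
            d = self.enc[l].backward(d)

    def params(self):
        blocks = self.enc + [self.bottleneck] + self.dec + [self.head]
        out = []
        for b in blocks:
            out.extend(b.params() if not isinstance(b, Conv1x1)
                       else b.params())
        return out


def sliding_window_predict(fn: Callable[[np.ndarray], np.ndarray],
                           channels: np.ndarray, patch: int, stride: int,
                           batch: int = 1) -> np.ndarray:
    """Overlap-averaged sliding-window inference.

    ``fn`` maps a (C, p, p, p) patch to (p, p, p) scores (with
    ``batch > 1``, a stacked (N, C, p, p, p) group to (N, p, p, p)).  Every voxel's
    score is the arithmetic mean over all windows containing it; windows
    start at multiples of ``stride`` plus a final window flush with each
    edge.  Volumes smaller than the patch are symmetrically zero-padded
    and the result cropped back.
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    c, *shape = channels.shape
    shape = tuple(shape)
    pads = []
    for n in shape:
        deficit = max(0, patch - n)
        pads.append((deficit // 2, deficit - deficit // 2))
    if any(p != (0, 0) for p in pads):
        channels = np.pad(channels, [(0, 0)] + pads)
    _, d, h, w = channels.shape

    def origins(n):
        out = list(range(0, n - patch + 1, stride))
        if out[-1] != n - patch:
            out.append(n - patch)
        return out

    acc = np.zeros((d, h, w), dtype=np.float64)
    cnt = np.zeros((d, h, w), dtype=np.int64)
    all_origins = [(z, y, x) for z in origins(d) for y in origins(h)
                   for x in origins(w)]
    batch = max(1, int(batch))
    for k in range(0, len(all_origins), batch):
        group = all_origins[k:k + batch]
        if batch == 1:
            outs = [fn(channels[:, z:z + patch, y:y + patch, x:x + patch])
                    for z, y, x in group]
        else:
            stackin = np.stack([
                channels[:, z:z + patch, y:y + patch, x:x + patch]
                for z, y, x in group])
            outs = fn(stackin)
        for (z, y, x), out in zip(group, outs):
            acc[z:z + patch, y:y + patch, x:x + patch] += out
            cnt[z:z + patch, y:y + patch, x:x + patch] += 1
    avg = acc / cnt
    sl = tuple(slice(p[0], p[0] + n) for p, n in zip(pads, shape))
    return avg[sl]


def window_coverage_counts(shape, patch: int, stride: int) -> np.ndarray:
    """Per-voxel number of sliding windows covering it (same origin rule as
    :func:`sliding_window_predict`)."""
    cnt = np.zeros(shape, dtype=np.int64)
    def origins(n):
        out = list(range(0, n - patch + 1, stride))
        if out[-1] != n - patch:
            out.append(n - patch)
        return out
    for z in origins(shape[0]):
        for y in origins(shape[1]):
            for x in origins(shape[2]):
                cnt[z:z + patch, y:y + patch, x:x + patch] += 1
    return cnt


class UNetSegmenter(BaseEstimator):
    """Patch-based 3D U-Net localizer (sklearn-style estimator).

    Defaults follow the reference training recipe (patch 132, stride 10,
    batch 8, 20 epochs, lr 0.002 with 95% drops every 5 epochs, 16 initial
    filters, two down-sampling stages); desk-scale runs shrink the patch,
    filters and epochs.  ``steps_per_epoch`` controls how many mini-batches
    form one epoch; half of all sampled patches are constrained to
    intersect the target mask to counter the extreme class imbalance of a
    ~20 mm^3 target.
    """

    def __init__(self, side: str = "left", variant: str = "nmz",
                 depth: int = 2, base_filters: int = 16,
                 patch_size: int = 132, stride: int = 10, epochs: int = 20,
                 batch_size: int = 8, steps_per_epoch: int = 10,
                 lr0: float = 0.002, lr_drop: float = 0.05,
                 lr_drop_every: int = 5, smooth: float = 1.0,
                 fg_fraction: float = 0.5, loss: str = "batch",
                 augment_mirror: bool = False,
                 threshold: float = 0.5, epsilon_frac: float = 0.001,
                 seed: int = 0):
        self.side = side
        self.variant = variant
        self.depth = depth
        self.base_filters = base_filters
        self.patch_size = patch_size
        self.stride = stride
        self.epochs = epochs
        self.batch_size = batch_size
        self.steps_per_epoch = steps_per_epoch
        self.lr0 = lr0
        self.lr_drop = lr_drop
        self.lr_drop_every = lr_drop_every
        self.smooth = smooth
        self.fg_fraction = fg_fraction
        self.loss = loss
        self.augment_mirror = augment_mirror
        self.threshold = threshold
        self.epsilon_frac = epsilon_frac
        self.seed = seed

    # -- preprocessing -----------------------------------------------------
    def _channels(self, v: Volume) -> np.ndarray:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; "
                             f"expected one of {VARIANTS}")
        chans = []
        if self.variant in ("image", "image+phase"):
            chans.append(np.asarray(v.data, dtype=np.float32))
        if self.variant in ("nmz", "nmz+phase"):
            chans.append(np.asarray(normalize_std(v).data, dtype=np.float32))
        if self.variant in ("phase", "image+phase", "nmz+phase"):
            ph = phase_image(v, PhaseParams(self.epsilon_frac))
            chans.append(np.asarray(ph.data, dtype=np.float32))
        return np.stack(chans, axis=0)

    @property
    def _patchwise_norm(self) -> bool:
        return self.variant in ("nmz", "nmz+phase")

    def _norm_patch(self, patch: np.ndarray) -> np.ndarray:
        if not self._patchwise_norm:
            return patch
        out = np.empty_like(patch)
        for c in range(patch.shape[0]):
            p = patch[c]
            out[c] = (p - p.mean()) / (p.std() + 1e-6)
        return out

    # -- training ----------------------------------------------------------
    def fit(self, cases, y=None):
        cases = list(cases)
        if len(cases) < 2:
            raise ValueError("training requires at least 2 cases")
        patch = int(self.patch_size)
        if patch % 2**self.depth != 0:
            raise ValueError(
                f"patch size {patch} not divisible by 2^depth")
        vols = [self._channels(c.image) for c in cases]
        targets = [np.asarray(c.mask(self.side).data, dtype=np.float32)
                   for c in cases]
        if self.augment_mirror:
            # The contralateral side is a mirrored example of the same
            # structure: flip the volume left-right and use the opposite
            # side's mask.  Doubles the effective training set.
            other = "right" if self.side == "left" else "left"
            for c in cases:
                vols.append(np.ascontiguousarray(
                    self._channels(c.image)[:, ::-1]))
                targets.append(np.ascontiguousarray(
                    np.asarray(c.mask(other).data,
                               dtype=np.float32)[::-1]))
        shape = np.asarray(vols[0].shape[1:])
        if np.any(shape < patch):
            pads = [(max(0, patch - n) // 2,
                     max(0, patch - n) - max(0, patch - n) // 2)
                    for n in shape]
            vols = [np.pad(v, [(0, 0)] + pads) for v in vols]
            targets = [np.pad(t, pads) for t in targets]
            shape = np.asarray(vols[0].shape[1:])

        net = UNet3D(in_channels=vols[0].shape[0],
                     base_filters=self.base_filters, depth=self.depth,
                     seed=self.seed)
        opt = Adam(net.params(), lr=self.lr0)
        rng = np.random.default_rng([int(self.seed), 977])

        fg_voxels = [np.argwhere(t > 0) for t in targets]

        self.loss_trace_ = []
        for epoch in range(1, int(self.epochs) + 1):
            opt.lr = learning_rate(epoch, self.lr0, self.lr_drop,
                                   self.lr_drop_every)
            losses = []
            for _ in range(int(self.steps_per_epoch)):
                opt.zero_grad()
                # Assemble the mini-batch: a fg_fraction share of draws is
                # forced to intersect the target mask (at least one per
                # batch, so the batch objective always sees foreground).
                xs, ts = [], []
                for b in range(int(self.batch_size)):
                    i = int(rng.integers(len(vols)))
                    forced = b == 0 or rng.random() < self.fg_fraction
                    if forced:
                        # Center the patch on a random target voxel with
                        # jitter, so most forced draws contain the whole
                        # (tiny) target rather than cutting it.
                        vox = fg_voxels[i][
                            int(rng.integers(len(fg_voxels[i])))]
                        jit = rng.integers(-patch // 4, patch // 4 + 1,
                                           size=3)
                        o = np.clip(vox - patch // 2 + jit, 0,
                                    shape - patch).astype(int).tolist()
                    else:
                        o = [int(rng.integers(0, shape[k] - patch + 1))
                             for k in range(3)]
                    sl = (slice(None),) + tuple(
                        slice(o[k], o[k] + patch) for k in range(3))
                    xs.append(self._norm_patch(vols[i][sl]))
                    ts.append(targets[i][sl[1:]])
                xb = np.stack(xs)
                tb = np.stack(ts)
                preds = net.forward(xb)
                if self.loss == "batch":
                    # One class-weighted Dice over the whole batch: a
                    # single gradient scale for all patches.
                    loss, grad = generalized_dice_loss_grad(
                        preds, tb, self.smooth)
                else:
                    loss = 0.0
                    grad = np.empty_like(preds)
                    for k in range(len(xs)):
                        if self.loss == "generalized":
                            lk, gk = generalized_dice_loss_grad(
                                preds[k], tb[k], self.smooth)
                        else:
                            lk, gk = dice_loss_grad(preds[k], tb[k],
                                                    self.smooth)
                        loss += lk / self.batch_size
                        grad[k] = gk / self.batch_size
                net.backward(grad)
                losses.append(loss)
                opt.step()
            self.loss_trace_.append(float(np.mean(losses)))
        self.net_ = net
        self.n_channels_ = vols[0].shape[0]
        return self

    # -- inference ---------------------------------------------------------
    def predict(self, v: Volume) -> SoftMask:
        channels = self._channels(v)

        def fn(group):
            normed = np.stack([self._norm_patch(g) for g in group])
            return self.net_.forward(normed.astype(np.float32))

        scores = sliding_window_predict(fn, channels, int(self.patch_size),
                                        int(self.stride), batch=4)
        return SoftMask(np.clip(scores, 0.0, 1.0), v.affine.copy())
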