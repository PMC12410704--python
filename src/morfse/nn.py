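"""Minimal NumPy convolutional network with manual backpropagation.

Implements the desk-scale ``smallcnn`` backbone: a stack of 3x3 conv + ReLU +
2x2 max-pool blocks, global average pooling and a linear head, trained with
Adam on the cross-entropy loss.  Everything is deterministic given the seed:
initialisation, and (with the caller supplying the data order) the whole loss
curve.

Convolutions use im2col so the inner loop is a single matrix product; the
col2im scatter in the backward pass is unrolled over the 9 kernel offsets.
Input sides must be divisible by ``2**n_blocks`` (each block halves the side).
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["SmallCNN", "Adam", "softmax", "cross_entropy_grad"]


def softmax(logits: np.ndarray) -> np.ndarray:
    """Row-wise stable softmax."""
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy_grad(logits: np.ndarray, targets: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy of integer ``targets`` and its gradient w.r.t. logits."""
    p = softmax(logits)
    n = logits.shape[0]
    loss = -float(np.mean(np.log(np.maximum(p[np.arange(n), targets], 1e-12))))
    g = p.copy()
    g[np.arange(n), targets] -= 1.0
    return loss, g / n


def _im2col(x: np.ndarray, k: int = 3, pad: int = 1) -> np.ndarray:
    b, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = sliding_window_view(xp, (k, k), axis=(2, 3))  # b,c,h,w,k,k
    return win.transpose(0, 2, 3, 1, 4, 5).reshape(b * h * w, c * k * k)


def _col2im(dcols: np.ndarray, xshape: tuple[int, ...], k: int = 3, pad: int = 1) -> np.ndarray:
    b, c, h, w = xshape
    dxp = np.zeros((b, c, h + 2 * pad, w + 2 * pad), dtype=dcols.dtype)
    d6 = dcols.reshape(b, h, w, c, k, k).transpose(0, 3, 1, 2, 4, 5)
    for i in range(k):
        for j in range(k):
            dxp[:, :, i : i + h, j : j + w] += d6[:, :, :, :, i, j]
    return dxp[:, :, pad : pad + h, pad : pad + w]


class Adam:
    """Adam with optional decoupled-from-nothing L2 weight decay added to the
    gradient (the convention of the common deep-learning implementation)."""

    def __init__(self, lr: float = 1e-3, betas: tuple[float, float] = (0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.0) -> None:
        self.lr, self.eps, self.weight_decay = lr, eps, weight_decay
        self.b1, self.b2 = betas
        self.t = 0
        self.m: list[np.ndarray] | None = None
        self.v: list[np.ndarray] | None = None

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        if self.m is None:
            self.m = [np.zeros_like(p) for p in params]
            self.v = [np.zeros_like(p) for p in params]
        self.t += 1
        for p, g, m, v in zip(params, grads, self.m, self.v):
            if self.weight_decay:
                g = g + self.weight_decay * p
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1 ** self.t)
            vhat = v / (1 - self.b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class SmallCNN:
    """Conv blocks + global average pooling + linear head.

    Parameters
    ----------
    in_side : input image side in pixels; must be divisible by ``2**len(channels)``
    n_out : number of logits (2 for a gate, 3 for an expert)
    channels : output channels of successive conv blocks
    seed : He initialisation seed
    """

    def __init__(self, in_side: int, n_out: int,
                 channels: Sequence[int] = (8, 16, 32, 32), seed: int = 0) -> None:
        if in_side % (2 ** len(channels)) != 0:
            raise ValueError(f"in_side {in_side} not divisible by 2^{len(channels)}")
        self.in_side = in_side
        self.n_out = n_out
        self.channels = tuple(channels)
        rng = np.random.default_rng(seed)
        self.params: list[np.ndarray] = []
        c_in = 1
        for c_out in channels:
            fan_in = c_in * 9
            self.params.append(rng.normal(0.0, math.sqrt(2.0 / fan_in), (c_out, c_in * 9)).astype(np.float32))
            self.params.append(np.zeros(c_out, dtype=np.float32))
            c_in = c_out
        self.params.append(rng.normal(0.0, math.sqrt(2.0 / c_in), (n_out, c_in)).astype(np.float32))
        self.params.append(np.zeros(n_out, dtype=np.float32))

    # -- forward / backward ------------------------------------------------

    @staticmethod
    def _preprocess(images: np.ndarray) -> np.ndarray:
        """(B, H, W) in [0,1] -> standardized (B, 1, H, W)."""
        x = (np.asarray(images, dtype=np.float32) - 0.5) / np.float32(0.25)
        return x[:, None, :, :]

    def forward(self, images: np.ndarray, train: bool = False):
        x = self._preprocess(images)
        caches = []
        for blk in range(len(self.channels)):
            w, bias = self.params[2 * blk], self.params[2 * blk + 1]
            b, c, h, wd = x.shape
            cols = _im2col(x)
            pre = (cols @ w.T + bias).reshape(b, h, wd, -1).transpose(0, 3, 1, 2)
            act = np.maximum(pre, 0.0)
            # 2x2 max pool, stride 2
            f = act.shape[1]
            xr = act.reshape(b, f, h // 2, 2, wd // 2, 2).transpose(0, 1, 2, 4, 3, 5)
            xr = xr.reshape(b, f, h // 2, wd // 2, 4)
            idx = xr.argmax(axis=-1)
            pooled = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
            if train:
                caches.append((x.shape, cols, pre, idx))
            x = pooled
        feats = x.mean(axis=(2, 3))  # global average pool
        w_fc, b_fc = self.params[-2], self.params[-1]
        logits = feats @ w_fc.T + b_fc
        if not train:
            return logits
        return logits, (caches, x.shape, feats)

    def loss_and_grads(self, images: np.ndarray, targets: np.ndarray):
        logits, (caches, pooled_shape, feats) = self.forward(images, train=True)
        loss, dlogits = cross_entropy_grad(logits, targets)
        grads: list[np.ndarray] = [np.zeros_like(p) for p in self.params]
        grads[-2] = dlogits.T @ feats
        grads[-1] = dlogits.sum(axis=0)
        dfeats = dlogits @ self.params[-2]
        b, f, ph, pw = pooled_shape
        dx = np.broadcast_to((dfeats / (ph * pw))[:, :, None, None], pooled_shape).astype(np.float32)
        for blk in reversed(range(len(self.channels))):
            xshape, cols, pre, idx = caches[blk]
            _, _, h, wd = pre.shape[0], pre.shape[1], xshape[2], xshape[3]
            # unpool: route gradient to the argmax slot of each 2x2 window
            bsz, fch = pre.shape[0], pre.shape[1]
            dxr = np.zeros((bsz, fch, h // 2, wd // 2, 4), dtype=np.float32)
            np.put_along_axis(dxr, idx[..., None], dx[..., None], axis=-1)
            dact = dxr.reshape(bsz, fch, h // 2, wd // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
            dact = dact.reshape(bsz, fch, h, wd)
            dpre = dact * (pre > 0)
            dpre_cols = dpre.transpose(0, 2, 3, 1).reshape(-1, fch)
            grads[2 * blk] = dpre_cols.T @ cols
            grads[2 * blk + 1] = dpre_cols.sum(axis=0)
            if blk > 0:
                dcols = dpre_cols @ self.params[2 * blk]
                dx = _col2im(dcols, xshape)
        return loss, grads

    # -- training ----------------------------------------------------------

    def configure_optimizer(self, lr: float, weight_decay: float = 0.0) -> None:
        self._opt = Adam(lr=lr, weight_decay=weight_decay)

    def train_batch(self, images: np.ndarray, targets: np.ndarray) -> float:
        """One Adam step on a mini-batch; returns the batch loss."""
        loss, grads = self.loss_and_grads(images, targets)
        self._opt.step(self.params, grads)
        return loss

    # -- inference ---------------------------------------------------------

    def predict_logits(self, images: np.ndarray) -> np.ndarray:
        images = np.asarray(images, dtype=np.float64)
        if images.ndim == 2:
            images = images[None]
        if images.shape[-1] != self.in_side or images.shape[-2] != self.in_side:
            raise ValueError(
                f"input side {images.shape[-2:]} does not match network side {self.in_side}"
            )
        return self.forward(images, train=False)

    def predict_proba(self, images: np.ndarray) -> np.ndarray:
        return softmax(self.predict_logits(images))

    def copy_params(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params]
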