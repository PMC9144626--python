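"""Minimal CPU neural-network layers for the encoder--decoder segmenter.

Implements exactly what the segmenter needs, in numpy: 3x3 same-padding
convolutions via im2col, 2x2 max pooling that records argmax indices, index
unpooling (the SegNet hallmark: the decoder upsamples by scattering into the
encoder's pooling positions), ReLU, pixel-wise softmax cross-entropy, and
SGD with momentum and L2 weight decay. All tensors are channels-last
(N, H, W, C) float32. Single-threaded numpy matmul keeps training
bit-deterministic for a fixed seed.
"""

from __future__ import annotations

import numpy as np

from .errors import TrainingDivergedError


def _im2col(x: np.ndarray) -> np.ndarray:
    """(N, H, W, C) -> (N*H*W, 9*C) patches of the 3x3 neighbourhood with
    zero padding 1."""
    n, h, w, c = x.shape
    xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (3, 3), axis=(1, 2))
    # win: (N, H, W, C, 3, 3) -> (N*H*W, 3*3*C)
    return np.ascontiguousarray(win.transpose(0, 1, 2, 4, 5, 3)).reshape(n * h * w, 9 * c)


class Conv3x3:
    """3x3 convolution, stride 1, zero padding 1 (shape-preserving)."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        fan_in = 9 * c_in
        self.w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, c_out)).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.c_in, self.c_out = c_in, c_out
        self._cols: np.ndarray | None = None
        self._shape: tuple | None = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, h, w, _ = x.shape
        cols = _im2col(x)
        if train:
            self._cols, self._shape = cols, x.shape
        return (cols @ self.w + self.b).reshape(n, h, w, self.c_out)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, h, w, _ = self._shape
        dflat = dout.reshape(-1, self.c_out)
        self.dw = self._cols.T @ dflat
        self.db = dflat.sum(axis=0)
        # input gradient = convolution of dout with the spatially flipped,
        # channel-transposed kernel
        w_k = self.w.reshape(3, 3, self.c_in, self.c_out)
        w_rot = w_k[::-1, ::-1].transpose(0, 1, 3, 2).reshape(9 * self.c_out, self.c_in)
        dx = _im2col(dout) @ w_rot
        self._cols = None
        return dx.reshape(n, h, w, self.c_in)

    def params(self):
        return [(self.w, "dw"), (self.b, "db")]


class ReLU:
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        out = np.maximum(x, 0.0)
        if train:
            self._mask = x > 0
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


def maxpool2(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """2x2 max pooling; returns pooled map and argmax indices in {0..3}
    (position within each 2x2 window) for later unpooling."""
    n, h, w, c = x.shape
    xr = (
        x.reshape(n, h // 2, 2, w // 2, 2, c)
        .transpose(0, 1, 3, 2, 4, 5)
        .reshape(n, h // 2, w // 2, 4, c)
    )
    idx = xr.argmax(axis=3)
    out = np.take_along_axis(xr, idx[:, :, :, None, :], axis=3)[:, :, :, 0, :]
    return out, idx.astype(np.uint8)


def maxpool2_backward(dout: np.ndarray, idx: np.ndarray, in_shape: tuple) -> np.ndarray:
    return unpool2(dout, idx, in_shape)


def unpool2(x: np.ndarray, idx: np.ndarray, out_shape: tuple) -> np.ndarray:
    """Scatter each value into the recorded argmax position of its 2x2 window
    (zeros elsewhere). Shared by decoder unpooling and pooling backward."""
    n, hh, ww, c = x.shape
    out4 = np.zeros((n, hh, ww, 4, c), dtype=x.dtype)
    np.put_along_axis(out4, idx[:, :, :, None, :].astype(np.intp), x[:, :, :, None, :], axis=3)
    out = (
        out4.reshape(n, hh, ww, 2, 2, c)
        .transpose(0, 1, 3, 2, 4, 5)
        .reshape(out_shape)
    )
    return out


def unpool2_grad(dout: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Gradient of unpool2: gather back from the scattered positions."""
    n, h, w, c = dout.shape
    d4 = (
        dout.reshape(n, h // 2, 2, w // 2, 2, c)
        .transpose(0, 1, 3, 2, 4, 5)
        .reshape(n, h // 2, w // 2, 4, c)
    )
    return np.take_along_axis(d4, idx[:, :, :, None, :].astype(np.intp), axis=3)[:, :, :, 0, :]


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean pixel-wise cross-entropy and its gradient w.r.t. logits."""
    p = softmax(logits)
    n_pix = labels.size
    onehot_p = np.take_along_axis(p, labels[..., None].astype(np.intp), axis=-1)[..., 0]
    loss = float(-np.log(np.maximum(onehot_p, 1e-12)).mean())
    if not np.isfinite(loss):
        raise TrainingDivergedError("non-finite cross-entropy loss")
    grad = p.astype(np.float32)
    np.subtract.at(grad.reshape(n_pix, -1), (np.arange(n_pix), labels.ravel().astype(np.intp)), 1.0)
    return loss, grad / np.float32(n_pix)


class SGDMomentum:
    """SGD with classical momentum and decoupled-from-loss L2 weight decay,
    matching the reported optimizer settings (momentum 0.9, lr 0.01,
    L2 5e-4)."""

    def __init__(self, layers, lr: float, momentum: float, weight_decay: float):
        self.convs = [l for l in layers if isinstance(l, Conv3x3)]
        self.lr, self.momentum, self.wd = lr, momentum, weight_decay
        self.vel = [
            [np.zeros_like(c.w), np.zeros_like(c.b)] for c in self.convs
        ]

    def step(self) -> None:
        for conv, (vw, vb) in zip(self.convs, self.vel):
            gw = conv.dw + self.wd * conv.w
            vw *= self.momentum
            vw -= self.lr * gw
            conv.w += vw
            gb = conv.db.astype(np.float32)
            vb *= self.momentum
            vb -= self.lr * gb
            conv.b += vb
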