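"""A compact numpy neural-network engine (conv / batch-norm / dense, Adam).

Implements exactly the pieces the spectrogram quality classifier needs:
2-D convolutions with stride 1 and same padding, batch normalization with
running statistics, ReLU, 2x2 max pooling, dense layers, and the Adam
optimizer with a binary-cross-entropy-with-logits loss.

All image tensors are channels-last ``(N, H, W, C)`` and float32; the
convolution is computed as a sum of kernel-offset matmuls, which keeps
the inner loops inside BLAS without materializing im2col patch matrices.
Everything is deterministic given a seeded generator.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg.blas import sgemm


def _gemm_acc(a: np.ndarray, b: np.ndarray, out: np.ndarray) -> None:
    """out += a @ b for C-contiguous float32 arrays, accumulating in BLAS.

    Row-major arrays are passed as their (Fortran-contiguous) transposes:
    ``out.T = b.T @ a.T`` computed in place, so the product is accumulated
    into ``out`` without allocating an intermediate.
    """
    sgemm(1.0, b.T, a.T, beta=1.0, c=out.T, overwrite_c=True)

__all__ = [
    "Conv2d",
    "BatchNorm2d",
    "ReLU",
    "MaxPool2x2",
    "Dense",
    "Adam",
    "bce_with_logits",
]


class Conv2d:
    """Stride-1, same-padding 2-D convolution with bias (NHWC layout)."""

    def __init__(self, c_in: int, c_out: int, kernel: tuple[int, int], rng: np.random.Generator):
        kh, kw = kernel
        fan_in = c_in * kh * kw
        self.w = (rng.standard_normal((kh, kw, c_in, c_out)) * np.sqrt(2.0 / fan_in)).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)
        self.kernel = (kh, kw)
        self._slices: list | None = None

    @property
    def params(self):
        return [(self.w, self.gw), (self.b, self.gb)]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        # The convolution is a sum over the kh*kw kernel offsets of one
        # GEMM per offset, accumulated in place.  Each offset's input
        # slice is copied to a contiguous buffer first — contiguous
        # destinations keep every heavy memory pass at full bandwidth.
        kh, kw = self.kernel
        ph, pw = kh // 2, kw // 2
        n, h, w, c = x.shape
        f = self.b.size
        x_pad = np.pad(x, ((0, 0), (ph, ph), (pw, pw), (0, 0))) if ph or pw else x
        slices = []
        out = np.broadcast_to(self.b, (n * h * w, f)).copy()
        wmat = self.w.reshape(kh * kw, c, f)
        for k in range(kh * kw):
            di, dj = divmod(k, kw)
            xs = np.ascontiguousarray(x_pad[:, di : di + h, dj : dj + w, :]).reshape(-1, c)
            slices.append(xs)
            _gemm_acc(xs, wmat[k], out)
        if train:
            self._slices = slices
        return out.reshape(n, h, w, f)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        kh, kw = self.kernel
        ph, pw = kh // 2, kw // 2
        n, h, w, f = dout.shape
        c = self.w.shape[2]
        dmat = dout.reshape(-1, f)
        self.gb[...] = dmat.sum(axis=0)
        wmat = self.w.reshape(kh * kw, c, f)
        for k in range(kh * kw):
            self.gw.reshape(kh * kw, c, f)[k] = self._slices[k].T @ dmat
        self._slices = None
        # dx is the correlation of dout with the flipped kernel: same
        # per-offset accumulated-GEMM structure on the padded gradient.
        dout_pad = np.pad(dout, ((0, 0), (ph, ph), (pw, pw), (0, 0))) if ph or pw else dout
        dx = np.zeros((n * h * w, c), dtype=np.float32)
        for k in range(kh * kw):
            di, dj = divmod(k, kw)
            ds = np.ascontiguousarray(dout_pad[:, di : di + h, dj : dj + w, :]).reshape(-1, f)
            w_flip = wmat[(kh - 1 - di) * kw + (kw - 1 - dj)]  # (c, f)
            _gemm_acc(ds, np.ascontiguousarray(w_flip.T), dx)
        return dx.reshape(n, h, w, c)


class BatchNorm2d:
    """Per-channel batch normalization over (N, H, W) in NHWC layout."""

    def __init__(self, c: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = np.ones(c, dtype=np.float32)
        self.beta = np.zeros(c, dtype=np.float32)
        self.ggamma = np.zeros_like(self.gamma)
        self.gbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps
        self._cache = None

    @property
    def params(self):
        return [(self.gamma, self.ggamma), (self.beta, self.gbeta)]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            flat = x.reshape(-1, x.shape[-1])
            mean = flat.mean(axis=0)
            var = np.square(flat).mean(axis=0) - mean**2
            var = np.maximum(var, 0)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        inv = (1.0 / np.sqrt(var + self.eps)).astype(np.float32)
        xhat = x - mean
        xhat *= inv
        if train:
            self._cache = (xhat, inv)
        out = xhat * self.gamma
        out += self.beta
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, inv = self._cache
        self._cache = None
        m = dout.size // dout.shape[-1]
        dflat = dout.reshape(-1, dout.shape[-1])
        xflat = xhat.reshape(-1, xhat.shape[-1])
        self.ggamma[...] = np.einsum("nc,nc->c", dflat, xflat)
        self.gbeta[...] = dflat.sum(axis=0)
        # gbeta/ggamma double as the per-channel batch sums the formula needs
        dx = xhat * (self.ggamma / m)
        dx += self.gbeta / m
        np.subtract(dout, dx, out=dx)
        dx *= self.gamma * inv
        return dx


class ReLU:
    params: list = []

    def __init__(self):
        self._mask = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        out = np.maximum(x, 0)
        if train:
            self._mask = x > 0
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dx = dout * self._mask
        self._mask = None
        return dx


class MaxPool2x2:
    """2x2 max pooling, stride 2, NHWC (odd trailing rows/cols dropped)."""

    params: list = []

    def __init__(self):
        self._cache = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, h, w, c = x.shape
        h2, w2 = h // 2, w // 2
        xc = x[:, : h2 * 2, : w2 * 2, :].reshape(n, h2, 2, w2, 2, c)
        out = xc.max(axis=(2, 4))
        if train:
            self._cache = (x.shape, xc, out)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        shape, xc, out = self._cache
        self._cache = None
        mask = xc == out[:, :, None, :, None, :]
        counts = mask.sum(axis=(2, 4), keepdims=True)
        dxc = mask * (dout[:, :, None, :, None, :] / counts)
        n, h, w, c = shape
        h2, w2 = h // 2, w // 2
        dx = np.zeros(shape, dtype=np.float32)
        dx[:, : h2 * 2, : w2 * 2, :] = dxc.reshape(n, h2 * 2, w2 * 2, c)
        return dx


class Dense:
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        self.w = (rng.standard_normal((d_in, d_out)) * np.sqrt(2.0 / d_in)).astype(np.float32)
        self.b = np.zeros(d_out, dtype=np.float32)
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)
        self._x = None

    @property
    def params(self):
        return [(self.w, self.gw), (self.b, self.gb)]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._x = x
        return x @ self.w + self.b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.gw[...] = self._x.T @ dout
        self.gb[...] = dout.sum(axis=0)
        self._x = None
        return dout @ self.w.T


class Adam:
    """Adam optimizer over a flat list of (param, grad) pairs."""

    def __init__(self, params, lr: float = 5e-4, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in self.params]
        self.v = [np.zeros_like(p) for p, _ in self.params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for (p, g), m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def bce_with_logits(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy on raw logits; returns (loss, dlogits)."""
    z = logits.astype(np.float64)
    loss = float(np.mean(np.maximum(z, 0) - z * labels + np.log1p(np.exp(-np.abs(z)))))
    probs = 1.0 / (1.0 + np.exp(-z))
    dz = ((probs - labels) / z.size).astype(np.float32)
    return loss, dz
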