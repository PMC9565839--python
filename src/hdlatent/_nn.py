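"""Minimal 3D convolutional network primitives in numpy.

Forward/backward passes for strided 3D convolution and transposed
convolution via im2col/col2im, a ReLU, and an Adam optimizer — just
enough machinery to train the patch autoencoder deterministically on a
CPU.  Layouts: activations (B, C, D, H, W); conv weights
(Cout, Cin*k^3); transposed-conv weights (Cout*k^3, Cin).
"""

from __future__ import annotations

import numpy as np


def _conv_out(n: int, k: int, s: int, p: int) -> int:
    return (n + 2 * p - k) // s + 1


def im2col(xp: np.ndarray, k: int, s: int, out_shape) -> np.ndarray:
    """(B, C, Dp, Hp, Wp) padded input -> (B, C*k^3, L) column matrix."""
    B, C = xp.shape[:2]
    do, ho, wo = out_shape
    cols = np.empty((B, C, k, k, k, do, ho, wo), dtype=xp.dtype)
    for a in range(k):
        for b in range(k):
            for c in range(k):
                cols[:, :, a, b, c] = xp[
                    :, :, a:a + do * s:s, b:b + ho * s:s, c:c + wo * s:s
                ]
    return cols.reshape(B, C * k**3, do * ho * wo)


def col2im(cols: np.ndarray, xp_shape, k: int, s: int, out_shape) -> np.ndarray:
    """Scatter-add inverse of :func:`im2col`."""
    B, C = xp_shape[:2]
    do, ho, wo = out_shape
    view = cols.reshape(B, C, k, k, k, do, ho, wo)
    xp = np.zeros(xp_shape, dtype=cols.dtype)
    for a in range(k):
        for b in range(k):
            for c in range(k):
                xp[:, :, a:a + do * s:s, b:b + ho * s:s, c:c + wo * s:s] += view[:, :, a, b, c]
    return xp


def _pad(x: np.ndarray, p: int) -> np.ndarray:
    if p == 0:
        return x
    return np.pad(x, ((0, 0), (0, 0), (p, p), (p, p), (p, p)))


def _unpad(xp: np.ndarray, p: int) -> np.ndarray:
    if p == 0:
        return xp
    return xp[:, :, p:-p, p:-p, p:-p]


class Layer:
    params: list[np.ndarray]
    grads: list[np.ndarray]

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError


class Conv3d(Layer):
    def __init__(self, cin: int, cout: int, k: int = 3, stride: int = 2,
                 pad: int = 1, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        fan_in = cin * k**3
        self.w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(cout, fan_in)).astype(np.float32)
        self.b = np.zeros(cout, dtype=np.float32)
        self.k, self.s, self.p = k, stride, pad
        self.cin, self.cout = cin, cout
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._in_shape = x.shape
        out_shape = tuple(_conv_out(n, self.k, self.s, self.p) for n in x.shape[2:])
        xp = _pad(x, self.p)
        self._xp_shape = xp.shape
        self._cols = im2col(xp, self.k, self.s, out_shape)
        y = np.matmul(self.w, self._cols) + self.b[:, None]
        return y.reshape(x.shape[0], self.cout, *out_shape)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        B = dy.shape[0]
        out_shape = dy.shape[2:]
        dym = dy.reshape(B, self.cout, -1)
        self.grads[0][...] = np.einsum("bol,bcl->oc", dym, self._cols) / B
        self.grads[1][...] = dym.sum(axis=(0, 2)) / B
        dcols = np.matmul(self.w.T, dym)
        dxp = col2im(dcols, self._xp_shape, self.k, self.s, out_shape)
        return _unpad(dxp, self.p)


class ConvTranspose3d(Layer):
    """Mirror of Conv3d; ``output_padding`` recovers odd input sizes."""

    def __init__(self, cin: int, cout: int, k: int = 3, stride: int = 2,
                 pad: int = 1, output_padding: int = 1,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        fan_in = cin * k**3
        self.w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(cout * k**3, cin)).astype(np.float32)
        self.b = np.zeros(cout, dtype=np.float32)
        self.k, self.s, self.p, self.op = k, stride, pad, output_padding
        self.cin, self.cout = cin, cout
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def out_size(self, n: int) -> int:
        return (n - 1) * self.s - 2 * self.p + self.k + self.op

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, cin = x.shape[:2]
        in_spatial = x.shape[2:]
        out_spatial = tuple(self.out_size(n) for n in in_spatial)
        self._xm = x.reshape(B, cin, -1)
        cols = np.matmul(self.w, self._xm)              # (B, cout*k^3, L)
        xp_shape = (B, self.cout) + tuple(n + 2 * self.p for n in out_spatial)
        y = col2im(cols, xp_shape, self.k, self.s, in_spatial)
        y = _unpad(y, self.p)
        self._in_spatial, self._out_spatial = in_spatial, out_spatial
        return y + self.b[None, :, None, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        B = dy.shape[0]
        dyp = _pad(dy, self.p)
        dcols = im2col(dyp, self.k, self.s, self._in_spatial)
        self.grads[0][...] = np.einsum("bkl,bcl->kc", dcols, self._xm) / B
        self.grads[1][...] = dy.sum(axis=(0, 2, 3, 4)) / B
        dx = np.matmul(self.w.T, dcols)
        return dx.reshape(B, self.cin, *self._in_spatial)


class ReLU(Layer):
    params: list[np.ndarray] = []
    grads: list[np.ndarray] = []

    def __init__(self):
        self.params = []
        self.grads = []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class Adam:
    def __init__(self, layers: list[Layer], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.layers = [l for l in layers if l.params]
        self.lr, self.b1, self.b2, self.eps = lr, *betas, eps
        self.m = [[np.zeros_like(p) for p in l.params] for l in self.layers]
        self.v = [[np.zeros_like(p) for p in l.params] for l in self.layers]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        corr1 = 1.0 - self.b1**self.t
        corr2 = 1.0 - self.b2**self.t
        for li, layer in enumerate(self.layers):
            for pi, (p, g) in enumerate(zip(layer.params, layer.grads)):
                m = self.m[li][pi]
                v = self.v[li][pi]
                m *= self.b1
                m += (1 - self.b1) * g
                v *= self.b2
                v += (1 - self.b2) * g * g
                p -= self.lr * (m / corr1) / (np.sqrt(v / corr2) + self.eps)
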