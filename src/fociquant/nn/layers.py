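"""Minimal layers with explicit backprop for the focus-detection U-net.

All tensors are channels-first float32 ``(N, C, H, W)``.  The 3x3
convolutions are direct (no im2col) numba kernels specialized for stride 1
-- the inner loops run along the contiguous width axis so they vectorize --
with generic gather/scatter kernels for the stride-2 stages, which operate
on small feature maps.  Every layer exposes ``params`` / ``grads`` lists
consumed by the Adam optimizer.  All computation is deterministic for
fixed inputs.
"""

from __future__ import annotations

from typing import List

import numpy as np
from numba import njit

F32 = np.float32


# ---------------------------------------------------------------------------
# numba convolution kernels (3x3, padding 1)

@njit(fastmath=True, cache=True)
def _conv_fwd_s1(x, W, b, out):
    n_im, cin, h, wd = x.shape
    cout = W.shape[0]
    for n in range(n_im):
        for o in range(cout):
            for y in range(h):
                row = out[n, o, y]
                for xx in range(wd):
                    row[xx] = b[o]
            for c in range(cin):
                for ky in range(3):
                    iy0 = ky - 1
                    for kx in range(3):
                        w = W[o, c, ky, kx]
                        for y in range(h):
                            iy = y + iy0
                            if iy < 0 or iy >= h:
                                continue
                            xin = x[n, c, iy]
                            orow = out[n, o, y]
                            if kx == 0:
                                for xx in range(1, wd):
                                    orow[xx] += w * xin[xx - 1]
                            elif kx == 1:
                                for xx in range(wd):
                                    orow[xx] += w * xin[xx]
                            else:
                                for xx in range(wd - 1):
                                    orow[xx] += w * xin[xx + 1]


@njit(fastmath=True, cache=True)
def _conv_fwd_s2(x, W, b, out):
    n_im, cin, h, wd = x.shape
    cout, _, _, _ = W.shape
    ho, wo = out.shape[2], out.shape[3]
    for n in range(n_im):
        for o in range(cout):
            for y in range(ho):
                row = out[n, o, y]
                for xx in range(wo):
                    row[xx] = b[o]
            for c in range(cin):
                for ky in range(3):
                    for kx in range(3):
                        w = W[o, c, ky, kx]
                        for y in range(ho):
                            iy = 2 * y + ky - 1
                            if iy < 0 or iy >= h:
                                continue
                            xin = x[n, c, iy]
                            orow = out[n, o, y]
                            for xx in range(wo):
                                ix = 2 * xx + kx - 1
                                if 0 <= ix < wd:
                                    orow[xx] += w * xin[ix]


@njit(fastmath=True, cache=True)
def _conv_bwd_dx_s2(g, W, dx):
    n_im, cout, ho, wo = g.shape
    cin = W.shape[1]
    h, wd = dx.shape[2], dx.shape[3]
    for n in range(n_im):
        for o in range(cout):
            for c in range(cin):
                for ky in range(3):
                    for kx in range(3):
                        w = W[o, c, ky, kx]
                        for y in range(ho):
                            iy = 2 * y + ky - 1
                            if iy < 0 or iy >= h:
                                continue
                            grow = g[n, o, y]
                            drow = dx[n, c, iy]
                            for xx in range(wo):
                                ix = 2 * xx + kx - 1
                                if 0 <= ix < wd:
                                    drow[ix] += w * grow[xx]


@njit(fastmath=True, cache=True)
def _conv_bwd_dw_s1(x, g, gW):
    n_im, cin, h, wd = x.shape
    cout = g.shape[1]
    for o in range(cout):
        for c in range(cin):
            for ky in range(3):
                iy0 = ky - 1
                for kx in range(3):
                    acc = F32(0.0)
                    for n in range(n_im):
                        for y in range(h):
                            iy = y + iy0
                            if iy < 0 or iy >= h:
                                continue
                            grow = g[n, o, y]
                            xrow = x[n, c, iy]
                            if kx == 0:
                                for xx in range(1, wd):
                                    acc += grow[xx] * xrow[xx - 1]
                            elif kx == 1:
                                for xx in range(wd):
                                    acc += grow[xx] * xrow[xx]
                            else:
                                for xx in range(wd - 1):
                                    acc += grow[xx] * xrow[xx + 1]
                    gW[o, c, ky, kx] = acc


@njit(fastmath=True, cache=True)
def _conv_bwd_dw_s2(x, g, gW):
    n_im, cin, h, wd = x.shape
    cout, ho, wo = g.shape[1], g.shape[2], g.shape[3]
    for o in range(cout):
        for c in range(cin):
            for ky in range(3):
                for kx in range(3):
                    acc = F32(0.0)
                    for n in range(n_im):
                        for y in range(ho):
                            iy = 2 * y + ky - 1
                            if iy < 0 or iy >= h:
                                continue
                            grow = g[n, o, y]
                            xrow = x[n, c, iy]
                            for xx in range(wo):
                                ix = 2 * xx + kx - 1
                                if 0 <= ix < wd:
                                    acc += grow[xx] * xrow[ix]
                    gW[o, c, ky, kx] = acc


# ---------------------------------------------------------------------------
# layers

class Layer:
    def params(self) -> List[np.ndarray]:
        return []

    def grads(self) -> List[np.ndarray]:
        return []


class Conv2d(Layer):
    """3x3 convolution, padding 1, stride 1 or 2, He-initialized.

    Weights are ``(Cout, Cin, 3, 3)``.  The stride-1 input gradient reuses
    the forward kernel with spatially flipped, channel-transposed weights.
    Output/gradient buffers persist across calls to avoid reallocation.
    """

    def __init__(self, cin: int, cout: int, rng: np.random.Generator,
                 stride: int = 1, need_input_grad: bool = True):
        scale = np.sqrt(2.0 / (9 * cin))
        self.W = rng.normal(0.0, scale, size=(cout, cin, 3, 3)).astype(F32)
        self.b = np.zeros(cout, dtype=F32)
        self.stride = stride
        self.cin = cin
        self.cout = cout
        self.need_input_grad = need_input_grad
        self._cache: dict = {}

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.gW, self.gb]

    def _buf(self, name: str, shape: tuple, zero: bool = False) -> np.ndarray:
        buf = self._cache.get(name)
        if buf is None or buf.shape != shape:
            buf = np.zeros(shape, dtype=F32)
            self._cache[name] = buf
        elif zero:
            buf.fill(0.0)
        return buf

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        if c != self.cin:
            raise ValueError(f"expected {self.cin} input channels, got {c}")
        self._x = x
        if self.stride == 1:
            out = self._buf("out", (n, self.cout, h, w))
            _conv_fwd_s1(x, self.W, self.b, out)
        else:
            ho, wo = (h - 1) // 2 + 1, (w - 1) // 2 + 1
            out = self._buf("out", (n, self.cout, ho, wo))
            _conv_fwd_s2(x, self.W, self.b, out)
        return out

    def backward(self, g: np.ndarray) -> np.ndarray:
        x = self._x
        g = np.ascontiguousarray(g, dtype=F32)
        self.gW = np.empty_like(self.W)
        self.gb = g.sum(axis=(0, 2, 3))
        if self.stride == 1:
            _conv_bwd_dw_s1(x, g, self.gW)
        else:
            _conv_bwd_dw_s2(x, g, self.gW)
        if not self.need_input_grad:
            self._x = None
            return None
        dx = self._buf("dx", x.shape, zero=True)
        if self.stride == 1:
            # correlation with flipped kernels == input gradient
            w_flip = np.ascontiguousarray(
                self.W[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)
            )
            _conv_fwd_s1(g, w_flip, np.zeros(self.cin, F32), dx)
        else:
            _conv_bwd_dx_s2(g, self.W, dx)
        self._x = None
        return dx


class BatchNorm2d(Layer):
    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = np.ones(c, dtype=F32)
        self.beta = np.zeros(c, dtype=F32)
        self.running_mean = np.zeros(c, dtype=F32)
        self.running_var = np.ones(c, dtype=F32)
        self.momentum = momentum
        self.eps = eps

    def params(self):
        return [self.gamma, self.beta]

    def grads(self):
        return [self.ggamma, self.gbeta]

    @staticmethod
    def _cview(v: np.ndarray) -> np.ndarray:
        return v.reshape(1, -1, 1, 1)

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            mu = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean += self.momentum * (mu - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mu, var = self.running_mean, self.running_var
        self._ivar = (1.0 / np.sqrt(var + self.eps)).astype(F32)
        self._xhat = (x - self._cview(mu)) * self._cview(self._ivar)
        return self._cview(self.gamma) * self._xhat + self._cview(self.beta)

    def backward(self, g: np.ndarray) -> np.ndarray:
        xhat = self._xhat
        m = float(g.shape[0] * g.shape[2] * g.shape[3])
        self.gbeta = g.sum(axis=(0, 2, 3))
        self.ggamma = (g * xhat).sum(axis=(0, 2, 3))
        dxhat = g * self._cview(self.gamma)
        dx = (self._cview(self._ivar) / m) * (
            m * dxhat
            - self._cview(dxhat.sum(axis=(0, 2, 3)))
            - xhat * self._cview((dxhat * xhat).sum(axis=(0, 2, 3)))
        )
        self._xhat = None
        return dx.astype(F32, copy=False)


class PReLU(Layer):
    """Parametric ReLU with one learnable negative slope per channel."""

    def __init__(self, c: int, init: float = 0.25):
        self.a = np.full(c, init, dtype=F32)

    def params(self):
        return [self.a]

    def grads(self):
        return [self.ga]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._x = x
        self._pos = x > 0
        return np.where(self._pos, x, self.a.reshape(1, -1, 1, 1) * x)

    def backward(self, g: np.ndarray) -> np.ndarray:
        neg = ~self._pos
        self.ga = (g * self._x * neg).sum(axis=(0, 2, 3))
        dx = np.where(self._pos, g, self.a.reshape(1, -1, 1, 1) * g)
        self._x = None
        self._pos = None
        return dx.astype(F32, copy=False)


class Upsample2x(Layer):
    """Nearest-neighbor 2x upsampling; backward sums each 2x2 block."""

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, g: np.ndarray) -> np.ndarray:
        n, c, h2, w2 = g.shape
        return g.reshape(n, c, h2 // 2, 2, w2 // 2, 2).sum(axis=(3, 5))


class Adam:
    """Adam update rule with bias correction."""

    def __init__(self, params: List[np.ndarray], lr: float,
                 betas=(0.99, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: List[np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            g = g.astype(p.dtype, copy=False)
            m += (1.0 - self.b1) * (g - m)
            v += (1.0 - self.b2) * (g * g - v)
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
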