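"""NumPy building blocks for the 3-D CNN: forward and backward passes.

Layers operate on float32 arrays of shape ``(N, C, D, H, W)``.  Each layer
caches what its backward pass needs during forward; ``params()`` /
``grads()`` expose parameter and gradient arrays in matching order for the
optimizer.  Convolution uses im2col (sliding windows + matmul); the input
gradient is scattered back with a precomputed flat index map and
``np.bincount``, which keeps everything deterministic on CPU.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Conv3d", "BatchNorm3d", "ReLU", "MaxPool3d",
    "GlobalAvgPool", "Linear", "softmax", "SoftmaxCrossEntropy", "Adam",
]


def _out_dim(d: int, k: int, s: int, p: int) -> int:
    return (d + 2 * p - k) // s + 1


class Conv3d:
    """3-D convolution with cubic kernel, isotropic stride and padding."""

    def __init__(self, cin: int, cout: int, k: int, stride: int, pad: int,
                 rng: np.random.Generator):
        self.cin, self.cout, self.k, self.stride, self.pad = cin, cout, k, stride, pad
        fan_in = cin * k**3
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                            size=(cout, fan_in)).astype(np.float32)
        self.b = np.zeros(cout, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._idx: np.ndarray | None = None
        self._in_shape: tuple[int, ...] | None = None

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]

    def _build_index(self, cdp: tuple[int, int, int, int],
                     out_sp: tuple[int, int, int]) -> np.ndarray:
        # Flat index into the padded (C, Dp, Hp, Wp) grid for every
        # (output position, patch element) pair; used to scatter gradients.
        c, dp, hp, wp = cdp
        k, s = self.k, self.stride
        od, oh, ow = out_sp
        d0 = np.arange(od) * s
        h0 = np.arange(oh) * s
        w0 = np.arange(ow) * s
        ci = np.arange(c)
        # position grid (od,oh,ow) x patch grid (c,k,k,k)
        pos_d = d0[:, None, None, None, None, None, None]
        pos_h = h0[None, :, None, None, None, None, None]
        pos_w = w0[None, None, :, None, None, None, None]
        pat_c = ci[None, None, None, :, None, None, None]
        kd = np.arange(k)[None, None, None, None, :, None, None]
        kh = np.arange(k)[None, None, None, None, None, :, None]
        kw = np.arange(k)[None, None, None, None, None, None, :]
        idx = (((pat_c * dp + pos_d + kd) * hp + pos_h + kh) * wp
               + pos_w + kw)
        return idx.reshape(od * oh * ow, c * k**3)

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, c, d, h, w = x.shape
        k, s, p = self.k, self.stride, self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p), (p, p)))
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k, k),
                                                       axis=(2, 3, 4))
        win = win[:, :, ::s, ::s, ::s]
        od, oh, ow = win.shape[2:5]
        cols = np.ascontiguousarray(win.transpose(0, 2, 3, 4, 1, 5, 6, 7))
        cols = cols.reshape(n * od * oh * ow, c * k**3)
        out = cols @ self.W.T + self.b
        self._cols = cols
        self._in_shape = x.shape
        self._pad_shape = xp.shape
        self._out_sp = (od, oh, ow)
        return out.reshape(n, od, oh, ow, self.cout).transpose(0, 4, 1, 2, 3)

    def backward(self, dout: np.ndarray, need_dx: bool = True) -> np.ndarray | None:
        n = dout.shape[0]
        od, oh, ow = self._out_sp
        dr = dout.transpose(0, 2, 3, 4, 1).reshape(n * od * oh * ow, self.cout)
        self.dW[...] = dr.T @ self._cols
        self.db[...] = dr.sum(axis=0)
        if not need_dx:  # first layer: input gradient is never consumed
            self._cols = None
            return None
        dcols = (dr @ self.W).reshape(n, od * oh * ow, -1)
        cdp = self._pad_shape[1:]
        if self._idx is None or self._idx_key != (cdp, self._out_sp):
            self._idx = self._build_index(cdp, self._out_sp)
            self._idx_key = (cdp, self._out_sp)
        size = int(np.prod(cdp))
        flat_idx = self._idx.ravel()
        dxp = np.empty((n, size), dtype=np.float32)
        for i in range(n):
            dxp[i] = np.bincount(flat_idx, weights=dcols[i].ravel(),
                                 minlength=size).astype(np.float32)
        c, dp, hp, wp = cdp
        dxp = dxp.reshape(n, c, dp, hp, wp)
        p = self.pad
        if p:
            dxp = dxp[:, :, p:-p, p:-p, p:-p]
        self._cols = None
        return dxp


class BatchNorm3d:
    """Per-channel batch normalization over (N, D, H, W)."""

    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = np.ones(c, dtype=np.float32)
        self.beta = np.zeros(c, dtype=np.float32)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self.momentum, self.eps = momentum, eps

    def params(self):
        return [self.gamma, self.beta]

    def grads(self):
        return [self.dgamma, self.dbeta]

    def start_accumulate(self) -> None:
        """Begin exact recomputation of running stats (see ResNet3D.recalibrate_bn)."""
        self._acc = [0.0, np.zeros_like(self.running_mean, dtype=np.float64),
                     np.zeros_like(self.running_var, dtype=np.float64)]

    def finish_accumulate(self) -> None:
        n, s1, s2 = self._acc
        mean = s1 / n
        self.running_mean[...] = mean.astype(np.float32)
        self.running_var[...] = np.maximum(s2 / n - mean**2, 0.0).astype(np.float32)
        self._acc = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        axes = (0, 2, 3, 4)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            if getattr(self, "_acc", None) is not None:
                m = x.shape[0] * x.shape[2] * x.shape[3] * x.shape[4]
                self._acc[0] += m
                self._acc[1] += m * mean.astype(np.float64)
                self._acc[2] += m * (var + mean**2).astype(np.float64)
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        ivstd = 1.0 / np.sqrt(var + self.eps)
        sh = (1, -1, 1, 1, 1)
        xhat = (x - mean.reshape(sh)) * ivstd.reshape(sh)
        self._cache = (xhat, ivstd, train)
        return (self.gamma.reshape(sh) * xhat + self.beta.reshape(sh)).astype(
            np.float32)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, ivstd, train = self._cache
        sh = (1, -1, 1, 1, 1)
        axes = (0, 2, 3, 4)
        self.dgamma[...] = (dout * xhat).sum(axis=axes)
        self.dbeta[...] = dout.sum(axis=axes)
        g = self.gamma.reshape(sh) * ivstd.reshape(sh)
        if not train:
            return (dout * g).astype(np.float32)
        m = dout.shape[0] * dout.shape[2] * dout.shape[3] * dout.shape[4]
        dxhat = dout * self.gamma.reshape(sh)
        dx = (dxhat - dxhat.mean(axis=axes).reshape(sh)
              - xhat * (dxhat * xhat).mean(axis=axes).reshape(sh))
        dx *= ivstd.reshape(sh)
        self._cache = None
        return dx.astype(np.float32)


class ReLU:
    def params(self):
        return []

    def grads(self):
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0).astype(np.float32)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        out = np.where(self._mask, dout, 0.0).astype(np.float32)
        self._mask = None
        return out


class MaxPool3d:
    """Max pooling with cubic window; padding uses -inf."""

    def __init__(self, k: int = 3, stride: int = 2, pad: int = 1):
        self.k, self.stride, self.pad = k, stride, pad
        self._idx_map: np.ndarray | None = None

    def params(self):
        return []

    def grads(self):
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, c, d, h, w = x.shape
        k, s, p = self.k, self.stride, self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p), (p, p)),
                    constant_values=-np.inf)
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k, k),
                                                       axis=(2, 3, 4))
        win = win[:, :, ::s, ::s, ::s]
        od, oh, ow = win.shape[2:5]
        flat = win.reshape(n, c, od, oh, ow, k**3)
        arg = flat.argmax(axis=-1)
        out = np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0]
        self._arg = arg
        self._pad_sp = xp.shape[2:]
        self._in_shape = x.shape
        self._out_sp = (od, oh, ow)
        return out.astype(np.float32, copy=False)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c = self._in_shape[:2]
        dp, hp, wp = self._pad_sp
        k, s = self.k, self.stride
        od, oh, ow = self._out_sp
        key = (self._pad_sp, self._out_sp)
        if self._idx_map is None or self._idx_key != key:
            d0 = (np.arange(od) * s)[:, None, None, None, None, None]
            h0 = (np.arange(oh) * s)[None, :, None, None, None, None]
            w0 = (np.arange(ow) * s)[None, None, :, None, None, None]
            kd = np.arange(k)[None, None, None, :, None, None]
            kh = np.arange(k)[None, None, None, None, :, None]
            kw = np.arange(k)[None, None, None, None, None, :]
            idx = ((d0 + kd) * hp + h0 + kh) * wp + w0 + kw
            self._idx_map = idx.reshape(od * oh * ow, k**3)
            self._idx_key = key
        p_count = od * oh * ow
        arg = self._arg.reshape(n * c, p_count)
        sel = self._idx_map[np.arange(p_count)[None, :], arg]
        vox = dp * hp * wp
        offsets = (np.arange(n * c) * vox)[:, None]
        flat = np.bincount((sel + offsets).ravel(),
                           weights=dout.reshape(n * c, p_count).astype(
                               np.float64).ravel(),
                           minlength=n * c * vox)
        dxp = flat.reshape(n, c, dp, hp, wp).astype(np.float32)
        p = self.pad
        if p:
            dxp = dxp[:, :, p:-p, p:-p, p:-p]
        self._arg = None
        return dxp


class GlobalAvgPool:
    def params(self):
        return []

    def grads(self):
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._sp = x.shape[2:]
        return x.mean(axis=(2, 3, 4)).astype(np.float32)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        d, h, w = self._sp
        scale = 1.0 / (d * h * w)
        return (dout[:, :, None, None, None]
                * np.full((1, 1, d, h, w), scale, dtype=np.float32))


class Linear:
    def __init__(self, nin: int, nout: int, rng: np.random.Generator):
        self.W = rng.normal(0.0, np.sqrt(2.0 / nin),
                            size=(nout, nin)).astype(np.float32)
        self.b = np.zeros(nout, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._x = x
        return x @ self.W.T + self.b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.dW[...] = dout.T @ self._x
        self.db[...] = dout.sum(axis=0)
        dx = dout @ self.W
        self._x = None
        return dx.astype(np.float32)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class SoftmaxCrossEntropy:
    """Combined softmax + mean cross-entropy over the batch."""

    def forward(self, logits: np.ndarray, y: np.ndarray) -> float:
        self._p = softmax(logits.astype(np.float64))
        self._y = y
        n = len(y)
        return float(-np.log(self._p[np.arange(n), y] + 1e-12).mean())

    def backward(self) -> np.ndarray:
        n = len(self._y)
        d = self._p.copy()
        d[np.arange(n), self._y] -= 1.0
        return (d / n).astype(np.float32)


class Adam:
    """Adaptive moment estimation with bias correction.

    ``weight_decay`` is an L2 penalty added to the gradient (the convention
    of the optimizer implementation the training recipe references); it is
    applied only to parameters flagged in ``decay_mask`` (weight matrices,
    not biases or normalization parameters).
    """

    def __init__(self, params: list[np.ndarray], grads: list[np.ndarray],
                 lr: float = 1e-4, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8, weight_decay: float = 0.0,
                 decay_mask: list[bool] | None = None):
        self.params, self.grad_refs = params, grads
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.weight_decay = weight_decay
        self.decay_mask = decay_mask or [p.ndim > 1 for p in params]
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for p, g, m, v, dec in zip(self.params, self.grad_refs, self.m,
                                   self.v, self.decay_mask):
            if self.weight_decay and dec:
                g = g + self.weight_decay * p
            m += (1.0 - self.beta1) * (g - m)
            v += (1.0 - self.beta2) * (g * g - v)
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
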