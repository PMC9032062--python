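"""Minimal numpy neural-network engine.

Implements exactly the layer vocabulary the classifier architectures
need — 2-D convolution with size-preserving padding, batch
normalization, leaky rectifiers, boundary-truncating max pooling,
dropout, GRU/LSTM recurrences, dense layers — plus the Adam optimizer
and binary cross-entropy on logits.  Convolutions are evaluated in the
frequency domain (real FFTs over the spatial axes, per-bin
channel-mixing matrix products); the gradient with respect to the
convolution input is the full convolution with the spatially flipped,
channel-transposed kernel, and the weight gradient a correlation of
the padded input with the output gradient, all on the same FFT grid.

Layout convention: batches are (N, time, electrode, channels) for 2-D
stages and (N, time, features) for recurrent stages.  All parameters
are float32 unless a layer is built with ``dtype=np.float64`` (used by
the finite-difference gradient checks).
"""

from __future__ import annotations

import math

import numpy as np

__all__ = [
    "Dense",
    "Flatten",
    "Squeeze",
    "ZeroPadTime",
    "BatchNorm",
    "Conv2D",
    "LeakyReLU",
    "ReLU",
    "MaxPool2D",
    "Dropout",
    "GRU",
    "LSTM",
    "Model",
    "Adam",
    "sigmoid",
    "bce_with_logits",
]


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_with_logits(z: np.ndarray, y: np.ndarray) -> float:
    """Mean binary cross-entropy, numerically stable in the logits."""
    z = np.asarray(z, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    return float(np.mean(np.logaddexp(0.0, z) - y * z))


def _glorot(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int,
            fan_out: int, dtype) -> np.ndarray:
    limit = math.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


class Layer:
    """Base layer: stateless by default, with empty parameter lists."""

    def __init__(self) -> None:
        self.params: list[np.ndarray] = []
        self.grads: list[np.ndarray] = []

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 dtype=np.float32) -> None:
        super().__init__()
        self.w = _glorot(rng, (n_in, n_out), n_in, n_out, dtype)
        self.b = np.zeros(n_out, dtype=dtype)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def forward(self, x, training):
        self._x = x
        return x @ self.w + self.b

    def backward(self, dy):
        self.grads[0][...] = self._x.T @ dy
        self.grads[1][...] = dy.sum(axis=0)
        return dy @ self.w.T


class Flatten(Layer):
    def forward(self, x, training):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class Squeeze(Layer):
    """Drop a singleton axis (electrode axis fully pooled away)."""

    def __init__(self, axis: int = 2) -> None:
        super().__init__()
        self.axis = axis

    def forward(self, x, training):
        if x.shape[self.axis] != 1:
            raise ValueError(f"axis {self.axis} of {x.shape} is not singleton")
        self._shape = x.shape
        return np.squeeze(x, axis=self.axis)

    def backward(self, dy):
        return dy.reshape(self._shape)


class FoldWidth(Layer):
    """(N, T, W, C) -> (N, T, W*C): stack spatial remnants into features."""

    def forward(self, x, training):
        self._shape = x.shape
        n, t, w, c = x.shape
        return x.reshape(n, t, w * c)

    def backward(self, dy):
        return dy.reshape(self._shape)


class ZeroPadTime(Layer):
    """Symmetric zero padding along the time axis (axis 1)."""

    def __init__(self, pad: int) -> None:
        super().__init__()
        self.pad = pad

    def forward(self, x, training):
        p = self.pad
        return np.pad(x, ((0, 0), (p, p)) + ((0, 0),) * (x.ndim - 2))

    def backward(self, dy):
        p = self.pad
        return dy[:, p : dy.shape[1] - p]


class BatchNorm(Layer):
    """Per-feature-channel normalization over batch and spatial axes."""

    def __init__(self, n_channels: int, momentum: float = 0.9,
                 eps: float = 1e-5, dtype=np.float32) -> None:
        super().__init__()
        self.gamma = np.ones(n_channels, dtype=dtype)
        self.beta = np.zeros(n_channels, dtype=dtype)
        self.params = [self.gamma, self.beta]
        self.grads = [np.zeros_like(self.gamma), np.zeros_like(self.beta)]
        self.momentum = momentum
        self.eps = eps
        self.run_mean = np.zeros(n_channels, dtype=np.float64)
        self.run_var = np.ones(n_channels, dtype=np.float64)

    def forward(self, x, training):
        axes = tuple(range(x.ndim - 1))
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            self.run_mean = m * self.run_mean + (1 - m) * mean.astype(np.float64)
            self.run_var = m * self.run_var + (1 - m) * var.astype(np.float64)
        else:
            mean = self.run_mean.astype(x.dtype)
            var = self.run_var.astype(x.dtype)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv
        self._cache = (xhat, inv.astype(x.dtype), training, axes)
        return self.gamma * xhat + self.beta

    def backward(self, dy):
        xhat, inv, training, axes = self._cache
        self.grads[0][...] = (dy * xhat).sum(axis=axes)
        self.grads[1][...] = dy.sum(axis=axes)
        if not training:
            return dy * self.gamma * inv
        m = np.prod([xhat.shape[a] for a in axes])
        dxhat = dy * self.gamma
        return (
            dxhat - dxhat.mean(axis=axes) - xhat * (dxhat * xhat).mean(axis=axes)
        ) * inv


def _bin_matmul(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Batched per-frequency-bin product: (A,B,n,k) @ (A,B,k,m)."""
    return np.matmul(a, b)


class Conv2D(Layer):
    """2-D convolution, stride 1, size-preserving ('same') padding.

    Kernels must have odd extents; kernel orientation (time, electrode)
    is whatever shape the caller passes.  Forward and both backward
    products are evaluated in the frequency domain (real FFTs over the
    two spatial axes, per-bin channel-mixing matrix products): for the
    large activation maps and 23 x 5 kernels used here this is an order
    of magnitude cheaper than direct or im2col convolution, and exact up
    to floating-point rounding.
    """

    def __init__(self, kh: int, kw: int, cin: int, cout: int,
                 rng: np.random.Generator, dtype=np.float32) -> None:
        super().__init__()
        if kh % 2 == 0 or kw % 2 == 0:
            raise ValueError("kernel extents must be odd for 'same' padding")
        fan_in = kh * kw * cin
        self.w = _glorot(rng, (kh, kw, cin, cout), fan_in, kh * kw * cout, dtype)
        self.b = np.zeros(cout, dtype=dtype)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def _fft_sizes(self, h: int, wid: int) -> tuple[int, int]:
        from scipy.fft import next_fast_len

        kh, kw = self.w.shape[:2]
        # transforms of the padded extent suffice: with kernel size
        # 2p+1 and padding p per side, circular wrap-around only
        # contaminates lags outside the retained output range
        return (
            next_fast_len(h + 2 * (kh // 2), real=True),
            next_fast_len(wid + 2 * (kw // 2), real=True),
        )

    def forward(self, x, training):
        from scipy.fft import irfft2, rfft2

        kh, kw, cin, cout = self.w.shape
        n, h, wid, _ = x.shape
        ph, pw = kh // 2, kw // 2
        s = self._fft_sizes(h, wid)
        xp = np.pad(x, ((0, 0), (ph, ph), (pw, pw), (0, 0)))
        xf = rfft2(xp, s=s, axes=(1, 2)).transpose(1, 2, 0, 3)  # (A,B,N,Cin)
        kf = rfft2(self.w, s=s, axes=(0, 1))  # (A,B,Cin,Cout)
        yf = _bin_matmul(xf, np.conj(kf))  # circular correlation
        y = irfft2(yf.transpose(2, 0, 1, 3), s=s, axes=(1, 2))[:, :h, :wid, :]
        self._cache = (xf, kf, s, (n, h, wid, cin)) if training else None
        return np.ascontiguousarray(y, dtype=x.dtype) + self.b

    def backward(self, dy):
        from scipy.fft import irfft2, rfft2

        kh, kw, cin, cout = self.w.shape
        xf, kf, s, (n, h, wid, _) = self._cache
        self._cache = None
        ph, pw = kh // 2, kw // 2
        self.grads[1][...] = dy.sum(axis=(0, 1, 2))
        dyf = rfft2(dy, s=s, axes=(1, 2)).transpose(1, 2, 0, 3)  # (A,B,N,Cout)
        # weight gradient: correlation of padded input with output grad
        dwf = _bin_matmul(np.conj(dyf).transpose(0, 1, 3, 2), xf)  # (A,B,Cout,Cin)
        dw = irfft2(dwf, s=s, axes=(0, 1))[:kh, :kw]
        self.grads[0][...] = dw.transpose(0, 1, 3, 2).astype(self.w.dtype)
        # input gradient: full convolution of output grad with the kernel
        dxf = _bin_matmul(dyf, kf.transpose(0, 1, 3, 2))  # (A,B,N,Cin)
        dxp = irfft2(dxf.transpose(2, 0, 1, 3), s=s, axes=(1, 2))
        return dxp[:, ph : ph + h, pw : pw + wid, :].astype(dy.dtype, copy=False)


def _conv2d_same(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Functional size-preserving correlation (reference/tests)."""
    rng = np.random.default_rng(0)
    layer = Conv2D(w.shape[0], w.shape[1], w.shape[2], w.shape[3], rng,
                   dtype=x.dtype)
    layer.w[...] = w
    layer.b[...] = 0
    return layer.forward(x, training=False)


class LeakyReLU(Layer):
    def __init__(self, alpha: float = 0.3) -> None:
        super().__init__()
        self.alpha = alpha

    def forward(self, x, training):
        self._neg = x < 0
        return np.where(self._neg, self.alpha * x, x)

    def backward(self, dy):
        return np.where(self._neg, self.alpha * dy, dy)


class ReLU(LeakyReLU):
    def __init__(self) -> None:
        super().__init__(alpha=0.0)


def _pool_axis_forward(x: np.ndarray, axis: int, k: int, s: int):
    """Max pool axis 1 or 2 of (N,H,W,C); n_out = floor((n-k)/s)+1."""
    n = x.shape[axis]
    n_out = (n - k) // s + 1
    if n_out < 1:
        raise ValueError(f"axis of length {n} too short for pool {k}/{s}")
    if s == k:
        if axis == 1:
            xr = np.ascontiguousarray(x[:, : n_out * k]).reshape(
                x.shape[0], n_out, k, *x.shape[2:]
            )
            idx = xr.argmax(axis=2)
            y = np.take_along_axis(xr, idx[:, :, None], axis=2)[:, :, 0]
        else:
            xr = np.ascontiguousarray(x[:, :, : n_out * k]).reshape(
                x.shape[0], x.shape[1], n_out, k, x.shape[3]
            )
            idx = xr.argmax(axis=3)
            y = np.take_along_axis(xr, idx[:, :, :, None], axis=3)[:, :, :, 0]
        return y, ("reshape", idx, x.shape, axis, k, s)
    if s == 1:
        sl = (slice(None),) * axis
        y = x[sl + (slice(0, n_out),)].copy()
        for o in range(1, k):
            np.maximum(y, x[sl + (slice(o, o + n_out),)], out=y)
        return y, ("overlap", x, y, x.shape, axis, k, s)
    raise NotImplementedError("pooling supports stride==k or stride==1")


def _pool_axis_backward(dy: np.ndarray, cache) -> np.ndarray:
    mode = cache[0]
    if mode == "reshape":
        _, idx, shape, axis, k, s = cache
        n_out = dy.shape[axis]
        dx = np.zeros(shape, dtype=dy.dtype)
        if axis == 1:
            dxr = np.zeros((shape[0], n_out, k) + shape[2:], dtype=dy.dtype)
            np.put_along_axis(dxr, idx[:, :, None], dy[:, :, None], axis=2)
            dx[:, : n_out * k] = dxr.reshape((shape[0], n_out * k) + shape[2:])
        else:
            dxr = np.zeros((shape[0], shape[1], n_out, k, shape[3]), dtype=dy.dtype)
            np.put_along_axis(dxr, idx[:, :, :, None], dy[:, :, :, None], axis=3)
            dx[:, :, : n_out * k] = dxr.reshape(shape[0], shape[1], n_out * k, shape[3])
        return dx
    _, x, y, shape, axis, k, s = cache
    n_out = dy.shape[axis]
    dx = np.zeros(shape, dtype=dy.dtype)
    sl = (slice(None),) * axis
    unclaimed = np.ones(dy.shape, dtype=bool)
    for o in range(k):
        win = (slice(o, o + n_out),)
        sel = (x[sl + win] == y) & unclaimed
        dx[sl + win][sel] += dy[sel]
        unclaimed &= ~sel
    return dx


class MaxPool2D(Layer):
    """Separable max pooling over (time, electrode) axes."""

    def __init__(self, kh: int, kw: int, sh: int, sw: int) -> None:
        super().__init__()
        self.kh, self.kw, self.sh, self.sw = kh, kw, sh, sw

    def forward(self, x, training):
        y, self._ch = _pool_axis_forward(x, 1, self.kh, self.sh)
        y, self._cw = _pool_axis_forward(y, 2, self.kw, self.sw)
        return y

    def backward(self, dy):
        dy = _pool_axis_backward(dy, self._cw)
        return _pool_axis_backward(dy, self._ch)


class Dropout(Layer):
    def __init__(self, p: float, rng: np.random.Generator) -> None:
        super().__init__()
        self.p = p
        self.rng = rng

    def forward(self, x, training):
        if not training or self.p <= 0:
            self._mask = None
            return x
        keep = 1.0 - self.p
        u = self.rng.random(x.shape, dtype=np.float32)
        self._mask = (u < keep).astype(x.dtype) / x.dtype.type(keep)
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


class GRU(Layer):
    """Gated recurrent unit over (N, T, features) sequences.

    Gate order (z, r, h); state update h_t = (1-z)*h_{t-1} + z*hcand.
    """

    def __init__(self, n_in: int, units: int, rng: np.random.Generator,
                 return_sequences: bool = False, dtype=np.float32) -> None:
        super().__init__()
        self.units = units
        self.return_sequences = return_sequences
        self.w = _glorot(rng, (n_in, 3 * units), n_in, units, dtype)
        self.u = _glorot(rng, (units, 3 * units), units, units, dtype)
        self.b = np.zeros(3 * units, dtype=dtype)
        self.params = [self.w, self.u, self.b]
        self.grads = [np.zeros_like(p) for p in self.params]

    def forward(self, x, training):
        n, t, _ = x.shape
        u = self.units
        h = np.zeros((n, u), dtype=x.dtype)
        hs = np.zeros((n, t, u), dtype=x.dtype)
        cache = []
        xw = x @ self.w + self.b  # (N, T, 3u)
        for i in range(t):
            hu = h @ self.u
            z = sigmoid(xw[:, i, :u] + hu[:, :u]).astype(x.dtype)
            r = sigmoid(xw[:, i, u : 2 * u] + hu[:, u : 2 * u]).astype(x.dtype)
            hc = np.tanh(xw[:, i, 2 * u :] + (r * h) @ self.u[:, 2 * u :])
            h_new = (1.0 - z) * h + z * hc
            cache.append((h, z, r, hc))
            h = h_new
            hs[:, i] = h
        self._cache = (x, cache)
        return hs if self.return_sequences else h

    def backward(self, dy):
        x, cache = self._cache
        n, t, _ = x.shape
        u = self.units
        dw = self.grads[0]
        du = self.grads[1]
        db = self.grads[2]
        dw[...] = 0.0
        du[...] = 0.0
        db[...] = 0.0
        dx = np.zeros_like(x)
        dh = np.zeros((n, u), dtype=x.dtype)
        for i in range(t - 1, -1, -1):
            h_prev, z, r, hc = cache[i]
            if self.return_sequences:
                dh = dh + dy[:, i]
            elif i == t - 1:
                dh = dh + dy
            dz = dh * (hc - h_prev) * z * (1.0 - z)
            dhc = dh * z * (1.0 - hc * hc)
            dr = (dhc @ self.u[:, 2 * u :].T) * h_prev * r * (1.0 - r)
            dg = np.concatenate([dz, dr, dhc], axis=1)  # (N, 3u)
            dw += x[:, i].T @ dg
            db += dg.sum(axis=0)
            du[:, : 2 * u] += h_prev.T @ dg[:, : 2 * u]
            du[:, 2 * u :] += (r * h_prev).T @ dhc
            dx[:, i] = dg @ self.w.T
            dh = (
                dh * (1.0 - z)
                + dg[:, : 2 * u] @ self.u[:, : 2 * u].T
                + (dhc @ self.u[:, 2 * u :].T) * r
            )
        return dx


class LSTM(Layer):
    """Long short-term memory over (N, T, features); gate order (i, f, c, o)."""

    def __init__(self, n_in: int, units: int, rng: np.random.Generator,
                 return_sequences: bool = False, dtype=np.float32) -> None:
        super().__init__()
        self.units = units
        self.return_sequences = return_sequences
        self.w = _glorot(rng, (n_in, 4 * units), n_in, units, dtype)
        self.u = _glorot(rng, (units, 4 * units), units, units, dtype)
        self.b = np.zeros(4 * units, dtype=dtype)
        self.b[units : 2 * units] = 1.0  # forget-gate bias
        self.params = [self.w, self.u, self.b]
        self.grads = [np.zeros_like(p) for p in self.params]

    def forward(self, x, training):
        n, t, _ = x.shape
        u = self.units
        h = np.zeros((n, u), dtype=x.dtype)
        c = np.zeros((n, u), dtype=x.dtype)
        hs = np.zeros((n, t, u), dtype=x.dtype)
        cache = []
        xw = x @ self.w + self.b
        for k in range(t):
            g = xw[:, k] + h @ self.u
            i_g = sigmoid(g[:, :u]).astype(x.dtype)
            f_g = sigmoid(g[:, u : 2 * u]).astype(x.dtype)
            c_g = np.tanh(g[:, 2 * u : 3 * u])
            o_g = sigmoid(g[:, 3 * u :]).astype(x.dtype)
            c_new = f_g * c + i_g * c_g
            tc = np.tanh(c_new)
            cache.append((h, c, i_g, f_g, c_g, o_g, tc))
            c = c_new
            h = o_g * tc
            hs[:, k] = h
        self._cache = (x, cache)
        return hs if self.return_sequences else h

    def backward(self, dy):
        x, cache = self._cache
        n, t, _ = x.shape
        u = self.units
        dw, du, db = self.grads
        dw[...] = 0.0
        du[...] = 0.0
        db[...] = 0.0
        dx = np.zeros_like(x)
        dh = np.zeros((n, u), dtype=x.dtype)
        dc = np.zeros((n, u), dtype=x.dtype)
        for k in range(t - 1, -1, -1):
            h_prev, c_prev, i_g, f_g, c_g, o_g, tc = cache[k]
            if self.return_sequences:
                dh = dh + dy[:, k]
            elif k == t - 1:
                dh = dh + dy
            do = dh * tc * o_g * (1.0 - o_g)
            dc = dc + dh * o_g * (1.0 - tc * tc)
            di = dc * c_g * i_g * (1.0 - i_g)
            df = dc * c_prev * f_g * (1.0 - f_g)
            dcg = dc * i_g * (1.0 - c_g * c_g)
            dg = np.concatenate([di, df, dcg, do], axis=1)
            dw += x[:, k].T @ dg
            du += h_prev.T @ dg
            db += dg.sum(axis=0)
            dx[:, k] = dg @ self.w.T
            dh = dg @ self.u.T
            dc = dc * f_g
        return dx


class Adam:
    """Adam optimizer over a model's (params, grads) pairs."""

    def __init__(self, model: "Model", lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-7) -> None:
        self.model = model
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p) for p, _ in model.param_grad_pairs()]
        self.v = [np.zeros_like(p) for p, _ in model.param_grad_pairs()]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        corr1 = 1.0 - b1**self.t
        corr2 = 1.0 - b2**self.t
        for i, (p, g) in enumerate(self.model.param_grad_pairs()):
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / corr1
            vhat = self.v[i] / corr2
            p -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(p.dtype)


class Model:
    """Sequential binary classifier with a sigmoid output on one logit."""

    def __init__(self, layers: list[Layer], input_shape: tuple[int, ...],
                 dtype=np.float32) -> None:
        self.layers = layers
        self.input_shape = tuple(input_shape)
        self.dtype = dtype

    def param_grad_pairs(self):
        return [
            (p, g)
            for layer in self.layers
            for p, g in zip(layer.params, layer.grads)
        ]

    @property
    def n_params(self) -> int:
        return sum(p.size for p, _ in self.param_grad_pairs())

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        h = np.ascontiguousarray(x, dtype=self.dtype)
        shapes = [h.shape]
        for layer in self.layers:
            h = layer.forward(h, training)
            shapes.append(h.shape)
        self.last_shapes = shapes
        return h[:, 0]  # single logit

    def backward(self, dlogit: np.ndarray) -> None:
        g = dlogit[:, None].astype(self.dtype)
        for layer in reversed(self.layers):
            g = layer.backward(g)

    def train_step(self, xb: np.ndarray, yb: np.ndarray, opt: Adam) -> float:
        z = self.forward(xb, training=True)
        loss = bce_with_logits(z, yb)
        dlogit = (sigmoid(z) - yb) / len(yb)
        self.backward(dlogit)
        opt.step()
        return loss

    def predict_logits(self, x: np.ndarray, batch_size: int = 32) -> np.ndarray:
        out = np.empty(len(x), dtype=np.float64)
        for a in range(0, len(x), batch_size):
            out[a : a + batch_size] = self.forward(x[a : a + batch_size], False)
        return out

    def predict_proba(self, x: np.ndarray, batch_size: int = 32) -> np.ndarray:
        return sigmoid(self.predict_logits(x, batch_size))

    def _state_arrays(self) -> list[np.ndarray]:
        arrays = [p for p, _ in self.param_grad_pairs()]
        for layer in self.layers:
            if isinstance(layer, BatchNorm):
                arrays.extend([layer.run_mean, layer.run_var])
        return arrays

    def get_weights(self) -> list[np.ndarray]:
        """Snapshot of all parameters plus batch-norm running statistics."""
        return [a.copy() for a in self._state_arrays()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        arrays = self._state_arrays()
        if len(weights) != len(arrays):
            raise ValueError("weight list length mismatch")
        for a, w in zip(arrays, weights):
            a[...] = w
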