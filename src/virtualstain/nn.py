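"""Minimal CPU neural-network backbone: layers with explicit backprop.

Everything runs on numpy float64 arrays in NCHW layout.  Each layer exposes
``forward(x, train)`` / ``backward(dy)``, a dict of named parameters and a
matching dict of accumulated gradients.  Convolutions use SAME padding with
stride ``s`` (output spatial size = ceil(in / s)); the transposed convolution
is implemented as the exact adjoint of that operator, so a stride-2 transpose
doubles the spatial size and adjointness can be verified directly:
``<conv(x), y> == <x, conv_T(y)>``.
"""

from __future__ import annotations

import numpy as np

# ---------------------------------------------------------------------------
# im2col / col2im


def _same_pads(size: int, k: int, s: int) -> tuple[int, int, int]:
    out = -(-size // s)  # ceil
    total = max((out - 1) * s + k - size, 0)
    return out, total // 2, total - total // 2


def _im2col(xp: np.ndarray, k: int, s: int, oh: int, ow: int) -> np.ndarray:
    n, c = xp.shape[:2]
    cols = np.empty((n, c, k, k, oh, ow), dtype=xp.dtype)
    for ki in range(k):
        for kj in range(k):
            cols[:, :, ki, kj] = xp[:, :, ki:ki + s * oh:s, kj:kj + s * ow:s]
    return cols.reshape(n, c * k * k, oh * ow)


def _col2im(cols: np.ndarray, xp_shape: tuple, k: int, s: int, oh: int, ow: int) -> np.ndarray:
    n, c = xp_shape[:2]
    xp = np.zeros(xp_shape, dtype=cols.dtype)
    cols = cols.reshape(n, c, k, k, oh, ow)
    for ki in range(k):
        for kj in range(k):
            xp[:, :, ki:ki + s * oh:s, kj:kj + s * ow:s] += cols[:, :, ki, kj]
    return xp


class Layer:
    """Base layer: no parameters, identity wiring."""

    def params(self) -> dict[str, np.ndarray]:
        return {}

    def grads(self) -> dict[str, np.ndarray]:
        return {}

    def state(self) -> dict[str, np.ndarray]:
        """Parameters plus non-trainable buffers (running stats)."""
        return dict(self.params())

    def load_state(self, state: dict[str, np.ndarray]) -> None:
        own = self.state()
        for k, v in state.items():
            own[k][...] = v


class Conv2d(Layer):
    """SAME-padded strided convolution."""

    def __init__(self, in_ch: int, out_ch: int, k: int, stride: int, rng: np.random.Generator):
        self.in_ch, self.out_ch, self.k, self.s = in_ch, out_ch, k, stride
        std = np.sqrt(2.0 / (in_ch * k * k))
        self.W = rng.normal(0.0, std, size=(out_ch, in_ch * k * k))
        self.b = np.zeros(out_ch)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return {"W": self.W, "b": self.b}

    def grads(self):
        return {"W": self.dW, "b": self.db}

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        oh, pt, pb = _same_pads(h, self.k, self.s)
        ow, pl, pr = _same_pads(w, self.k, self.s)
        xp = np.pad(x, ((0, 0), (0, 0), (pt, pb), (pl, pr)))
        cols = _im2col(xp, self.k, self.s, oh, ow)
        y = np.matmul(self.W[None], cols) + self.b[None, :, None]
        self._cache = (cols, xp.shape, (pt, pb, pl, pr), (h, w), (oh, ow))
        return y.reshape(n, self.out_ch, oh, ow)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        cols, xp_shape, (pt, pb, pl, pr), (h, w), (oh, ow) = self._cache
        n = dy.shape[0]
        dyr = dy.reshape(n, self.out_ch, oh * ow)
        self.dW += np.einsum("nop,nkp->ok", dyr, cols)
        self.db += dyr.sum(axis=(0, 2))
        dcols = np.matmul(self.W.T[None], dyr)
        dxp = _col2im(dcols, xp_shape, self.k, self.s, oh, ow)
        return dxp[:, :, pt:pt + h, pl:pl + w]


class ConvTranspose2d(Layer):
    """Adjoint of :class:`Conv2d`; stride-2 transpose doubles spatial size."""

    def __init__(self, in_ch: int, out_ch: int, k: int, stride: int, rng: np.random.Generator):
        self.in_ch, self.out_ch, self.k, self.s = in_ch, out_ch, k, stride
        std = np.sqrt(2.0 / (in_ch * k * k))
        # stored as the weights of the adjoint conv (out_ch -> in_ch)
        self.W = rng.normal(0.0, std, size=(in_ch, out_ch * k * k))
        self.b = np.zeros(out_ch)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return {"W": self.W, "b": self.b}

    def grads(self):
        return {"W": self.dW, "b": self.db}

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        H, W_ = h * self.s, w * self.s
        oh, pt, pb = _same_pads(H, self.k, self.s)
        ow, pl, pr = _same_pads(W_, self.k, self.s)
        assert (oh, ow) == (h, w)
        xr = x.reshape(n, self.in_ch, h * w)
        cols = np.matmul(self.W.T[None], xr)
        yp = _col2im(cols, (n, self.out_ch, H + pt + pb, W_ + pl + pr), self.k, self.s, oh, ow)
        y = yp[:, :, pt:pt + H, pl:pl + W_] + self.b[None, :, None, None]
        self._cache = (x, (H, W_), (pt, pb, pl, pr), (oh, ow))
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x, (H, W_), (pt, pb, pl, pr), (oh, ow) = self._cache
        n = dy.shape[0]
        dyp = np.pad(dy, ((0, 0), (0, 0), (pt, pb), (pl, pr)))
        dcols = _im2col(dyp, self.k, self.s, oh, ow)
        xr = x.reshape(n, self.in_ch, oh * ow)
        self.dW += np.einsum("nip,nkp->ik", xr, dcols)
        self.db += dy.sum(axis=(0, 2, 3))
        dx = np.matmul(self.W[None], dcols)
        return dx.reshape(x.shape)


class BatchNorm2d(Layer):
    """Per-channel batch normalization with running statistics for inference."""

    def __init__(self, ch: int, momentum: float = 0.9, eps: float = 1e-5):
        self.ch, self.momentum, self.eps = ch, momentum, eps
        self.gamma = np.ones(ch)
        self.beta = np.zeros(ch)
        self.run_mean = np.zeros(ch)
        self.run_var = np.ones(ch)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)

    def params(self):
        return {"gamma": self.gamma, "beta": self.beta}

    def grads(self):
        return {"gamma": self.dgamma, "beta": self.dbeta}

    def state(self):
        return {"gamma": self.gamma, "beta": self.beta,
                "run_mean": self.run_mean, "run_var": self.run_var}

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.run_mean = self.momentum * self.run_mean + (1 - self.momentum) * mean
            self.run_var = self.momentum * self.run_var + (1 - self.momentum) * var
        else:
            mean, var = self.run_mean, self.run_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        self._cache = (xhat, inv, x.shape, train)
        return self.gamma[None, :, None, None] * xhat + self.beta[None, :, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv, shape, train = self._cache
        m = shape[0] * shape[2] * shape[3]
        self.dgamma += (dy * xhat).sum(axis=(0, 2, 3))
        self.dbeta += dy.sum(axis=(0, 2, 3))
        g = self.gamma[None, :, None, None]
        if not train:
            return dy * g * inv[None, :, None, None]
        dxhat = dy * g
        t1 = dxhat - dxhat.mean(axis=(0, 2, 3), keepdims=True)
        t2 = xhat * (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True) / m
        return inv[None, :, None, None] * (t1 - t2)


class Dense(Layer):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        self.W = rng.normal(0.0, np.sqrt(2.0 / d_in), size=(d_in, d_out))
        self.b = np.zeros(d_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return {"W": self.W, "b": self.b}

    def grads(self):
        return {"W": self.dW, "b": self.db}

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.dW += self._x.T @ dy
        self.db += dy.sum(axis=0)
        return dy @ self.W.T


class LeakyReLU(Layer):
    def __init__(self, alpha: float = 0.2):
        self.alpha = alpha

    def forward(self, x, train=True):
        self._mask = x > 0
        return np.where(self._mask, x, self.alpha * x)

    def backward(self, dy):
        return np.where(self._mask, dy, self.alpha * dy)


class ReLU(Layer):
    def forward(self, x, train=True):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class Tanh(Layer):
    def forward(self, x, train=True):
        self._y = np.tanh(x)
        return self._y

    def backward(self, dy):
        return dy * (1.0 - self._y ** 2)


class Sigmoid(Layer):
    def forward(self, x, train=True):
        self._y = 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))
        return self._y

    def backward(self, dy):
        return dy * self._y * (1.0 - self._y)


class Flatten(Layer):
    def forward(self, x, train=True):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x, train=True):
        for lay in self.layers:
            x = lay.forward(x, train)
        return x

    def backward(self, dy):
        for lay in reversed(self.layers):
            dy = lay.backward(dy)
        return dy

    def _named(self, what):
        out = {}
        for i, lay in enumerate(self.layers):
            for k, v in getattr(lay, what)().items():
                out[f"{i}/{k}"] = v
        return out

    def params(self):
        return self._named("params")

    def grads(self):
        return self._named("grads")

    def state(self):
        out = {}
        for i, lay in enumerate(self.layers):
            for k, v in lay.state().items():
                out[f"{i}/{k}"] = v
        return out

    def load_state(self, state):
        own = self.state()
        if set(own) != set(state):
            raise ValueError("state keys do not match network structure")
        for k, v in state.items():
            own[k][...] = v


class Adam:
    """Adaptive-momentum optimizer (standard defaults beta1=0.9, beta2=0.999)."""

    def __init__(self, lr: float = 2e-4, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m: dict[str, np.ndarray] = {}
        self.v: dict[str, np.ndarray] = {}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        for k, p in params.items():
            g = grads[k]
            if k not in self.m:
                self.m[k] = np.zeros_like(p)
                self.v[k] = np.zeros_like(p)
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def zero_grads(net: Layer) -> None:
    for g in net.grads().values():
        g[...] = 0.0


def l1_norm(params: dict[str, np.ndarray]) -> float:
    return float(sum(np.abs(p).sum() for p in params.values()))
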