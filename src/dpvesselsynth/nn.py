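"""Minimal NumPy neural-network backend with per-sample gradients.

The DP-SGD mechanism needs the gradient of the loss with respect to every
parameter *for each sample individually* (to clip per-sample norms before
aggregation).  Mainstream autodiff frameworks hide that quantity, so the
layers here keep the batch axis all the way through the backward pass:
``layer.psg[name]`` holds an array of shape ``(batch, *param.shape)`` after
``backward``, and the conventional summed gradient is its sum over axis 0.

Only the operations the package's networks need are implemented: dense,
strided convolution (im2col), nearest-neighbour upsampling, 2x2 max
pooling, dropout, the usual activations, and an RMSprop/Adam optimizer.
Everything is deterministic given the seeds of the generators passed in.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

#: all parameters and activations are single precision: the networks are
#: small and shallow, and the halved memory traffic roughly doubles speed
DTYPE = np.float32

__all__ = [
    "Layer",
    "Dense",
    "Conv2d",
    "LeakyReLU",
    "ReLU",
    "Tanh",
    "Sigmoid",
    "Upsample2x",
    "MaxPool2x",
    "Dropout",
    "Flatten",
    "Reshape",
    "Sequential",
    "RMSprop",
    "Adam",
    "flatten_per_sample",
    "unflatten_gradient",
]


class Layer:
    """Base layer: parameters in ``params``, per-sample grads in ``psg``."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.psg: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def grad(self, name: str) -> np.ndarray:
        return self.psg[name].sum(axis=0)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        scale = np.sqrt(2.0 / n_in)
        self.params["W"] = rng.normal(0, scale, size=(n_out, n_in)).astype(DTYPE)
        self.params["b"] = np.zeros(n_out, dtype=DTYPE)

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._x = x
        return x @ self.params["W"].T + self.params["b"]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.psg["W"] = np.einsum("bo,bi->boi", dy, self._x, optimize=True)
        self.psg["b"] = dy.copy()
        return dy @ self.params["W"]


def _im2col(x: np.ndarray, k: int, stride: int) -> np.ndarray:
    """(B, C, H, W) -> (B, C*k*k, L) column matrix of k x k patches."""
    win = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]  # (B, C, Ho, Wo, k, k)
    B, C, Ho, Wo, _, _ = win.shape
    cols = win.transpose(0, 1, 4, 5, 2, 3).reshape(B, C * k * k, Ho * Wo)
    return np.ascontiguousarray(cols), (Ho, Wo)


class Conv2d(Layer):
    """2-D convolution (cross-correlation) via im2col.

    ``pad`` is symmetric zero padding; output spatial size is
    ``(H + 2 pad - k) // stride + 1``.
    """

    def __init__(
        self,
        c_in: int,
        c_out: int,
        k: int,
        rng: np.random.Generator,
        stride: int = 1,
        pad: int = 0,
    ):
        super().__init__()
        self.c_in, self.c_out, self.k, self.stride, self.pad = c_in, c_out, k, stride, pad
        scale = np.sqrt(2.0 / (c_in * k * k))
        self.params["W"] = rng.normal(0, scale, size=(c_out, c_in * k * k)).astype(DTYPE)
        self.params["b"] = np.zeros(c_out, dtype=DTYPE)

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if self.pad:
            x = np.pad(x, ((0, 0), (0, 0), (self.pad,) * 2, (self.pad,) * 2))
        self._shape_padded = x.shape
        self._cols, (Ho, Wo) = _im2col(x, self.k, self.stride)
        y = np.matmul(self.params["W"], self._cols)
        y += self.params["b"][None, :, None]
        B = x.shape[0]
        return y.reshape(B, self.c_out, Ho, Wo)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        B, _, Ho, Wo = dy.shape
        dyf = dy.reshape(B, self.c_out, Ho * Wo)
        self.psg["W"] = np.einsum("bol,bcl->boc", dyf, self._cols, optimize=True)
        self.psg["b"] = dyf.sum(axis=2)
        dcols = np.matmul(self.params["W"].T, dyf)
        k, s = self.k, self.stride
        dcols = dcols.reshape(B, self.c_in, k, k, Ho, Wo)
        dxp = np.zeros(self._shape_padded, dtype=DTYPE)
        for ki in range(k):
            for kj in range(k):
                dxp[:, :, ki : ki + s * Ho : s, kj : kj + s * Wo : s] += dcols[
                    :, :, ki, kj, :, :
                ]
        if self.pad:
            p = self.pad
            dxp = dxp[:, :, p:-p, p:-p]
        return dxp


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.2):
        super().__init__()
        self.slope = slope

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._neg = x < 0
        return np.where(self._neg, self.slope * x, x)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._neg, self.slope * dy, dy)


class ReLU(LeakyReLU):
    def __init__(self):
        super().__init__(slope=0.0)


class Tanh(Layer):
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._y = np.tanh(x)
        return self._y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * (1 - self._y**2)


class Sigmoid(Layer):
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._y = 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))
        return self._y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._y * (1 - self._y)


class Upsample2x(Layer):
    """Nearest-neighbour 2x spatial upsampling."""

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        B, C, H, W = dy.shape
        return dy.reshape(B, C, H // 2, 2, W // 2, 2).sum(axis=(3, 5))


class MaxPool2x(Layer):
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        B, C, H, W = x.shape
        xr = x.reshape(B, C, H // 2, 2, W // 2, 2)
        y = xr.max(axis=(3, 5))
        # tie-splitting mask keeps the backward pass well defined
        m = xr == y[:, :, :, None, :, None]
        self._m = m / np.maximum(m.sum(axis=(3, 5), keepdims=True), 1)
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        g = self._m * dy[:, :, :, None, :, None]
        return self._expand(g)

    @staticmethod
    def _expand(g: np.ndarray) -> np.ndarray:
        B, C, Ho, _, Wo, _ = g.shape
        out = np.zeros((B, C, Ho * 2, Wo * 2), dtype=g.dtype)
        out[:, :, 0::2, 0::2] = g[:, :, :, 0, :, 0]
        out[:, :, 0::2, 1::2] = g[:, :, :, 0, :, 1]
        out[:, :, 1::2, 0::2] = g[:, :, :, 1, :, 0]
        out[:, :, 1::2, 1::2] = g[:, :, :, 1, :, 1]
        return out


class Dropout(Layer):
    def __init__(self, rate: float, rng: np.random.Generator):
        super().__init__()
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if not train or self.rate == 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1 - self.rate)
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy if self._mask is None else dy * self._mask


class Flatten(Layer):
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy.reshape(self._shape)


class Reshape(Layer):
    def __init__(self, shape: tuple[int, ...]):
        super().__init__()
        self.shape = shape

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._shape = x.shape
        return x.reshape((x.shape[0],) + self.shape)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy.reshape(self._shape)


class Sequential:
    def __init__(self, layers: Sequence[Layer]):
        self.layers = list(layers)

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        x = np.asarray(x, dtype=DTYPE)
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dy = np.asarray(dy, dtype=DTYPE)
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    __call__ = forward

    def named_params(self) -> list[tuple[Layer, str]]:
        return [(l, name) for l in self.layers for name in l.params]

    def n_params(self) -> int:
        return sum(l.params[n].size for l, n in self.named_params())

    def state(self) -> list[np.ndarray]:
        return [l.params[n].copy() for l, n in self.named_params()]

    def load_state(self, state: Iterable[np.ndarray]) -> None:
        for (l, n), arr in zip(self.named_params(), state):
            if l.params[n].shape != arr.shape:
                raise ValueError("state shape mismatch")
            l.params[n] = arr.copy()


def flatten_per_sample(net: Sequential, batch_size: int) -> np.ndarray:
    """Stack per-sample gradients of all parameters into a (B, D) matrix."""
    chunks = []
    for layer, name in net.named_params():
        g = layer.psg[name]
        chunks.append(g.reshape(batch_size, -1))
    return np.concatenate(chunks, axis=1)


def unflatten_gradient(net: Sequential, flat: np.ndarray) -> list[np.ndarray]:
    """Split a flat aggregate gradient back into per-parameter arrays."""
    out, i = [], 0
    for layer, name in net.named_params():
        size = layer.params[name].size
        out.append(flat[i : i + size].reshape(layer.params[name].shape))
        i += size
    if i != flat.size:
        raise ValueError("flat gradient size mismatch")
    return out


class RMSprop:
    def __init__(self, net: Sequential, lr: float, alpha: float = 0.99, eps: float = 1e-8):
        self.net, self.lr, self.alpha, self.eps = net, lr, alpha, eps
        self.sq = [np.zeros_like(l.params[n]) for l, n in net.named_params()]

    def step(self, grads: Sequence[np.ndarray]) -> None:
        for (layer, name), g, s in zip(self.net.named_params(), grads, self.sq):
            s *= self.alpha
            s += (1 - self.alpha) * g * g
            layer.params[name] -= self.lr * g / (np.sqrt(s) + self.eps)

    def step_from_layers(self) -> None:
        self.step([l.grad(n) for l, n in self.net.named_params()])


class Adam:
    def __init__(
        self,
        net: Sequential,
        lr: float,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ):
        self.net, self.lr, self.b1, self.b2, self.eps = net, lr, beta1, beta2, eps
        self.m = [np.zeros_like(l.params[n]) for l, n in net.named_params()]
        self.v = [np.zeros_like(l.params[n]) for l, n in net.named_params()]
        self.t = 0

    def step(self, grads: Sequence[np.ndarray]) -> None:
        self.t += 1
        for (layer, name), g, m, v in zip(self.net.named_params(), grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mh = m / (1 - self.b1**self.t)
            vh = v / (1 - self.b2**self.t)
            layer.params[name] -= self.lr * mh / (np.sqrt(vh) + self.eps)

    def step_from_layers(self) -> None:
        self.step([l.grad(n) for l, n in self.net.named_params()])
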