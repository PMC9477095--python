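"""Minimal CNN engine in numpy.

Layers carry their own forward caches and analytic backward passes; a
network is a composition of :class:`Module` objects whose gradients are
accumulated into per-parameter ``grad`` buffers and consumed by
:class:`Adam`.  Everything operates on float32 NCHW arrays and is fully
deterministic for a fixed seed (no threading, no atomics).

Convolutions use im2col/col2im so the inner loop is a single BLAS GEMM;
transposed convolution is implemented as the adjoint of convolution
(col2im of ``W^T x``), which makes its backward pass an ordinary
convolution.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Module",
    "Conv2d",
    "ConvTranspose2d",
    "BatchNorm2d",
    "ReLU",
    "LeakyReLU",
    "Tanh",
    "Sequential",
    "ResidualBlock",
    "Adam",
]


class Param:
    """A trainable array plus its gradient accumulator."""

    __slots__ = ("data", "grad", "name")

    def __init__(self, data: np.ndarray, name: str = ""):
        self.data = np.ascontiguousarray(data, dtype=np.float32)
        self.grad = np.zeros_like(self.data)
        self.name = name

    @property
    def size(self) -> int:
        return self.data.size


class Module:
    """Base class: forward caches whatever backward needs."""

    training: bool = True

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def train(self, mode: bool = True) -> "Module":
        self.training = mode
        for child in self.children():
            child.train(mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def use_instance_stats(self, flag: bool = True) -> "Module":
        """Normalize eval-time forwards by per-batch statistics."""
        if hasattr(self, "batch_stats_in_eval"):
            self.batch_stats_in_eval = flag
        for child in self.children():
            child.use_instance_stats(flag)
        return self

    def children(self) -> list["Module"]:
        return []

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad[...] = 0.0

    def n_params(self) -> int:
        return sum(p.size for p in self.params())

    def state_arrays(self) -> dict[str, np.ndarray]:
        """Flat name -> array mapping of parameters and buffers."""
        out = {}
        for i, p in enumerate(self.params()):
            out[f"p{i}"] = p.data
        for i, b in enumerate(self.buffers()):
            out[f"b{i}"] = b
        return out

    def buffers(self) -> list[np.ndarray]:
        buf: list[np.ndarray] = []
        for child in self.children():
            buf.extend(child.buffers())
        return buf

    def load_state_arrays(self, state: dict[str, np.ndarray]) -> None:
        for i, p in enumerate(self.params()):
            p.data[...] = state[f"p{i}"]
        for i, b in enumerate(self.buffers()):
            b[...] = state[f"b{i}"]


def _im2col(x: np.ndarray, k: int, stride: int, pad: int):
    """(N,C,H,W) -> columns (N, C*k*k, OH*OW) plus output spatial size."""
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    oh = (h + 2 * pad - k) // stride + 1
    ow = (w + 2 * pad - k) // stride + 1
    windows = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(2, 3))
    windows = windows[:, :, ::stride, ::stride, :, :]  # (N,C,OH,OW,k,k)
    cols = windows.transpose(0, 1, 4, 5, 2, 3).reshape(n, c * k * k, oh * ow)
    return np.ascontiguousarray(cols), oh, ow


def _col2im(cols: np.ndarray, x_shape, k: int, stride: int, pad: int) -> np.ndarray:
    """Adjoint of _im2col: scatter-add columns back to image layout."""
    n, c, h, w = x_shape
    hp, wp = h + 2 * pad, w + 2 * pad
    oh = (hp - k) // stride + 1
    ow = (wp - k) // stride + 1
    cols = cols.reshape(n, c, k, k, oh, ow)
    x_pad = np.zeros((n, c, hp, wp), dtype=cols.dtype)
    for i in range(k):
        for j in range(k):
            x_pad[:, :, i : i + stride * oh : stride, j : j + stride * ow : stride] += cols[
                :, :, i, j, :, :
            ]
    if pad:
        return x_pad[:, :, pad:-pad, pad:-pad]
    return x_pad


def _he_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)


class Conv2d(Module):
    def __init__(self, c_in: int, c_out: int, k: int, stride: int = 1, pad: int = 0,
                 rng: np.random.Generator | None = None, bias: bool = True):
        rng = rng or np.random.default_rng(0)
        self.c_in, self.c_out, self.k, self.stride, self.pad = c_in, c_out, k, stride, pad
        self.weight = Param(_he_init(rng, (c_out, c_in * k * k), c_in * k * k), "conv.w")
        self.bias = Param(np.zeros(c_out, dtype=np.float32), "conv.b") if bias else None
        self._cache = None

    def params(self):
        return [self.weight] + ([self.bias] if self.bias is not None else [])

    def forward(self, x):
        cols, oh, ow = _im2col(x, self.k, self.stride, self.pad)
        y = self.weight.data @ cols  # (N, c_out, OH*OW) via broadcasting over N
        y = y.reshape(x.shape[0], self.c_out, oh, ow)
        if self.bias is not None:
            y += self.bias.data[None, :, None, None]
        self._cache = (x.shape, cols)
        return y

    def backward(self, dy):
        x_shape, cols = self._cache
        n = x_shape[0]
        dy_flat = dy.reshape(n, self.c_out, -1)
        # dW: sum over batch of dy @ cols^T (batched GEMM)
        self.weight.grad += np.matmul(dy_flat, cols.transpose(0, 2, 1)).sum(axis=0)
        if self.bias is not None:
            self.bias.grad += dy_flat.sum(axis=(0, 2))
        dcols = self.weight.data.T @ dy_flat
        return _col2im(dcols, x_shape, self.k, self.stride, self.pad)


class ConvTranspose2d(Module):
    """Transposed convolution = adjoint of a stride-s convolution.

    Output size: (H-1)*stride - 2*pad + k + output_padding.
    """

    def __init__(self, c_in: int, c_out: int, k: int, stride: int = 2, pad: int = 1,
                 output_padding: int = 1, rng: np.random.Generator | None = None,
                 bias: bool = True):
        rng = rng or np.random.default_rng(0)
        self.c_in, self.c_out, self.k = c_in, c_out, k
        self.stride, self.pad, self.opad = stride, pad, output_padding
        # stored in conv orientation: (c_in, c_out*k*k) so forward is the conv adjoint
        self.weight = Param(_he_init(rng, (c_in, c_out * k * k), c_in), "convT.w")
        self.bias = Param(np.zeros(c_out, dtype=np.float32), "convT.b") if bias else None
        self._cache = None

    def params(self):
        return [self.weight] + ([self.bias] if self.bias is not None else [])

    def _out_hw(self, h, w):
        oh = (h - 1) * self.stride - 2 * self.pad + self.k + self.opad
        ow = (w - 1) * self.stride - 2 * self.pad + self.k + self.opad
        return oh, ow

    def forward(self, x):
        n, c, h, w = x.shape
        oh, ow = self._out_hw(h, w)
        x_flat = x.reshape(n, c, h * w)
        cols = self.weight.data.T @ x_flat  # (N, c_out*k*k, H*W)
        # cols correspond to an im2col of the *output* with an extra output_padding
        # absorbed into the virtual padded canvas
        y = _col2im_t(cols, (n, self.c_out, oh, ow), self.k, self.stride, self.pad, h, w)
        if self.bias is not None:
            y += self.bias.data[None, :, None, None]
        self._cache = (x_flat, (n, self.c_out, oh, ow), (h, w))
        return y

    def backward(self, dy):
        x_flat, y_shape, (h, w) = self._cache
        n = x_flat.shape[0]
        dcols = _im2col_t(dy, self.k, self.stride, self.pad, h, w)
        self.weight.grad += np.matmul(x_flat, dcols.transpose(0, 2, 1)).sum(axis=0)
        if self.bias is not None:
            self.bias.grad += dy.sum(axis=(0, 2, 3))
        dx_flat = self.weight.data @ dcols
        return dx_flat.reshape(n, self.c_in, h, w)


def _col2im_t(cols, y_shape, k, stride, pad, h_in, w_in):
    """col2im for transposed conv: scatter k*k taps of each input site into y."""
    n, c, oh, ow = y_shape
    hp, wp = oh + 2 * pad, ow + 2 * pad
    cols = cols.reshape(n, c, k, k, h_in, w_in)
    y_pad = np.zeros((n, c, hp, wp), dtype=cols.dtype)
    for i in range(k):
        for j in range(k):
            y_pad[:, :, i : i + stride * h_in : stride, j : j + stride * w_in : stride] += cols[
                :, :, i, j, :, :
            ]
    if pad:
        return y_pad[:, :, pad : pad + oh, pad : pad + ow]
    return y_pad[:, :, :oh, :ow]


def _im2col_t(y, k, stride, pad, h_in, w_in):
    """Adjoint of _col2im_t: gather k*k taps around each input site from y."""
    n, c, oh, ow = y.shape
    hp, wp = oh + 2 * pad, ow + 2 * pad
    y_pad = np.zeros((n, c, hp, wp), dtype=y.dtype)
    y_pad[:, :, pad : pad + oh, pad : pad + ow] = y
    cols = np.empty((n, c, k, k, h_in, w_in), dtype=y.dtype)
    for i in range(k):
        for j in range(k):
            cols[:, :, i, j, :, :] = y_pad[
                :, :, i : i + stride * h_in : stride, j : j + stride * w_in : stride
            ]
    return cols.reshape(n, c * k * k, h_in * w_in)


class BatchNorm2d(Module):
    """Batch normalization with an optional instance-statistics eval mode.

    ``batch_stats_in_eval`` makes eval-time forward passes normalize by
    the current batch's own statistics (without touching the running
    averages).  A generator conditioned on a mask label sees a different
    feature distribution per target domain, so blended running averages
    misnormalize every domain; per-sample statistics are exact for all
    of them.
    """

    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        self.c, self.momentum, self.eps = c, momentum, eps
        self.gamma = Param(np.ones(c, dtype=np.float32), "bn.gamma")
        self.beta = Param(np.zeros(c, dtype=np.float32), "bn.beta")
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self.batch_stats_in_eval = False
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def buffers(self):
        return [self.running_mean, self.running_var]

    def forward(self, x):
        if self.training or self.batch_stats_in_eval:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            if self.training:
                self.running_mean += self.momentum * (mean - self.running_mean)
                self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv_std[None, :, None, None]
        self._cache = (xhat, inv_std)
        return self.gamma.data[None, :, None, None] * xhat + self.beta.data[None, :, None, None]

    def backward(self, dy):
        xhat, inv_std = self._cache
        self.gamma.grad += (dy * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dy.sum(axis=(0, 2, 3))
        g = self.gamma.data[None, :, None, None]
        if not self.training:
            return dy * g * inv_std[None, :, None, None]
        m = dy.shape[0] * dy.shape[2] * dy.shape[3]
        dxhat = dy * g
        # standard batchnorm backward
        return (
            inv_std[None, :, None, None]
            / m
            * (
                m * dxhat
                - dxhat.sum(axis=(0, 2, 3), keepdims=True)
                - xhat * (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
            )
        )


class ReLU(Module):
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class LeakyReLU(Module):
    def __init__(self, slope: float = 0.2):
        self.slope = slope

    def forward(self, x):
        self._mask = x > 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, dy):
        return np.where(self._mask, dy, self.slope * dy)


class Tanh(Module):
    def forward(self, x):
        self._y = np.tanh(x)
        return self._y

    def backward(self, dy):
        return dy * (1.0 - self._y**2)


class Sequential(Module):
    def __init__(self, *layers: Module):
        self.layers = list(layers)

    def children(self):
        return self.layers

    def params(self):
        out = []
        for layer in self.layers:
            out.extend(layer.params())
        return out

    def forward(self, x):
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy


class ResidualBlock(Module):
    """x + BN(ReLU(BN(Conv3x3(x)))) — Conv-BN-ReLU-BN with identity skip."""

    def __init__(self, c: int, rng: np.random.Generator | None = None):
        self.body = Sequential(
            Conv2d(c, c, 3, 1, 1, rng=rng),
            BatchNorm2d(c),
            ReLU(),
            BatchNorm2d(c),
        )

    def children(self):
        return [self.body]

    def params(self):
        return self.body.params()

    def forward(self, x):
        return x + self.body.forward(x)

    def backward(self, dy):
        return dy + self.body.backward(dy)


class Adam:
    """Adam with the (0.5, 0.999) moments conventional for GAN training."""

    def __init__(self, params: list[Param], lr: float = 2e-4,
                 betas: tuple[float, float] = (0.5, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr, self.betas, self.eps = lr, betas, eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self):
        self.t += 1
        b1, b2 = self.betas
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m += (1.0 - b1) * (p.grad - m)
            v += (1.0 - b2) * (p.grad**2 - v)
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0
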