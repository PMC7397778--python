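"""A small reverse-mode autodiff engine for convolutional networks on numpy.

Implements exactly the primitives the translation and regression networks
need: 2-D convolution (im2col), zero/reflection padding, instance
normalization, ReLU/LeakyReLU/tanh, nearest-neighbor upsampling, channel
concatenation, L1/L2 losses, and an Adam optimizer. Tensors carry a tape of
parent closures; ``Tensor.backward()`` runs the tape in reverse topological
order. All arithmetic is float32; shapes are NCHW.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np
from numpy.lib.stride_tricks import as_strided

EPS = 1e-5


class Tensor:
    """An ndarray node in the computation graph."""

    __slots__ = ("data", "grad", "parents", "_backward", "is_param")

    def __init__(
        self,
        data: np.ndarray,
        parents: tuple["Tensor", ...] = (),
        backward: Callable[[np.ndarray], None] | None = None,
        is_param: bool = False,
    ) -> None:
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.parents = parents
        self._backward = backward
        self.is_param = is_param

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def item(self) -> float:
        return float(self.data)

    def backward(self) -> None:
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node.parents:
                stack.append((p, False))
        for t in topo:
            if not t.is_param:
                t.grad = None
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    def __add__(self, other: "Tensor") -> "Tensor":
        return add(self, other)

    def __mul__(self, k: float) -> "Tensor":
        return scale(self, k)

    __rmul__ = __mul__


def _accum(t: Tensor, g: np.ndarray) -> None:
    if t.grad is None:
        t.grad = g.copy()
    else:
        t.grad += g


def parameter(data: np.ndarray) -> Tensor:
    return Tensor(data, is_param=True)


# ---------------------------------------------------------------------------
# elementwise and structural ops
# ---------------------------------------------------------------------------


def add(a: Tensor, b: Tensor) -> Tensor:
    if a.data.shape != b.data.shape:
        raise ValueError("add requires identical shapes")
    out = Tensor(a.data + b.data, (a, b))

    def bw(g: np.ndarray) -> None:
        _accum(a, g)
        _accum(b, g)

    out._backward = bw
    return out


def scale(a: Tensor, k: float) -> Tensor:
    out = Tensor(a.data * np.float32(k), (a,))
    out._backward = lambda g: _accum(a, g * np.float32(k))
    return out


def relu(a: Tensor) -> Tensor:
    mask = a.data > 0
    out = Tensor(np.where(mask, a.data, 0.0), (a,))
    out._backward = lambda g: _accum(a, g * mask)
    return out


def leaky_relu(a: Tensor, slope: float = 0.2) -> Tensor:
    mask = a.data > 0
    out = Tensor(np.where(mask, a.data, slope * a.data), (a,))
    out._backward = lambda g: _accum(a, g * np.where(mask, 1.0, slope).astype(np.float32))
    return out


def softplus(a: Tensor) -> Tensor:
    """Smooth rectifier log(1+eˣ); strictly positive with nonvanishing gradient."""
    x = a.data
    y = np.maximum(x, 0.0) + np.log1p(np.exp(-np.abs(x)))
    out = Tensor(y, (a,))
    sig = 1.0 / (1.0 + np.exp(-x))
    out._backward = lambda g: _accum(a, g * sig)
    return out


def tanh(a: Tensor) -> Tensor:
    y = np.tanh(a.data)
    out = Tensor(y, (a,))
    out._backward = lambda g: _accum(a, g * (1.0 - y * y))
    return out


def concat(tensors: Sequence[Tensor], axis: int = 1) -> Tensor:
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bw(g: np.ndarray) -> None:
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            _accum(t, piece)

    out._backward = bw
    return out


def upsample_nearest(a: Tensor, factor: int = 2) -> Tensor:
    out_data = a.data.repeat(factor, axis=2).repeat(factor, axis=3)
    out = Tensor(out_data, (a,))
    n, c, h, w = a.data.shape

    def bw(g: np.ndarray) -> None:
        _accum(a, g.reshape(n, c, h, factor, w, factor).sum(axis=(3, 5)))

    out._backward = bw
    return out


def smooth3(a: Tensor) -> Tensor:
    """Fixed depthwise 3×3 binomial smoothing (zero-padded, self-adjoint)."""
    k = np.array([1.0, 2.0, 1.0], dtype=np.float32) / 4.0

    def filt(x: np.ndarray) -> np.ndarray:
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
        y = xp[:, :, :-2] * k[0] + xp[:, :, 1:-1] * k[1] + xp[:, :, 2:] * k[2]
        return y[:, :, :, :-2] * k[0] + y[:, :, :, 1:-1] * k[1] + y[:, :, :, 2:] * k[2]

    out = Tensor(filt(a.data), (a,))
    out._backward = lambda g: _accum(a, filt(g))
    return out


def crop2d(a: Tensor, height: int, width: int) -> Tensor:
    """Crop the top-left height×width window (undoes bottom/right padding)."""
    out = Tensor(a.data[:, :, :height, :width], (a,))

    def bw(g: np.ndarray) -> None:
        full = np.zeros_like(a.data)
        full[:, :, :height, :width] = g
        _accum(a, full)

    out._backward = bw
    return out


def _reflect_index(n: int, p: int) -> np.ndarray:
    return np.pad(np.arange(n), p, mode="reflect")


def pad2d(a: Tensor, p: int, mode: str = "zero") -> Tensor:
    if p == 0:
        return a
    n, c, h, w = a.data.shape
    if mode == "zero":
        out = Tensor(np.pad(a.data, ((0, 0), (0, 0), (p, p), (p, p))), (a,))
        out._backward = lambda g: _accum(a, g[:, :, p:-p, p:-p])
        return out
    if mode == "reflect":
        ri = _reflect_index(h, p)
        ci = _reflect_index(w, p)
        out = Tensor(a.data[:, :, ri][:, :, :, ci], (a,))

        def bw(g: np.ndarray) -> None:
            tmp = np.zeros((n, c, h, w + 2 * p), dtype=np.float32)
            np.add.at(tmp, (slice(None), slice(None), ri), g)
            dx = np.zeros((n, c, h, w), dtype=np.float32)
            np.add.at(dx, (slice(None), slice(None), slice(None), ci), tmp)
            _accum(a, dx)

        out._backward = bw
        return out
    raise ValueError(f"unknown pad mode {mode!r}")


# ---------------------------------------------------------------------------
# convolution
# ---------------------------------------------------------------------------


def _im2col(x: np.ndarray, k: int, stride: int) -> tuple[np.ndarray, int, int]:
    n, c, h, w = x.shape
    ho = (h - k) // stride + 1
    wo = (w - k) // stride + 1
    s0, s1, s2, s3 = x.strides
    view = as_strided(
        x, (n, c, k, k, ho, wo), (s0, s1, s2, s3, s2 * stride, s3 * stride)
    )
    cols = view.reshape(n, c * k * k, ho * wo)
    return np.ascontiguousarray(cols), ho, wo


def _col2im(dcols: np.ndarray, x_shape: tuple[int, ...], k: int, stride: int) -> np.ndarray:
    n, c, h, w = x_shape
    ho = (h - k) // stride + 1
    wo = (w - k) // stride + 1
    d = dcols.reshape(n, c, k, k, ho, wo)
    dx = np.zeros(x_shape, dtype=np.float32)
    for i in range(k):
        for j in range(k):
            dx[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride] += d[
                :, :, i, j
            ]
    return dx


def conv2d(x: Tensor, w: Tensor, b: Tensor | None, stride: int = 1) -> Tensor:
    """Valid (unpadded) convolution; pad beforehand with :func:`pad2d`."""
    f, cin, k, _ = w.data.shape
    if x.data.shape[2] < k or x.data.shape[3] < k:
        raise ValueError(
            f"input {x.data.shape[2]}×{x.data.shape[3]} smaller than kernel {k}; "
            "the network's receptive field exceeds the image"
        )
    wmat = w.data.reshape(f, cin * k * k)
    cols, ho, wo = _im2col(x.data, k, stride)
    out_data = np.matmul(wmat, cols)  # (N, F, L)
    if b is not None:
        out_data += b.data.reshape(1, f, 1)
    n = x.data.shape[0]
    out = Tensor(out_data.reshape(n, f, ho, wo), (x, w) if b is None else (x, w, b))

    def bw(g: np.ndarray) -> None:
        gmat = g.reshape(n, f, ho * wo)
        dw = np.einsum("nfl,nkl->fk", gmat, cols, optimize=True).reshape(w.data.shape)
        _accum(w, dw)
        if b is not None:
            _accum(b, gmat.sum(axis=(0, 2)))
        dcols = np.matmul(wmat.T, gmat)
        _accum(x, _col2im(dcols, x.data.shape, k, stride))

    out._backward = bw
    return out


def instance_norm(x: Tensor, gamma: Tensor, beta: Tensor) -> Tensor:
    """Per-sample, per-channel normalization with affine parameters."""
    mu = x.data.mean(axis=(2, 3), keepdims=True)
    xc = x.data - mu
    var = (xc * xc).mean(axis=(2, 3), keepdims=True)
    inv = 1.0 / np.sqrt(var + EPS)
    xhat = xc * inv
    gm = gamma.data.reshape(1, -1, 1, 1)
    out = Tensor(xhat * gm + beta.data.reshape(1, -1, 1, 1), (x, gamma, beta))

    def bw(g: np.ndarray) -> None:
        _accum(gamma, (g * xhat).sum(axis=(0, 2, 3)))
        _accum(beta, g.sum(axis=(0, 2, 3)))
        dxhat = g * gm
        m1 = dxhat.mean(axis=(2, 3), keepdims=True)
        m2 = (dxhat * xhat).mean(axis=(2, 3), keepdims=True)
        _accum(x, inv * (dxhat - m1 - xhat * m2))

    out._backward = bw
    return out


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------


def mse_loss(pred: Tensor, target: np.ndarray | float) -> Tensor:
    t = np.broadcast_to(np.asarray(target, dtype=np.float32), pred.data.shape)
    diff = pred.data - t
    out = Tensor(np.float32(np.mean(diff**2)), (pred,))
    out._backward = lambda g: _accum(pred, g * 2.0 * diff / diff.size)
    return out


def l1_loss(pred: Tensor, target: np.ndarray) -> Tensor:
    t = np.asarray(target, dtype=np.float32)
    diff = pred.data - t
    out = Tensor(np.float32(np.mean(np.abs(diff))), (pred,))
    out._backward = lambda g: _accum(pred, g * np.sign(diff) / diff.size)
    return out


# ---------------------------------------------------------------------------
# modules
# ---------------------------------------------------------------------------


class Module:
    """Base class; collects parameters from attributes recursively."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for value in self.__dict__.values():
            params.extend(_collect(value))
        return params

    def state_dict(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def load_state_dict(self, state: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(params) != len(state):
            raise ValueError("state does not match module parameters")
        for p, arr in zip(params, state):
            if p.data.shape != arr.shape:
                raise ValueError("parameter shape mismatch")
            p.data = arr.astype(np.float32).copy()

    def __call__(self, x: Tensor) -> Tensor:
        return self.forward(x)

    def forward(self, x: Tensor) -> Tensor:  # pragma: no cover - abstract
        raise NotImplementedError


def _collect(value: object) -> list[Tensor]:
    if isinstance(value, Tensor) and value.is_param:
        return [value]
    if isinstance(value, Module):
        return value.parameters()
    if isinstance(value, (list, tuple)):
        out: list[Tensor] = []
        for v in value:
            out.extend(_collect(v))
        return out
    return []


class Conv2d(Module):
    def __init__(
        self,
        cin: int,
        cout: int,
        k: int,
        rng: np.random.Generator,
        stride: int = 1,
        pad: int = 0,
        pad_mode: str = "zero",
        bias: bool = True,
        init: str = "gauss",
    ) -> None:
        if init == "gauss":  # DCGAN-family init
            w = rng.normal(0.0, 0.02, size=(cout, cin, k, k))
        else:  # He init for the ReLU regressor
            w = rng.normal(0.0, np.sqrt(2.0 / (cin * k * k)), size=(cout, cin, k, k))
        self.w = parameter(w)
        self.b = parameter(np.zeros(cout)) if bias else None
        self.stride, self.pad, self.pad_mode = stride, pad, pad_mode

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(pad2d(x, self.pad, self.pad_mode), self.w, self.b, self.stride)


class InstanceNorm2d(Module):
    def __init__(self, c: int) -> None:
        self.gamma = parameter(np.ones(c))
        self.beta = parameter(np.zeros(c))

    def forward(self, x: Tensor) -> Tensor:
        return instance_norm(x, self.gamma, self.beta)


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return relu(x)


class LeakyReLU(Module):
    def __init__(self, slope: float = 0.2) -> None:
        self.slope = slope

    def forward(self, x: Tensor) -> Tensor:
        return leaky_relu(x, self.slope)


class Tanh(Module):
    def forward(self, x: Tensor) -> Tensor:
        return tanh(x)


class Sequential(Module):
    def __init__(self, *mods: Module) -> None:
        self.mods = list(mods)

    def forward(self, x: Tensor) -> Tensor:
        for m in self.mods:
            x = m(x)
        return x


class Identity(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x


class ResBlock(Module):
    """Two 3×3 convolutions (optional instance norm) with an identity skip."""

    def __init__(self, ch: int, rng: np.random.Generator, pad_mode: str = "reflect",
                 init: str = "gauss", norm: bool = True) -> None:
        self.c1 = Conv2d(ch, ch, 3, rng, pad=1, pad_mode=pad_mode, init=init)
        self.n1 = InstanceNorm2d(ch) if norm else Identity()
        self.c2 = Conv2d(ch, ch, 3, rng, pad=1, pad_mode=pad_mode, init=init)
        self.n2 = InstanceNorm2d(ch) if norm else Identity()

    def forward(self, x: Tensor) -> Tensor:
        y = relu(self.n1(self.c1(x)))
        y = self.n2(self.c2(y))
        return add(x, y)


class Adam:
    """Adam with the GAN-family default β₁ = 0.5."""

    def __init__(self, params: Iterable[Tensor], lr: float = 2e-4,
                 betas: tuple[float, float] = (0.5, 0.999), eps: float = 1e-8,
                 clip_norm: float | None = None) -> None:
        self.params = list(params)
        self.lr, self.betas, self.eps = lr, betas, eps
        self.clip_norm = clip_norm
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        if self.clip_norm is not None:
            total = np.sqrt(
                sum(float((p.grad**2).sum()) for p in self.params if p.grad is not None)
            )
            if total > self.clip_norm:
                scale = self.clip_norm / (total + 1e-12)
                for p in self.params:
                    if p.grad is not None:
                        p.grad = p.grad * scale
        self.t += 1
        b1, b2 = self.betas
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            p.data -= self.lr * (self.m[i] / bc1) / (np.sqrt(self.v[i] / bc2) + self.eps)
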