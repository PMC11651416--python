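"""A small reverse-mode autodiff core for the detector.

Implements exactly the operations the two-stage network needs — im2col
convolution, linear layers, ReLU, nearest-neighbour upsampling, RoIAlign with
bilinear sampling, fused sigmoid-BCE / softmax-CE / smooth-L1 losses — on
float32 numpy arrays, with an SGD-with-momentum optimiser.  Graphs are built
dynamically per forward call and freed after ``backward``.

This is intentionally minimal: single-threaded CPU, NCHW layout, no broadcast
rules beyond what the network uses.  Gradient correctness is covered by
finite-difference tests.
"""

from __future__ import annotations

import math
from typing import Callable, Iterable, Optional

import numpy as np

__all__ = [
    "Tensor",
    "Parameter",
    "Module",
    "Conv2d",
    "Linear",
    "SGD",
    "relu",
    "add",
    "conv2d",
    "linear",
    "upsample2x",
    "permute",
    "concat",
    "roi_align",
    "gather_rows",
    "reshape",
    "sigmoid_bce_loss",
    "softmax_ce_loss",
    "smooth_l1_loss",
    "scalar_sum",
]

_F = np.float32


class Tensor:
    """Array node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=_F)
        self.grad: Optional[np.ndarray] = None
        self.requires_grad = requires_grad
        self._backward: Optional[Callable[[], None]] = None
        self._prev: tuple[Tensor, ...] = ()

    @property
    def shape(self):
        return self.data.shape

    def backward(self) -> None:
        """Reverse-accumulate gradients from this (scalar) tensor."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward()
        # free the graph
        for node in topo:
            node._backward = None
            node._prev = ()

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(_F, copy=True)
        else:
            self.grad += g


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def _node(data, parents: Iterable[Tensor], backward) -> Tensor:
    t = Tensor(data)
    parents = tuple(p for p in parents if isinstance(p, Tensor))
    if any(p.requires_grad or p._prev for p in parents):
        t.requires_grad = True
        t._prev = parents
        t._backward = backward(t)
    return t


# ---------------------------------------------------------------- basic ops


def add(a: Tensor, b: Tensor) -> Tensor:
    def bw(out):
        def run():
            a._accum(out.grad)
            b._accum(out.grad)
        return run

    return _node(a.data + b.data, (a, b), bw)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0

    def bw(out):
        def run():
            x._accum(out.grad * mask)
        return run

    return _node(x.data * mask, (x,), bw)


def reshape(x: Tensor, shape) -> Tensor:
    orig = x.data.shape

    def bw(out):
        def run():
            x._accum(out.grad.reshape(orig))
        return run

    return _node(x.data.reshape(shape), (x,), bw)


def permute(x: Tensor, axes: tuple[int, ...]) -> Tensor:
    inv = tuple(np.argsort(axes))

    def bw(out):
        def run():
            x._accum(out.grad.transpose(inv))
        return run

    return _node(x.data.transpose(axes), (x,), bw)


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    sizes = [t.data.shape[axis] for t in tensors]
    offs = np.cumsum([0] + sizes)

    def bw(out):
        def run():
            for t, a, b in zip(tensors, offs[:-1], offs[1:]):
                sl = [slice(None)] * out.grad.ndim
                sl[axis] = slice(a, b)
                t._accum(out.grad[tuple(sl)])
        return run

    return _node(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), bw)


def gather_rows(x: Tensor, idx: np.ndarray) -> Tensor:
    """Select rows of a 2-D (or leading-axis of N-D) tensor."""
    idx = np.asarray(idx, dtype=int)

    def bw(out):
        def run():
            g = np.zeros_like(x.data)
            np.add.at(g, idx, out.grad)
            x._accum(g)
        return run

    return _node(x.data[idx], (x,), bw)


def scalar_sum(tensors: list[Tensor]) -> Tensor:
    """Sum of scalar tensors (loss aggregation)."""
    total = sum(float(t.data) for t in tensors)

    def bw(out):
        def run():
            for t in tensors:
                t._accum(out.grad)
        return run

    return _node(np.asarray(total, dtype=_F), tuple(tensors), bw)


# ------------------------------------------------------------- convolution


def _im2col(x: np.ndarray, k: int, stride: int, pad: int):
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    ho = (h + 2 * pad - k) // stride + 1
    wo = (w + 2 * pad - k) // stride + 1
    cols = np.empty((n, c, k, k, ho, wo), dtype=_F)
    for i in range(k):
        for j in range(k):
            cols[:, :, i, j] = xp[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride]
    return cols.reshape(n, c * k * k, ho * wo), ho, wo


def _col2im(cols: np.ndarray, x_shape, k: int, stride: int, pad: int):
    n, c, h, w = x_shape
    ho = (h + 2 * pad - k) // stride + 1
    wo = (w + 2 * pad - k) // stride + 1
    cols = cols.reshape(n, c, k, k, ho, wo)
    xp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=_F)
    for i in range(k):
        for j in range(k):
            xp[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride] += cols[:, :, i, j]
    if pad == 0:
        return xp
    return xp[:, :, pad : pad + h, pad : pad + w]


def conv2d(x: Tensor, weight: Tensor, bias: Tensor, stride: int = 1, pad: int = 1) -> Tensor:
    """NCHW convolution; weight (O, C, k, k), bias (O,)."""
    n, c, h, w = x.data.shape
    o, ci, k, _ = weight.data.shape
    assert ci == c, f"channel mismatch: {ci} vs {c}"
    cols, ho, wo = _im2col(x.data, k, stride, pad)
    wm = weight.data.reshape(o, c * k * k)
    out = np.einsum("of,nfl->nol", wm, cols, optimize=True) + bias.data[None, :, None]
    out = out.reshape(n, o, ho, wo)

    def bw(node):
        def run():
            g = node.grad.reshape(n, o, ho * wo)
            weight._accum(
                np.einsum("nol,nfl->of", g, cols, optimize=True).reshape(weight.data.shape)
            )
            bias._accum(g.sum(axis=(0, 2)))
            if x.requires_grad or x._prev:
                dcols = np.einsum("of,nol->nfl", wm, g, optimize=True)
                x._accum(_col2im(dcols, x.data.shape, k, stride, pad))
        return run

    return _node(out, (x, weight, bias), bw)


def linear(x: Tensor, weight: Tensor, bias: Tensor) -> Tensor:
    """x (N, F) @ weight (F, O) + bias (O,)."""
    out = x.data @ weight.data + bias.data

    def bw(node):
        def run():
            weight._accum(x.data.T @ node.grad)
            bias._accum(node.grad.sum(axis=0))
            if x.requires_grad or x._prev:
                x._accum(node.grad @ weight.data.T)
        return run

    return _node(out, (x, weight, bias), bw)


def upsample2x(x: Tensor) -> Tensor:
    """Nearest-neighbour 2x spatial upsampling of an NCHW tensor."""
    out = x.data.repeat(2, axis=2).repeat(2, axis=3)

    def bw(node):
        def run():
            n, c, h2, w2 = node.grad.shape
            g = node.grad.reshape(n, c, h2 // 2, 2, w2 // 2, 2).sum(axis=(3, 5))
            x._accum(g)
        return run

    return _node(out, (x,), bw)


# ---------------------------------------------------------------- RoIAlign


def roi_align(features: Tensor, rois: np.ndarray, out_size: int, stride: float) -> Tensor:
    """Bilinear RoIAlign of image-coordinate boxes onto a feature map.

    ``features`` is (1, C, H, W); ``rois`` is (R, 4) as (x1, y1, x2, y2) in
    image pixels; ``stride`` is the feature map's pixel stride.  One bilinear
    sample is taken at the center of each of the ``out_size x out_size`` bins.
    Returns (R, C, out_size, out_size).
    """
    _, c, h, w = features.data.shape
    rois = np.asarray(rois, dtype=_F).reshape(-1, 4) / _F(stride)
    r = rois.shape[0]
    s = out_size
    if r == 0:
        return Tensor(np.zeros((0, c, s, s), dtype=_F))
    bw_ = np.maximum(rois[:, 2] - rois[:, 0], 1e-3)
    bh = np.maximum(rois[:, 3] - rois[:, 1], 1e-3)
    gx = rois[:, 0, None] + (np.arange(s, dtype=_F)[None, :] + 0.5) * (bw_[:, None] / s)
    gy = rois[:, 1, None] + (np.arange(s, dtype=_F)[None, :] + 0.5) * (bh[:, None] / s)
    # sample positions in array index space (pixel centers at integer indices)
    px = np.clip(gx - 0.5, 0.0, w - 1.0)
    py = np.clip(gy - 0.5, 0.0, h - 1.0)
    x0 = np.floor(px).astype(int)
    y0 = np.floor(py).astype(int)
    x1 = np.minimum(x0 + 1, w - 1)
    y1 = np.minimum(y0 + 1, h - 1)
    fx = (px - x0).astype(_F)
    fy = (py - y0).astype(_F)

    f = features.data[0]  # (C, H, W)
    # build (R, S, S) index grids from per-roi row/col vectors
    Y0 = y0[:, :, None].repeat(s, axis=2)
    Y1 = y1[:, :, None].repeat(s, axis=2)
    X0 = x0[:, None, :].repeat(s, axis=1)
    X1 = x1[:, None, :].repeat(s, axis=1)
    FY = fy[:, :, None]
    FX = fx[:, None, :]
    w00 = ((1 - FY) * (1 - FX)).astype(_F)
    w01 = ((1 - FY) * FX).astype(_F)
    w10 = (FY * (1 - FX)).astype(_F)
    w11 = (FY * FX).astype(_F)
    out = (
        f[:, Y0, X0] * w00[None]
        + f[:, Y0, X1] * w01[None]
        + f[:, Y1, X0] * w10[None]
        + f[:, Y1, X1] * w11[None]
    )  # (C, R, S, S)
    out = np.ascontiguousarray(np.moveaxis(out, 0, 1))

    def bw(node):
        def run():
            if not (features.requires_grad or features._prev):
                return
            g = np.moveaxis(node.grad, 1, 0)  # (C, R, S, S)
            df = np.zeros_like(features.data[0])
            for idx_y, idx_x, wgt in (
                (Y0, X0, w00),
                (Y0, X1, w01),
                (Y1, X0, w10),
                (Y1, X1, w11),
            ):
                np.add.at(df, (slice(None), idx_y, idx_x), g * wgt[None])
            features._accum(df[None])
        return run

    return _node(out, (features,), bw)


# -------------------------------------------------------------------- losses


def sigmoid_bce_loss(logits: Tensor, target: np.ndarray, weight: float = 1.0) -> Tensor:
    """Mean binary cross-entropy between sigmoid(logits) and target."""
    t = np.asarray(target, dtype=_F)
    if t.shape != logits.data.shape:
        raise ValueError(f"shape mismatch: {t.shape} vs {logits.data.shape}")
    z = logits.data
    # stable: max(z,0) - z*t + log(1+exp(-|z|))
    loss = np.maximum(z, 0) - z * t + np.log1p(np.exp(-np.abs(z)))
    n = max(z.size, 1)
    out_val = weight * loss.mean() if n else 0.0

    def bw(node):
        def run():
            p = 1.0 / (1.0 + np.exp(-z))
            logits._accum(node.grad * weight * (p - t) / n)
        return run

    return _node(np.asarray(out_val, dtype=_F), (logits,), bw)


def softmax_ce_loss(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean cross-entropy of row-wise softmax against integer labels."""
    labels = np.asarray(labels, dtype=int)
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    ez = np.exp(z)
    p = ez / ez.sum(axis=1, keepdims=True)
    n = max(labels.size, 1)
    loss = -np.log(np.maximum(p[np.arange(labels.size), labels], 1e-12)).mean()

    def bw(node):
        def run():
            g = p.copy()
            g[np.arange(labels.size), labels] -= 1.0
            logits._accum(node.grad * g / n)
        return run

    return _node(np.asarray(loss, dtype=_F), (logits,), bw)


def smooth_l1_loss(pred: Tensor, target: np.ndarray, beta: float = 1.0, norm: Optional[int] = None) -> Tensor:
    """Smooth-L1 (Huber) loss, summed then divided by ``norm`` (default: count)."""
    t = np.asarray(target, dtype=_F)
    d = pred.data - t
    ad = np.abs(d)
    loss = np.where(ad < beta, 0.5 * d * d / beta, ad - 0.5 * beta)
    n = norm if norm is not None else max(d.size, 1)
    n = max(n, 1)

    def bw(node):
        def run():
            g = np.where(ad < beta, d / beta, np.sign(d))
            pred._accum(node.grad * g / n)
        return run

    return _node(np.asarray(loss.sum() / n, dtype=_F), (pred,), bw)


# ------------------------------------------------------------------- modules


class Module:
    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        for v in self.__dict__.values():
            if isinstance(v, Parameter):
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
                    elif isinstance(item, Parameter):
                        params.append(item)
        return params

    def state_dict(self) -> dict[str, np.ndarray]:
        return {f"p{i}": p.data.copy() for i, p in enumerate(self.parameters())}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.parameters()
        if len(state) != len(params):
            raise ValueError("state dict size mismatch")
        for i, p in enumerate(params):
            arr = np.asarray(state[f"p{i}"], dtype=_F)
            if arr.shape != p.data.shape:
                raise ValueError(f"parameter {i} shape mismatch")
            p.data = arr.copy()


class Conv2d(Module):
    def __init__(self, cin: int, cout: int, k: int = 3, stride: int = 1,
                 pad: int = 1, rng: Optional[np.random.Generator] = None):
        rng = rng or np.random.default_rng(0)
        std = math.sqrt(2.0 / (cin * k * k))
        self.weight = Parameter(rng.normal(0.0, std, size=(cout, cin, k, k)))
        self.bias = Parameter(np.zeros(cout))
        self.stride, self.pad = stride, pad

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, self.stride, self.pad)


class Linear(Module):
    def __init__(self, fin: int, fout: int, rng: Optional[np.random.Generator] = None):
        rng = rng or np.random.default_rng(0)
        std = math.sqrt(2.0 / fin)
        self.weight = Parameter(rng.normal(0.0, std, size=(fin, fout)))
        self.bias = Parameter(np.zeros(fout))

    def __call__(self, x: Tensor) -> Tensor:
        return linear(x, self.weight, self.bias)


class SGD:
    """Stochastic gradient descent with momentum and decoupled weight decay."""

    def __init__(self, params: list[Parameter], lr: float, momentum: float = 0.9,
                 weight_decay: float = 0.0):
        self.params = params
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self._v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        for p, v in zip(self.params, self._v):
            if p.grad is None:
                continue
            g = p.grad + self.weight_decay * p.data
            v *= self.momentum
            v += g
            p.data -= (self.lr * v).astype(_F)
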