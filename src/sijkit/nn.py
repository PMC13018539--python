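"""Minimal vectorised reverse-mode automatic differentiation on numpy arrays.

This is the training substrate for every learnt component in the package:
the U-Net style contour delineator, the 21-heatmap landmark baseline, the
lesion-classification encoder/heads, and the rank-1 annotator matrices of
the multi-reader loss.  It deliberately implements only what those models
need: dense/conv layers at stride 1, 2x average pooling, nearest-neighbour
upsampling, the usual pointwise nonlinearities, reductions, slicing and
concatenation, plus an Adam optimiser.

All randomness is injected through ``numpy.random.Generator`` instances so
seeded runs are bit-reproducible at a fixed thread count.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Tensor",
    "concat",
    "relu",
    "sigmoid",
    "tanh",
    "softmax",
    "conv2d",
    "avg_pool2d",
    "upsample2x",
    "Module",
    "Parameter",
    "Conv2d",
    "Linear",
    "Sequential",
    "Adam",
]


def _as_array(x, dtype=None):
    a = np.asarray(x)
    if dtype is not None:
        a = a.astype(dtype, copy=False)
    elif not np.issubdtype(a.dtype, np.floating):
        a = a.astype(np.float64)
    return a


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    nd = grad.ndim - len(shape)
    if nd > 0:
        grad = grad.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array with a gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False, _prev=()):
        self.data = _as_array(data)
        self.grad = None
        self.requires_grad = bool(requires_grad) or any(
            p.requires_grad for p in _prev
        )
        self._backward = None
        self._prev = tuple(_prev)

    # -- introspection -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- autograd ------------------------------------------------------
    def _accumulate(self, g: np.ndarray):
        if self.grad is None:
            self.grad = g.astype(self.data.dtype, copy=True)
        else:
            self.grad += g

    def backward(self, free_graph: bool = True):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        # iterative topological sort (deep graphs exceed recursion limits)
        topo, seen, stack = [], set(), [(self, False)]
        while stack:
            t, done = stack.pop()
            if done:
                topo.append(t)
                continue
            if id(t) in seen:
                continue
            seen.add(id(t))
            stack.append((t, True))
            for p in t._prev:
                stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None and t.requires_grad:
                t._backward()
        if free_graph:
            # the _backward closures capture their output tensors, forming
            # reference cycles; break them so big graphs free immediately
            for t in topo:
                t._backward = None
                t._prev = ()

    # -- arithmetic ----------------------------------------------------
    @staticmethod
    def _lift(x):
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = Tensor._lift(other)
        out = Tensor(self.data + other.data, _prev=(self, other))

        def bw():
            if self.requires_grad:
                self._accumulate(_unbroadcast(out.grad, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(out.grad, other.data.shape))

        out._backward = bw
        return out

    __radd__ = __add__

    def __mul__(self, other):
        other = Tensor._lift(other)
        out = Tensor(self.data * other.data, _prev=(self, other))

        def bw():
            if self.requires_grad:
                self._accumulate(_unbroadcast(out.grad * other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(out.grad * self.data, other.data.shape))

        out._backward = bw
        return out

    __rmul__ = __mul__

    def __neg__(self):
        return self * -1.0

    def __sub__(self, other):
        return self + (-Tensor._lift(other))

    def __rsub__(self, other):
        return Tensor._lift(other) + (-self)

    def __truediv__(self, other):
        return self * Tensor._lift(other) ** -1.0

    def __rtruediv__(self, other):
        return Tensor._lift(other) * self**-1.0

    def __pow__(self, p: float):
        out = Tensor(self.data**p, _prev=(self,))

        def bw():
            if self.requires_grad:
                self._accumulate(out.grad * p * self.data ** (p - 1))

        out._backward = bw
        return out

    def __matmul__(self, other):
        other = Tensor._lift(other)
        out = Tensor(self.data @ other.data, _prev=(self, other))

        def bw():
            if self.requires_grad:
                self._accumulate(out.grad @ other.data.T)
            if other.requires_grad:
                other._accumulate(self.data.T @ out.grad)

        out._backward = bw
        return out

    # -- pointwise -----------------------------------------------------
    def exp(self):
        out = Tensor(np.exp(self.data), _prev=(self,))

        def bw():
            if self.requires_grad:
                self._accumulate(out.grad * out.data)

        out._backward = bw
        return out

    def log(self):
        out = Tensor(np.log(self.data), _prev=(self,))

        def bw():
            if self.requires_grad:
                self._accumulate(out.grad / self.data)

        out._backward = bw
        return out

    def clip_min(self, lo: float):
        mask = self.data >= lo
        out = Tensor(np.where(mask, self.data, lo), _prev=(self,))

        def bw():
            if self.requires_grad:
                self._accumulate(out.grad * mask)

        out._backward = bw
        return out

    # -- reductions / shape --------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _prev=(self,))

        def bw():
            if not self.requires_grad:
                return
            g = out.grad
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.data.shape).copy())

        out._backward = bw
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def max(self, axis: int):
        idx = np.argmax(self.data, axis=axis)
        out = Tensor(np.take_along_axis(self.data, np.expand_dims(idx, axis), axis).squeeze(axis), _prev=(self,))

        def bw():
            if self.requires_grad:
                g = np.zeros_like(self.data)
                np.put_along_axis(
                    g, np.expand_dims(idx, axis), np.expand_dims(out.grad, axis), axis
                )
                self._accumulate(g)

        out._backward = bw
        return out

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape), _prev=(self,))

        def bw():
            if self.requires_grad:
                self._accumulate(out.grad.reshape(self.data.shape))

        out._backward = bw
        return out

    def transpose(self, axes):
        out = Tensor(self.data.transpose(axes), _prev=(self,))
        inv = np.argsort(axes)

        def bw():
            if self.requires_grad:
                self._accumulate(out.grad.transpose(inv))

        out._backward = bw
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], _prev=(self,))

        def bw():
            if self.requires_grad:
                g = np.zeros_like(self.data)
                np.add.at(g, idx, out.grad)
                self._accumulate(g)

        out._backward = bw
        return out


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), _prev=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw():
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * out.data.ndim
                sl[axis] = slice(a, b)
                t._accumulate(out.grad[tuple(sl)])

    out._backward = bw
    return out


def relu(t: Tensor) -> Tensor:
    mask = t.data > 0
    out = Tensor(t.data * mask, _prev=(t,))

    def bw():
        if t.requires_grad:
            t._accumulate(out.grad * mask)

    out._backward = bw
    return out


def sigmoid(t: Tensor) -> Tensor:
    from scipy.special import expit

    s = expit(t.data)
    out = Tensor(s, _prev=(t,))

    def bw():
        if t.requires_grad:
            t._accumulate(out.grad * s * (1.0 - s))

    out._backward = bw
    return out


def tanh(t: Tensor) -> Tensor:
    s = np.tanh(t.data)
    out = Tensor(s, _prev=(t,))

    def bw():
        if t.requires_grad:
            t._accumulate(out.grad * (1.0 - s * s))

    out._backward = bw
    return out


def softmax(t: Tensor, axis: int = -1) -> Tensor:
    shifted = t + Tensor(-t.data.max(axis=axis, keepdims=True))
    e = shifted.exp()
    return e / e.sum(axis=axis, keepdims=True)


# -- convolution machinery ---------------------------------------------


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, padding: int = 0) -> Tensor:
    """Stride-1 2D cross-correlation; x (N,C,H,W), w (O,C,kh,kw), b (O,)."""
    xp = x.data
    if padding:
        xp = np.pad(
            x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding))
        )
    kh, kw = w.data.shape[2], w.data.shape[3]
    win = sliding_window_view(xp, (kh, kw), axis=(2, 3))  # N,C,Ho,Wo,kh,kw
    out_data = np.einsum("nchwij,ocij->nohw", win, w.data, optimize=True)
    if b is not None:
        out_data = out_data + b.data[None, :, None, None]
    prev = (x, w) if b is None else (x, w, b)
    out = Tensor(out_data, _prev=prev)

    def bw():
        g = out.grad
        if w.requires_grad:
            w._accumulate(np.einsum("nohw,nchwij->ocij", g, win, optimize=True))
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gcols = np.einsum("nohw,ocij->ncijhw", g, w.data, optimize=True)
            gxp = np.zeros_like(xp)
            Ho, Wo = g.shape[2], g.shape[3]
            for i in range(kh):
                for j in range(kw):
                    gxp[:, :, i : i + Ho, j : j + Wo] += gcols[:, :, i, j]
            if padding:
                gxp = gxp[:, :, padding:-padding, padding:-padding]
            x._accumulate(gxp)

    out._backward = bw
    return out


def avg_pool2d(x: Tensor, k: int = 2) -> Tensor:
    n, c, h, w = x.data.shape
    if h % k or w % k:
        raise ValueError(f"spatial dims {(h, w)} not divisible by pool {k}")
    r = x.data.reshape(n, c, h // k, k, w // k, k)
    out = Tensor(r.mean(axis=(3, 5)), _prev=(x,))

    def bw():
        if x.requires_grad:
            g = out.grad[:, :, :, None, :, None] / (k * k)
            x._accumulate(np.broadcast_to(g, r.shape).reshape(x.data.shape).copy())

    out._backward = bw
    return out


def upsample2x(x: Tensor) -> Tensor:
    out = Tensor(np.repeat(np.repeat(x.data, 2, axis=2), 2, axis=3), _prev=(x,))

    def bw():
        if x.requires_grad:
            n, c, h, w = x.data.shape
            g = out.grad.reshape(n, c, h, 2, w, 2).sum(axis=(3, 5))
            x._accumulate(g)

    out._backward = bw
    return out


# -- modules -----------------------------------------------------------


def Parameter(data) -> Tensor:
    return Tensor(np.asarray(data), requires_grad=True)


class Module:
    def parameters(self) -> list[Tensor]:
        params = []
        for v in vars(self).values():
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
                    elif isinstance(item, Tensor) and item.requires_grad:
                        params.append(item)
        return params

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def state_dict(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def load_state_dict(self, state) -> None:
        params = self.parameters()
        if len(state) != len(params):
            raise ValueError("state/parameter count mismatch")
        for p, s in zip(params, state):
            p.data = np.asarray(s, dtype=p.data.dtype).reshape(p.data.shape)


class Conv2d(Module):
    def __init__(self, cin, cout, k=3, padding=None, rng=None, dtype=np.float32):
        rng = rng or np.random.default_rng()
        self.padding = (k // 2) if padding is None else padding
        std = np.sqrt(2.0 / (cin * k * k))
        self.weight = Parameter(rng.normal(0.0, std, (cout, cin, k, k)).astype(dtype))
        self.bias = Parameter(np.zeros(cout, dtype=dtype))

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, padding=self.padding)


class Linear(Module):
    def __init__(self, fin, fout, rng=None, dtype=np.float32):
        rng = rng or np.random.default_rng()
        std = np.sqrt(2.0 / fin)
        self.weight = Parameter(rng.normal(0.0, std, (fin, fout)).astype(dtype))
        self.bias = Parameter(np.zeros(fout, dtype=dtype))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Sequential(Module):
    def __init__(self, *layers):
        self.layers = list(layers)

    def __call__(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x) if isinstance(layer, Module) else layer(x)
        return x


class Adam:
    """Adam optimiser (Kingma & Ba) over a flat parameter list."""

    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p.data -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(
                p.data.dtype
            )
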