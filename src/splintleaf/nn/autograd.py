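"""Minimal reverse-mode automatic differentiation on numpy arrays.

A deliberately small tape-based engine sized for CPU training of compact
encoder-decoder segmentation networks.  Every operation returns a
:class:`Tensor` holding a float32 array, the parent tensors, and a closure
that accumulates gradients into the parents.  ``Tensor.backward()`` runs the
tape in reverse topological order.

Gradient computation can be disabled globally (:func:`no_grad`) for
inference, which skips tape construction entirely.
"""

from __future__ import annotations

import contextlib
from typing import Callable, Iterable

import numpy as np

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Context manager that disables tape construction (inference mode)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def _as_f32(x) -> np.ndarray:
    a = np.asarray(x, dtype=np.float32)
    return a


class Tensor:
    """A float32 array plus the bookkeeping needed for backpropagation."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False,
                 parents: tuple = (), backward: Callable | None = None):
        self.data = _as_f32(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents = parents if _GRAD_ENABLED else ()
        self._backward = backward if _GRAD_ENABLED else None

    # -- graph ------------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    def backward(self) -> None:
        """Backpropagate from this (scalar) tensor through the tape."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS; recursion depth scales with net depth
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g

    def zero_grad(self) -> None:
        self.grad = None

    # -- arithmetic -------------------------------------------------------
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = self.data + other.data

        def bwd(g, a=self, b=other):
            a._accum(_unbroadcast(g, a.data.shape))
            b._accum(_unbroadcast(g, b.data.shape))

        return Tensor(out_data, parents=(self, other), backward=bwd)

    __radd__ = __add__

    def __neg__(self):
        def bwd(g, a=self):
            a._accum(-g)

        return Tensor(-self.data, parents=(self,), backward=bwd)

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    def __rsub__(self, other):
        return Tensor(other) + (-self)

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = self.data * other.data

        def bwd(g, a=self, b=other):
            a._accum(_unbroadcast(g * b.data, a.data.shape))
            b._accum(_unbroadcast(g * a.data, b.data.shape))

        return Tensor(out_data, parents=(self, other), backward=bwd)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = self.data / other.data

        def bwd(g, a=self, b=other):
            a._accum(_unbroadcast(g / b.data, a.data.shape))
            b._accum(_unbroadcast(-g * a.data / (b.data * b.data),
                                  b.data.shape))

        return Tensor(out_data, parents=(self, other), backward=bwd)

    def __rtruediv__(self, other):
        return Tensor(other) / self

    def sum(self):
        def bwd(g, a=self):
            a._accum(np.full_like(a.data, float(g)))

        return Tensor(self.data.sum(), parents=(self,), backward=bwd)

    def reshape(self, *shape):
        old = self.data.shape

        def bwd(g, a=self):
            a._accum(g.reshape(old))

        return Tensor(self.data.reshape(*shape), parents=(self,), backward=bwd)


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce a broadcast gradient back to ``shape``."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


# -- elementwise nonlinearities -------------------------------------------

def relu(x: Tensor) -> Tensor:
    mask = x.data > 0

    def bwd(g, a=x, m=mask):
        a._accum(g * m)

    return Tensor(x.data * mask, parents=(x,), backward=bwd)


def sigmoid(x: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-x.data))

    def bwd(g, a=x, s=s):
        a._accum(g * s * (1.0 - s))

    return Tensor(s, parents=(x,), backward=bwd)


# -- structural ops --------------------------------------------------------

def matmul(x: Tensor, w: Tensor) -> Tensor:
    """x @ w for 2-D operands."""
    out = x.data @ w.data

    def bwd(g, a=x, b=w):
        a._accum(g @ b.data.T)
        b._accum(a.data.T @ g)

    return Tensor(out, parents=(x, w), backward=bwd)


def concat_channels(a: Tensor, b: Tensor) -> Tensor:
    """Concatenate two NCHW tensors along the channel axis."""
    ca = a.data.shape[1]
    out = np.concatenate([a.data, b.data], axis=1)

    def bwd(g, a=a, b=b, ca=ca):
        a._accum(g[:, :ca])
        b._accum(g[:, ca:])

    return Tensor(out, parents=(a, b), backward=bwd)


def global_avg_pool(x: Tensor) -> Tensor:
    """NCHW -> NC mean over the spatial axes."""
    n, c, h, w = x.data.shape
    out = x.data.mean(axis=(2, 3))

    def bwd(g, a=x, h=h, w=w):
        a._accum(np.broadcast_to(g[:, :, None, None] / (h * w),
                                 a.data.shape).astype(np.float32))

    return Tensor(out, parents=(x,), backward=bwd)


def scale_channels(x: Tensor, gates: Tensor) -> Tensor:
    """Multiply NCHW features by per-(sample, channel) gates of shape NC."""
    g4 = gates.data[:, :, None, None]
    out = x.data * g4

    def bwd(g, a=x, b=gates, g4=g4):
        a._accum(g * g4)
        b._accum((g * a.data).sum(axis=(2, 3)))

    return Tensor(out, parents=(x, gates), backward=bwd)


def conv2d(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Same-padded 2-D convolution, NCHW input, OIHW kernel, stride 1.

    Implemented as im2col + one GEMM; the backward pass reuses the column
    matrix for the weight gradient and folds the input gradient back with
    k*k shifted slice-adds (no scatter loops over pixels).
    """
    n, c, h, wd = x.data.shape
    co, ci, kh, kw = w.data.shape
    if ci != c:
        raise ValueError(f"conv2d channel mismatch: input {c}, kernel {ci}")
    ph, pw = kh // 2, kw // 2
    if kh == 1 and kw == 1:
        # fast path: 1x1 convolution is a channel-mixing GEMM
        xm = x.data.transpose(0, 2, 3, 1).reshape(-1, c)
        wm = w.data.reshape(co, c)
        out = (xm @ wm.T + b.data).reshape(n, h, wd, co).transpose(0, 3, 1, 2)

        def bwd1(g, a=x, wt=w, bt=b, xm=xm, wm=wm):
            gm = g.transpose(0, 2, 3, 1).reshape(-1, co)
            bt._accum(gm.sum(axis=0))
            wt._accum((gm.T @ xm).reshape(wt.data.shape))
            dx = (gm @ wm).reshape(n, h, wd, c).transpose(0, 3, 1, 2)
            a._accum(np.ascontiguousarray(dx))

        return Tensor(out, parents=(x, w, b), backward=bwd1)

    xp = np.pad(x.data, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    cols = np.empty((n, h, wd, c, kh, kw), dtype=np.float32)
    for i in range(kh):
        for j in range(kw):
            cols[:, :, :, :, i, j] = xp[:, :, i:i + h, j:j + wd].transpose(0, 2, 3, 1)
    cols2 = cols.reshape(n * h * wd, c * kh * kw)
    wm = w.data.reshape(co, -1)
    out = (cols2 @ wm.T + b.data).reshape(n, h, wd, co).transpose(0, 3, 1, 2)

    def bwd(g, a=x, wt=w, bt=b, cols2=cols2, wm=wm):
        gm = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(-1, co)
        bt._accum(gm.sum(axis=0))
        wt._accum((gm.T @ cols2).reshape(wt.data.shape))
        dcols = (gm @ wm).reshape(n, h, wd, c, kh, kw)
        dxp = np.zeros((n, c, h + 2 * ph, wd + 2 * pw), dtype=np.float32)
        for i in range(kh):
            for j in range(kw):
                dxp[:, :, i:i + h, j:j + wd] += dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
        a._accum(dxp[:, :, ph:ph + h, pw:pw + wd])

    return Tensor(out, parents=(x, w, b), backward=bwd)


def maxpool2(x: Tensor) -> Tensor:
    """2x2 max pooling with stride 2; ties route the gradient to the first
    maximal element of each window."""
    n, c, h, w = x.data.shape
    if h % 2 or w % 2:
        raise ValueError(f"maxpool2 needs even spatial dims, got {h}x{w}")
    xr = x.data.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    xr = xr.reshape(n, c, h // 2, w // 2, 4)
    idx = xr.argmax(axis=-1)
    out = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]

    def bwd(g, a=x, idx=idx):
        dxr = np.zeros((n, c, h // 2, w // 2, 4), dtype=np.float32)
        np.put_along_axis(dxr, idx[..., None], g[..., None], axis=-1)
        dx = dxr.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        a._accum(np.ascontiguousarray(dx.reshape(n, c, h, w)))

    return Tensor(out, parents=(x,), backward=bwd)


_UPSAMPLE_CACHE: dict[int, np.ndarray] = {}


def _bilinear_matrix(n: int) -> np.ndarray:
    """(2n, n) matrix for exact 2x bilinear upsampling (half-pixel centers)."""
    m = _UPSAMPLE_CACHE.get(n)
    if m is None:
        m = np.zeros((2 * n, n), dtype=np.float32)
        for o in range(2 * n):
            src = (o + 0.5) / 2.0 - 0.5
            lo = int(np.floor(src))
            t = src - lo
            lo_c = min(max(lo, 0), n - 1)
            hi_c = min(max(lo + 1, 0), n - 1)
            m[o, lo_c] += 1.0 - t
            m[o, hi_c] += t
        _UPSAMPLE_CACHE[n] = m
    return m


def upsample2(x: Tensor) -> Tensor:
    """Bilinear 2x spatial upsampling of an NCHW tensor."""
    n, c, h, w = x.data.shape
    uh, uw = _bilinear_matrix(h), _bilinear_matrix(w)
    out = np.einsum("ph,nchw,qw->ncpq", uh, x.data, uw, optimize=True)

    def bwd(g, a=x, uh=uh, uw=uw):
        a._accum(np.einsum("ph,ncpq,qw->nchw", uh, g, uw,
                           optimize=True).astype(np.float32))

    return Tensor(out.astype(np.float32), parents=(x,), backward=bwd)


def softmax_channels(x: Tensor) -> Tensor:
    """Softmax over the channel axis of an NCHW tensor."""
    z = x.data - x.data.max(axis=1, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=1, keepdims=True)

    def bwd(g, a=x, p=p):
        dot = (g * p).sum(axis=1, keepdims=True)
        a._accum(p * (g - dot))

    return Tensor(p, parents=(x,), backward=bwd)


# -- parameters and modules ------------------------------------------------

class Parameter(Tensor):
    """A trainable tensor."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Base class with recursive parameter discovery."""

    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        seen: set[int] = set()

        def walk(obj):
            if isinstance(obj, Parameter):
                if id(obj) not in seen:
                    seen.add(id(obj))
                    params.append(obj)
            elif isinstance(obj, Module):
                for v in vars(obj).values():
                    walk(v)
            elif isinstance(obj, (list, tuple)):
                for v in obj:
                    walk(v)

        walk(self)
        return params

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()]

    def load_state_arrays(self, arrays: Iterable[np.ndarray]) -> None:
        params = self.parameters()
        arrays = list(arrays)
        if len(arrays) != len(params):
            raise ValueError(
                f"state mismatch: {len(arrays)} arrays for {len(params)} parameters")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError(f"shape mismatch {p.data.shape} vs {a.shape}")
            p.data = a.astype(np.float32)


class Adam:
    """Adam optimizer (Kingma & Ba) with bias correction."""

    def __init__(self, params: list[Parameter], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = float(lr)
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mh = self.m[i] / b1t
            vh = self.v[i] / b2t
            p.data -= (self.lr * mh / (np.sqrt(vh) + self.eps)).astype(np.float32)
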