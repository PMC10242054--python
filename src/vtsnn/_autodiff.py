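"""Minimal reverse-mode automatic differentiation on numpy arrays.

This is the compute core for training the spiking U-net. It implements
exactly the operations the network needs — zero-bias 2-D convolution,
nearest-neighbour upsampling, channel concatenation, elementwise
arithmetic, and the Heaviside spiking nonlinearity whose backward pass is
a surrogate derivative — as a tape of :class:`Tensor` nodes. Convolutions
run through an im2col / BLAS-matmul path; their input gradients are
accumulated with strided slice-adds per kernel offset, so no Python-level
per-element scatter occurs.

The surrogate used for the firing rule is

    d(spike)/d(u) ≈ 1 / (1 + (scale * (u - threshold))^2)

with ``scale`` defaulting to pi, which peaks (at 1) exactly at the firing
boundary u = threshold.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "add",
    "sub",
    "scale",
    "square",
    "tsum",
    "conv2d",
    "upsample_nearest",
    "concat",
    "spike",
    "detach",
]


class Tensor:
    """A node in the autodiff tape: an ndarray plus an optional gradient."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    @property
    def shape(self):
        return self.data.shape

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(g, dtype=np.float64)
        else:
            self.grad += g

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Reverse-accumulate gradients from this node to all leaves."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a seed gradient "
                                 "requires a scalar tensor")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS: graphs span T*layers nodes
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
        self._accumulate(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def __repr__(self) -> str:  # pragma: no cover
        return f"Tensor(shape={self.data.shape}, grad={'set' if self.grad is not None else 'None'})"


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _node(data, parents, backward) -> Tensor:
    out = Tensor(data)
    if any(p.requires_grad or p._parents for p in parents):
        out._parents = tuple(parents)
        out._backward = backward
        out.requires_grad = True
    return out


def add(a: Tensor, b: Tensor) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    if a.data.shape != b.data.shape:
        raise ValueError(f"shape mismatch in add: {a.data.shape} vs {b.data.shape}")

    def backward(g):
        a._accumulate(g)
        b._accumulate(g)

    return _node(a.data + b.data, (a, b), backward)


def sub(a: Tensor, b: Tensor) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    if a.data.shape != b.data.shape:
        raise ValueError(f"shape mismatch in sub: {a.data.shape} vs {b.data.shape}")

    def backward(g):
        a._accumulate(g)
        b._accumulate(-g)

    return _node(a.data - b.data, (a, b), backward)


def scale(a: Tensor, k: float) -> Tensor:
    a = _as_tensor(a)
    k = float(k)

    def backward(g):
        a._accumulate(k * g)

    return _node(k * a.data, (a,), backward)


def square(a: Tensor) -> Tensor:
    a = _as_tensor(a)

    def backward(g):
        a._accumulate(2.0 * a.data * g)

    return _node(a.data * a.data, (a,), backward)


def tsum(a: Tensor) -> Tensor:
    """Sum of all elements, as a scalar tensor."""
    a = _as_tensor(a)

    def backward(g):
        a._accumulate(np.broadcast_to(g, a.data.shape))

    return _node(a.data.sum(), (a,), backward)


def detach(a: Tensor) -> Tensor:
    """Same values, severed from the gradient graph."""
    return Tensor(np.array(a.data))


def spike(u: Tensor, threshold: float, surrogate_scale: float = np.pi) -> Tensor:
    """Heaviside firing rule with h(0) = 1 and a surrogate backward pass."""
    u = _as_tensor(u)
    th = float(threshold)
    sc = float(surrogate_scale)
    out_data = (u.data >= th).astype(np.float64)

    def backward(g):
        v = sc * (u.data - th)
        u._accumulate(g / (1.0 + v * v))

    return _node(out_data, (u,), backward)


def _pad_nhwc(x: np.ndarray, p: int) -> np.ndarray:
    if p == 0:
        return x
    return np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))


def _im2col(xp: np.ndarray, kh: int, kw: int, stride: int) -> np.ndarray:
    """(N, Hp, Wp, C) padded input -> (N*Ho*Wo, kh*kw*C) patch matrix.

    Built as kh*kw contiguous slice copies (channels-last keeps each copy
    a run of C elements), which is far cheaper than a transposed gather.
    """
    n, hp, wp, c = xp.shape
    ho = (hp - kh) // stride + 1
    wo = (wp - kw) // stride + 1
    cols = np.empty((n, ho, wo, kh, kw, c))
    for i in range(kh):
        for j in range(kw):
            cols[:, :, :, i, j, :] = xp[:, i:i + stride * ho:stride,
                                        j:j + stride * wo:stride, :]
    return cols.reshape(n * ho * wo, kh * kw * c)


def conv2d(x: Tensor, w: Tensor, stride: int = 1, padding: int = 0) -> Tensor:
    """Bias-free 2-D convolution (cross-correlation).

    Activations are channels-last (N, H, W, C); weights are stored
    (C_out, C_in, kh, kw). The im2col patch matrix is rebuilt in the
    backward pass rather than captured, keeping the retained graph
    proportional to the activations.
    """
    x, w = _as_tensor(x), _as_tensor(w)
    n, h, wd, c = x.data.shape
    co, ci, kh, kw = w.data.shape
    if ci != c:
        raise ValueError(f"conv2d channel mismatch: input has {c}, weight expects {ci}")
    xp = _pad_nhwc(x.data, padding)
    hp, wp = xp.shape[1], xp.shape[2]
    ho = (hp - kh) // stride + 1
    wo = (wp - kw) // stride + 1
    cols = _im2col(xp, kh, kw, stride)
    wmat = np.ascontiguousarray(w.data.transpose(2, 3, 1, 0)).reshape(kh * kw * c, co)
    out = (cols @ wmat).reshape(n, ho, wo, co)
    del cols, xp

    def backward(g):
        gmat = g.reshape(n * ho * wo, co)
        if w.requires_grad or w._parents:
            cols = _im2col(_pad_nhwc(x.data, padding), kh, kw, stride)
            gw = (cols.T @ gmat).reshape(kh, kw, c, co)
            w._accumulate(gw.transpose(3, 2, 0, 1))
        if x.requires_grad or x._parents:
            gcols = (gmat @ wmat.T).reshape(n, ho, wo, kh, kw, c)
            gxp = np.zeros((n, hp, wp, c))
            for i in range(kh):
                for j in range(kw):
                    gxp[:, i:i + stride * ho:stride,
                        j:j + stride * wo:stride, :] += gcols[:, :, :, i, j, :]
            if padding:
                gxp = gxp[:, padding:hp - padding, padding:wp - padding, :]
            x._accumulate(gxp)

    return _node(out, (x, w), backward)


def upsample_nearest(x: Tensor, factor: int = 2) -> Tensor:
    """Nearest-neighbour upsampling (N, H, W, C); preserves binarity."""
    x = _as_tensor(x)
    f = int(factor)
    out = x.data.repeat(f, axis=1).repeat(f, axis=2)

    def backward(g):
        n, h, w, c = x.data.shape
        x._accumulate(g.reshape(n, h, f, w, f, c).sum(axis=(2, 4)))

    return _node(out, (x,), backward)


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            idx = [slice(None)] * g.ndim
            idx[axis] = slice(lo, hi)
            t._accumulate(g[tuple(idx)])

    return _node(np.concatenate([t.data for t in tensors], axis=axis),
                 tuple(tensors), backward)
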