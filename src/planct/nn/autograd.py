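"""Tape-based reverse-mode automatic differentiation on numpy arrays.

Tensors form a DAG; ``Tensor.backward()`` topologically sorts it and calls
each node's backward closure, which returns gradients aligned with the
node's parents. Dtypes follow the inputs (float32 in training, float64 in
numerical gradient checks).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor", "constant", "add", "sub", "mul", "neg", "abs_", "mean", "log",
    "relu", "leaky_relu", "sigmoid", "concat", "crop", "conv3d", "avgpool2",
    "upsample2", "channel_norm", "grid_sample",
]


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    @property
    def shape(self):
        return self.data.shape

    def detach(self) -> "Tensor":
        return Tensor(self.data, requires_grad=False)

    def item(self) -> float:
        return float(self.data)

    def zero_grad(self):
        self.grad = None

    # -- operator sugar -----------------------------------------------------
    def __add__(self, other):
        return add(self, _coerce(other, self))

    def __radd__(self, other):
        return add(_coerce(other, self), self)

    def __sub__(self, other):
        return sub(self, _coerce(other, self))

    def __rsub__(self, other):
        return sub(_coerce(other, self), self)

    def __mul__(self, other):
        return mul(self, _coerce(other, self))

    def __rmul__(self, other):
        return mul(_coerce(other, self), self)

    def __neg__(self):
        return neg(self)

    # -- backpropagation ----------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._backward is None or node.grad is None:
                continue
            grads = node._backward(node.grad)
            for parent, g in zip(node._parents, grads):
                if g is None or not parent.requires_grad:
                    continue
                if parent.grad is None:
                    parent.grad = g
                else:
                    parent.grad = parent.grad + g


def constant(data) -> Tensor:
    return Tensor(data, requires_grad=False)


def _coerce(value, like: Tensor) -> Tensor:
    if isinstance(value, Tensor):
        return value
    return Tensor(np.asarray(value, dtype=like.data.dtype))


def _node(data, parents, backward_fn) -> Tensor:
    out = Tensor(data, requires_grad=any(p.requires_grad for p in parents))
    if out.requires_grad:
        out._parents = tuple(parents)
        out._backward = backward_fn
    return out


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum a broadcasted gradient back down to ``shape``."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


# ---------------------------------------------------------------------------
# arithmetic

def add(a: Tensor, b: Tensor) -> Tensor:
    def backward(g):
        return _unbroadcast(g, a.data.shape), _unbroadcast(g, b.data.shape)

    return _node(a.data + b.data, (a, b), backward)


def sub(a: Tensor, b: Tensor) -> Tensor:
    def backward(g):
        return _unbroadcast(g, a.data.shape), _unbroadcast(-g, b.data.shape)

    return _node(a.data - b.data, (a, b), backward)


def mul(a: Tensor, b: Tensor) -> Tensor:
    def backward(g):
        return (
            _unbroadcast(g * b.data, a.data.shape),
            _unbroadcast(g * a.data, b.data.shape),
        )

    return _node(a.data * b.data, (a, b), backward)


def neg(a: Tensor) -> Tensor:
    def backward(g):
        return (-g,)

    return _node(-a.data, (a,), backward)


def abs_(a: Tensor) -> Tensor:
    sign = np.sign(a.data)

    def backward(g):
        return (g * sign,)

    return _node(np.abs(a.data), (a,), backward)


def mean(a: Tensor) -> Tensor:
    n = a.data.size

    def backward(g):
        return (np.full_like(a.data, g / n),)

    return _node(np.asarray(a.data.mean(), dtype=a.data.dtype), (a,), backward)


_LOG_EPS = 1e-12


def log(a: Tensor) -> Tensor:
    clipped = np.maximum(a.data, _LOG_EPS)

    def backward(g):
        return (g / clipped,)

    return _node(np.log(clipped), (a,), backward)


# ---------------------------------------------------------------------------
# activations

def relu(a: Tensor) -> Tensor:
    mask = a.data > 0

    def backward(g):
        return (g * mask,)

    return _node(a.data * mask, (a,), backward)


def leaky_relu(a: Tensor, alpha: float = 0.2) -> Tensor:
    mask = a.data > 0
    out = np.where(mask, a.data, a.data * alpha)

    def backward(g):
        return (np.where(mask, g, g * alpha),)

    return _node(out, (a,), backward)


def sigmoid(a: Tensor) -> Tensor:
    with np.errstate(over="ignore"):
        out = 1.0 / (1.0 + np.exp(-a.data))
    out = out.astype(a.data.dtype)

    def backward(g):
        return (g * out * (1.0 - out),)

    return _node(out, (a,), backward)


# ---------------------------------------------------------------------------
# shape ops

def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=axis))

    return _node(np.concatenate([t.data for t in tensors], axis=axis),
                 tuple(tensors), backward)


def crop(a: Tensor, slices: tuple[slice, ...]) -> Tensor:
    def backward(g):
        full = np.zeros_like(a.data)
        full[slices] = g
        return (full,)

    return _node(a.data[slices], (a,), backward)


# ---------------------------------------------------------------------------
# convolution and resolution changes (channel-first layout: (C, X, Y, Z))

def conv3d(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Same-padding stride-1 3D convolution (cross-correlation).

    ``x``: (Cin, X, Y, Z); ``w``: (Cout, Cin, k, k, k), k odd; ``b``: (Cout,).
    """
    from . import _kernels

    k = w.data.shape[2]
    pad = k // 2
    cin, nx, ny, nz = x.data.shape
    cout = w.data.shape[0]
    dt = x.data.dtype
    xp = np.pad(x.data, ((0, 0),) + ((pad, pad),) * 3, mode="constant")
    wd = np.ascontiguousarray(w.data, dtype=dt)
    out = np.zeros((cout, nx, ny, nz), dtype=dt)
    _kernels.conv3d_fwd(xp, wd, out)
    out += b.data.astype(dt)[:, None, None, None]

    def backward(g):
        g = np.ascontiguousarray(g, dtype=dt)
        dw = np.zeros_like(wd)
        _kernels.conv3d_bwd_dw(g, xp, dw)
        dxp = np.zeros_like(xp)
        _kernels.conv3d_bwd_dx(g, wd, dxp)
        dx = dxp[:, pad:pad + nx, pad:pad + ny, pad:pad + nz]
        db = g.sum(axis=(1, 2, 3))
        return (dx, dw.astype(w.data.dtype), db.astype(b.data.dtype))

    return _node(out, (x, w, b), backward)


def avgpool2(x: Tensor) -> Tensor:
    c, nx, ny, nz = x.data.shape
    if nx % 2 or ny % 2 or nz % 2:
        raise ValueError(f"avgpool2 requires even spatial dims, got {x.shape}")
    r = x.data.reshape(c, nx // 2, 2, ny // 2, 2, nz // 2, 2)
    out = r.mean(axis=(2, 4, 6))

    def backward(g):
        gexp = np.repeat(np.repeat(np.repeat(g, 2, axis=1), 2, axis=2),
                         2, axis=3) / 8.0
        return (gexp.astype(x.data.dtype),)

    return _node(out.astype(x.data.dtype), (x,), backward)


def upsample2(x: Tensor) -> Tensor:
    out = np.repeat(np.repeat(np.repeat(x.data, 2, axis=1), 2, axis=2),
                    2, axis=3)

    def backward(g):
        c, nx, ny, nz = x.data.shape
        r = g.reshape(c, nx, 2, ny, 2, nz, 2)
        return (r.sum(axis=(2, 4, 6)).astype(x.data.dtype),)

    return _node(out, (x,), backward)


def channel_norm(x: Tensor, eps: float = 1e-5) -> Tensor:
    """Normalize each channel over its spatial extent to zero mean, unit var."""
    axes = (1, 2, 3)
    mu = x.data.mean(axis=axes, keepdims=True)
    var = x.data.var(axis=axes, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv
    n = x.data[0].size

    def backward(g):
        gm = g.mean(axis=axes, keepdims=True)
        gxm = (g * xhat).mean(axis=axes, keepdims=True)
        dx = inv * (g - gm - xhat * gxm)
        return (dx.astype(x.data.dtype),)

    return _node(xhat.astype(x.data.dtype), (x,), backward)


# ---------------------------------------------------------------------------
# trilinear grid sampling

def grid_sample(f: Tensor, disp: Tensor) -> Tensor:
    """Sample ``f`` (C, X, Y, Z) at ``index + disp`` with trilinear weights.

    ``disp`` is a (3, X, Y, Z) displacement in voxel units. Out-of-domain
    coordinates are clamped (replicate boundary); the coordinate gradient is
    zeroed where clamping is active.
    """
    from . import _kernels

    c, nx, ny, nz = f.data.shape
    if disp.data.shape != (3, nx, ny, nz):
        raise ValueError(
            f"disp shape {disp.data.shape} incompatible with field {f.data.shape}"
        )
    dt = f.data.dtype
    fd = np.ascontiguousarray(f.data, dtype=dt)
    dd_in = np.ascontiguousarray(disp.data, dtype=dt)
    out = np.empty_like(fd)
    i0 = np.empty((3, nx, ny, nz), dtype=np.int64)
    frac = np.empty((3, nx, ny, nz), dtype=dt)
    inrange = np.empty((3, nx, ny, nz), dtype=np.bool_)
    _kernels.grid_sample_fwd(fd, dd_in, out, i0, frac, inrange)

    def backward(g):
        g = np.ascontiguousarray(g, dtype=dt)
        df = np.zeros_like(fd)
        dd = np.zeros_like(dd_in)
        _kernels.grid_sample_bwd(g, fd, i0, frac, inrange,
                                 f.requires_grad, disp.requires_grad, df, dd)
        return (df if f.requires_grad else None,
                dd if disp.requires_grad else None)

    return _node(out, (f, disp), backward)
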