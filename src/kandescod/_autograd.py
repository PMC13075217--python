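"""Minimal reverse-mode automatic differentiation over NumPy arrays.

Only the primitives needed by the denoising network are implemented:
elementwise arithmetic, matmul, 1-D convolution, SiLU, abs/log, reductions,
shape ops, and an Adam optimizer.  Everything runs in float64 on CPU.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor", "add", "mul", "matmul", "conv1d", "silu", "abs_", "log",
    "sum_", "mean", "reshape", "transpose", "repeat", "concat", "getitem",
    "upsample_nearest", "Adam",
]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` after NumPy broadcasting."""
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, (g, s) in enumerate(zip(grad.shape, shape)) if s == 1 and g != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A NumPy array with a gradient and a backward closure."""

    # force NumPy to defer to our reflected operators instead of coercing
    __array_ufunc__ = None

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._parents: tuple = ()
        self._backward = None

    # ------------------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def T(self):
        return transpose(self)

    def item(self) -> float:
        return float(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self, grad=None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        self.grad = np.asarray(grad, dtype=np.float64)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen and p.requires_grad:
                    stack.append((p, False))
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    # operators ---------------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        return add(self, mul(_wrap(other), -1.0))

    def __rsub__(self, other):
        return add(_wrap(other), mul(self, -1.0))

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return div(self, other)

    def __rtruediv__(self, other):
        return div(_wrap(other), self)

    def __matmul__(self, other):
        return matmul(self, other)

    def __rmatmul__(self, other):
        return matmul(_wrap(other), self)

    def __getitem__(self, idx):
        return getitem(self, idx)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _acc(t: Tensor, g: np.ndarray) -> None:
    if t.requires_grad:
        t.grad = g if t.grad is None else t.grad + g


def _node(data, parents, backward) -> Tensor:
    out = Tensor(data)
    if any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._parents = parents
        out._backward = backward
    return out


# ----------------------------------------------------------------------
# primitives
# ----------------------------------------------------------------------

def add(a, b):
    a, b = _wrap(a), _wrap(b)
    out_data = a.data + b.data

    def backward(g):
        _acc(a, _unbroadcast(g, a.data.shape))
        _acc(b, _unbroadcast(g, b.data.shape))

    out = _node(out_data, (a, b), backward)
    return out


def mul(a, b):
    a, b = _wrap(a), _wrap(b)
    out_data = a.data * b.data

    def backward(g):
        _acc(a, _unbroadcast(g * b.data, a.data.shape))
        _acc(b, _unbroadcast(g * a.data, b.data.shape))

    out = _node(out_data, (a, b), backward)
    return out


def div(a, b):
    a, b = _wrap(a), _wrap(b)
    out_data = a.data / b.data

    def backward(g):
        _acc(a, _unbroadcast(g / b.data, a.data.shape))
        _acc(b, _unbroadcast(-g * a.data / (b.data ** 2), b.data.shape))

    out = _node(out_data, (a, b), backward)
    return out


def matmul(a, b):
    a, b = _wrap(a), _wrap(b)
    out_data = a.data @ b.data

    def backward(g):
        ga = g @ np.swapaxes(b.data, -1, -2)
        gb = np.swapaxes(a.data, -1, -2) @ g
        _acc(a, _unbroadcast(ga, a.data.shape))
        _acc(b, _unbroadcast(gb, b.data.shape))

    out = _node(out_data, (a, b), backward)
    return out


def transpose(a):
    a = _wrap(a)

    def backward(g):
        _acc(a, g.T)

    out = _node(a.data.T, (a,), backward)
    return out


def reshape(a, shape):
    a = _wrap(a)
    old = a.data.shape

    def backward(g):
        _acc(a, g.reshape(old))

    out = _node(a.data.reshape(shape), (a,), backward)
    return out


def getitem(a, idx):
    a = _wrap(a)

    def backward(g):
        full = np.zeros_like(a.data)
        full[idx] += g
        _acc(a, full)

    out = _node(a.data[idx], (a,), backward)
    return out


def concat(tensors, axis=0):
    tensors = [_wrap(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        parts = np.split(g, splits, axis=axis)
        for t, gp in zip(tensors, parts):
            _acc(t, gp)

    out = _node(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), backward)
    return out


def repeat(a, repeats, axis):
    """Repeat each element ``repeats`` times along ``axis`` (like np.repeat)."""
    a = _wrap(a)
    axis = axis % a.data.ndim
    n = a.data.shape[axis]

    def backward(g):
        shp = list(g.shape)
        shp[axis:axis + 1] = [n, repeats]
        _acc(a, g.reshape(shp).sum(axis=axis + 1))

    out = _node(np.repeat(a.data, repeats, axis=axis), (a,), backward)
    return out


def upsample_nearest(a, factor):
    """Nearest-neighbour upsampling along the last axis."""
    return repeat(a, factor, axis=-1)


def abs_(a):
    a = _wrap(a)

    def backward(g):
        _acc(a, g * np.sign(a.data))

    out = _node(np.abs(a.data), (a,), backward)
    return out


def log(a):
    a = _wrap(a)

    def backward(g):
        _acc(a, g / a.data)

    out = _node(np.log(a.data), (a,), backward)
    return out


def silu(a):
    a = _wrap(a)
    sig = 1.0 / (1.0 + np.exp(-a.data))
    out_data = a.data * sig

    def backward(g):
        _acc(a, g * (sig * (1.0 + a.data * (1.0 - sig))))

    out = _node(out_data, (a,), backward)
    return out


def sum_(a, axis=None, keepdims=False):
    a = _wrap(a)

    def backward(g):
        g = g
        if axis is not None and not keepdims:
            g = np.expand_dims(g, axis)
        _acc(a, np.broadcast_to(g, a.data.shape).copy())

    out = _node(a.data.sum(axis=axis, keepdims=keepdims), (a,), backward)
    return out


def mean(a, axis=None, keepdims=False):
    a = _wrap(a)
    if axis is None:
        n = a.data.size
    else:
        n = a.data.shape[axis]
    return mul(sum_(a, axis=axis, keepdims=keepdims), 1.0 / n)


def conv1d(x, w, b=None, stride=1, padding=0):
    """1-D convolution. x: (B, Cin, L), w: (Cout, Cin, K), b: (Cout,)."""
    x, w = _wrap(x), _wrap(w)
    if b is not None:
        b = _wrap(b)
    xd, wd = x.data, w.data
    B, Ci, L = xd.shape
    Co, _, K = wd.shape
    xp = np.pad(xd, ((0, 0), (0, 0), (padding, padding))) if padding else xd
    Lp = xp.shape[2]
    Lo = (Lp - K) // stride + 1
    # (B, Ci, Lo, K) windows -> (B, Ci*K, Lo) im2col matrix
    win = np.lib.stride_tricks.sliding_window_view(xp, K, axis=2)[:, :, ::stride]
    cols = np.ascontiguousarray(win.transpose(0, 1, 3, 2)).reshape(B, Ci * K, Lo)
    w2 = wd.reshape(Co, Ci * K)
    out_data = np.matmul(w2, cols)  # (B, Co, Lo)
    if b is not None:
        out_data += b.data[:, None]

    def backward(g):  # g: (B, Co, Lo)
        _acc(w, np.matmul(g, cols.transpose(0, 2, 1)).sum(axis=0).reshape(Co, Ci, K))
        if b is not None:
            _acc(b, g.sum(axis=(0, 2)))
        if x.requires_grad:
            gcols = np.matmul(w2.T, g).reshape(B, Ci, K, Lo)
            gxp = np.zeros_like(xp)
            for k in range(K):
                gxp[:, :, k:k + stride * Lo:stride] += gcols[:, :, k]
            _acc(x, gxp[:, :, padding:Lp - padding] if padding else gxp)

    parents = (x, w, b) if b is not None else (x, w)
    out = _node(out_data, parents, backward)
    return out


# ----------------------------------------------------------------------
class Adam:
    """Adam optimizer over a list of Tensors (PyTorch defaults)."""

    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8):
        self.params = list(params)
        self.lr = float(lr)
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def state_dict(self):
        return {"t": self.t, "m": [m.copy() for m in self.m], "v": [v.copy() for v in self.v]}

    def load_state_dict(self, state):
        self.t = state["t"]
        self.m = [m.copy() for m in state["m"]]
        self.v = [v.copy() for v in state["v"]]
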