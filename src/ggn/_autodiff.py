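"""Reverse-mode automatic differentiation on numpy arrays.

A small tape-based engine: each :class:`Tensor` wraps a float64 ndarray and
remembers the operation that produced it. Calling :meth:`Tensor.backward`
walks the tape in reverse topological order and accumulates gradients into
every tensor created with ``requires_grad=True``. The op set is exactly what
the graph-generative network needs (broadcasted arithmetic, batched matmul,
pointwise nonlinearities, reductions, slicing, concatenation and a 2-D
convolution); everything is double precision.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor", "as_tensor", "parameter", "glorot",
    "concat", "stack", "conv2d", "softmax", "log_softmax", "logsumexp",
    "Adam",
]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing numpy broadcasting."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for i, s in enumerate(shape):
        if s == 1 and grad.shape[i] != 1:
            grad = grad.sum(axis=i, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False,
                 _parents: tuple = (), _backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents = _parents
        self._backward = _backward

    # -- introspection -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def numpy(self) -> np.ndarray:
        return self.data

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # -- autodiff ------------------------------------------------------
    def backward(self, grad=None):
        topo, seen = [], set()

        def build(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                build(p)
            topo.append(t)

        build(self)
        self.grad = np.ones_like(self.data) if grad is None else np.asarray(grad, float)
        for t in reversed(topo):
            if t._backward is None or t.grad is None:
                continue
            for p, g in zip(t._parents, t._backward(t.grad)):
                if p.requires_grad or p._parents:
                    if g is None:
                        continue
                    p.grad = g if p.grad is None else p.grad + g

    # -- arithmetic ----------------------------------------------------
    def __add__(self, other):
        a, b = self, as_tensor(other)

        def bwd(g):
            return _unbroadcast(g, a.shape), _unbroadcast(g, b.shape)

        return _node(a.data + b.data, (a, b), bwd)

    __radd__ = __add__

    def __mul__(self, other):
        a, b = self, as_tensor(other)

        def bwd(g):
            return _unbroadcast(g * b.data, a.shape), _unbroadcast(g * a.data, b.shape)

        return _node(a.data * b.data, (a, b), bwd)

    __rmul__ = __mul__

    def __neg__(self):
        a = self
        return _node(-a.data, (a,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __truediv__(self, other):
        a, b = self, as_tensor(other)

        def bwd(g):
            return (_unbroadcast(g / b.data, a.shape),
                    _unbroadcast(-g * a.data / (b.data ** 2), b.shape))

        return _node(a.data / b.data, (a, b), bwd)

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, n):
        a = self
        n = float(n)

        def bwd(g):
            return (g * n * a.data ** (n - 1),)

        return _node(a.data ** n, (a,), bwd)

    def __matmul__(self, other):
        a, b = self, as_tensor(other)
        if a.ndim < 2 or b.ndim < 2:
            raise ValueError("matmul requires tensors with ndim >= 2")

        def bwd(g):
            ga = g @ np.swapaxes(b.data, -1, -2)
            gb = np.swapaxes(a.data, -1, -2) @ g
            return _unbroadcast(ga, a.shape), _unbroadcast(gb, b.shape)

        return _node(a.data @ b.data, (a, b), bwd)

    # -- pointwise -----------------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)
        return _node(out_data, (self,), lambda g: (g * out_data,))

    def log(self):
        a = self
        return _node(np.log(a.data), (a,), lambda g: (g / a.data,))

    def sqrt(self):
        out_data = np.sqrt(self.data)
        return _node(out_data, (self,), lambda g: (g * 0.5 / out_data,))

    def tanh(self):
        out_data = np.tanh(self.data)
        return _node(out_data, (self,), lambda g: (g * (1.0 - out_data ** 2),))

    def sigmoid(self):
        from scipy.special import expit
        out_data = expit(self.data)
        return _node(out_data, (self,), lambda g: (g * out_data * (1.0 - out_data),))

    def relu(self):
        mask = self.data > 0

        def bwd(g):
            return (g * mask,)

        return _node(self.data * mask, (self,), bwd)

    def clip(self, lo, hi):
        """Clamp values; gradient passes only where unclamped."""
        mask = (self.data >= lo) & (self.data <= hi)
        return _node(np.clip(self.data, lo, hi), (self,), lambda g: (g * mask,))

    # -- reductions / shape --------------------------------------------
    def sum(self, axis=None, keepdims=False):
        a = self

        def bwd(g):
            if axis is None:
                return (np.broadcast_to(g, a.shape).copy(),)
            gg = g
            if not keepdims:
                gg = np.expand_dims(gg, axis)
            return (np.broadcast_to(gg, a.shape).copy(),)

        return _node(a.data.sum(axis=axis, keepdims=keepdims), (a,), bwd)

    def mean(self, axis=None, keepdims=False):
        if axis is None:
            n = self.size
        else:
            n = self.shape[axis] if isinstance(axis, int) else int(
                np.prod([self.shape[i] for i in axis]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        a = self
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return _node(a.data.reshape(shape), (a,),
                     lambda g: (g.reshape(a.shape),))

    def transpose(self, *axes):
        a = self
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        return _node(a.data.transpose(axes), (a,),
                     lambda g: (g.transpose(inv),))

    def swapaxes(self, i, j):
        a = self
        return _node(np.swapaxes(a.data, i, j), (a,),
                     lambda g: (np.swapaxes(g, i, j),))

    def __getitem__(self, idx):
        a = self

        def bwd(g):
            z = np.zeros_like(a.data)
            np.add.at(z, idx, g)
            return (z,)

        return _node(a.data[idx], (a,), bwd)


def _node(data, parents, backward):
    track = any(p.requires_grad or p._parents for p in parents)
    if not track:
        return Tensor(data)
    return Tensor(data, requires_grad=False, _parents=parents, _backward=backward)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def parameter(data) -> Tensor:
    return Tensor(np.array(data, dtype=np.float64), requires_grad=True)


def glorot(rng: np.random.Generator, fan_in: int, fan_out: int, *shape) -> Tensor:
    """Glorot-uniform initialized learnable tensor of shape (fan_in, fan_out) or custom."""
    lim = np.sqrt(6.0 / (fan_in + fan_out))
    full = shape if shape else (fan_in, fan_out)
    return parameter(rng.uniform(-lim, lim, size=full))


# -- multi-tensor ops --------------------------------------------------

def concat(tensors, axis=0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bwd(g):
        return tuple(np.split(g, splits, axis=axis))

    return _node(np.concatenate([t.data for t in tensors], axis=axis),
                 tuple(tensors), bwd)


def stack(tensors, axis=0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]

    def bwd(g):
        return tuple(np.take(g, i, axis=axis) for i in range(len(tensors)))

    return _node(np.stack([t.data for t in tensors], axis=axis),
                 tuple(tensors), bwd)


def logsumexp(t: Tensor, axis=-1, keepdims=False) -> Tensor:
    shift = Tensor(np.max(t.data, axis=axis, keepdims=True))
    s = (t - shift).exp().sum(axis=axis, keepdims=True).log() + shift
    if not keepdims:
        s = s.reshape(tuple(np.delete(s.shape, axis)))
    return s


def softmax(t: Tensor, axis=-1) -> Tensor:
    shift = Tensor(np.max(t.data, axis=axis, keepdims=True))
    e = (t - shift).exp()
    return e / e.sum(axis=axis, keepdims=True)


def log_softmax(t: Tensor, axis=-1) -> Tensor:
    return t - logsumexp(t, axis=axis, keepdims=True)


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None,
           padding: tuple[int, int] = (0, 0)) -> Tensor:
    """2-D convolution (cross-correlation), stride 1.

    x: [B, C_in, H, W]; w: [C_out, C_in, kh, kw]; b: [C_out] or None.
    """
    x, w = as_tensor(x), as_tensor(w)
    B, Cin, H, W = x.shape
    Cout, Cin2, kh, kw = w.shape
    if Cin != Cin2:
        raise ValueError("channel mismatch between input and kernels")
    ph, pw = padding
    xp = np.pad(x.data, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    Ho, Wo = H + 2 * ph - kh + 1, W + 2 * pw - kw + 1
    win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    # win: [B, Cin, Ho, Wo, kh, kw] -> cols [B, Ho*Wo, Cin*kh*kw]
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(B, Ho * Wo, Cin * kh * kw)
    wmat = w.data.reshape(Cout, Cin * kh * kw)
    out = (cols @ wmat.T).transpose(0, 2, 1).reshape(B, Cout, Ho, Wo)
    if b is not None:
        out = out + as_tensor(b).data.reshape(1, Cout, 1, 1)

    parents = (x, w) if b is None else (x, w, as_tensor(b))

    def bwd(g):
        gmat = g.reshape(B, Cout, Ho * Wo).transpose(0, 2, 1)  # [B, HoWo, Cout]
        gw = np.einsum("bpc,bpk->ck", gmat, cols).reshape(w.shape)
        gcols = gmat @ wmat  # [B, HoWo, Cin*kh*kw]
        gcols = gcols.reshape(B, Ho, Wo, Cin, kh, kw).transpose(0, 3, 1, 2, 4, 5)
        gxp = np.zeros_like(xp)
        for u in range(kh):
            for v in range(kw):
                gxp[:, :, u:u + Ho, v:v + Wo] += gcols[:, :, :, :, u, v]
        gx = gxp[:, :, ph:ph + H, pw:pw + W]
        if b is None:
            return gx, gw
        return gx, gw, g.sum(axis=(0, 2, 3))

    return _node(out, parents, bwd)


class Adam:
    """Adaptive-moment first-order optimizer over a list of parameter tensors."""

    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8):
        self.params = list(params)
        self.lr = lr
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
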