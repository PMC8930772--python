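"""Minimal reverse-mode automatic differentiation on numpy arrays.

Implements exactly the operations needed by the embedding-segmentation
network and its loss: broadcasting arithmetic, reductions, 3x3/1x1
convolutions (im2col), 2x2 average pooling, nearest-neighbour
upsampling, and the pointwise nonlinearities (relu, sigmoid, softplus,
exp).  Everything runs in float32 on the CPU and is deterministic.

Gradients are accumulated into ``Tensor.grad`` by ``backward()`` via a
topological sort of the recorded graph.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "relu",
    "sigmoid",
    "softplus",
    "exp",
    "conv2d",
    "avgpool2",
    "upsample2",
    "Adam",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, _parents=(), _backward=None):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents = _parents
        self._backward = _backward

    # -- basic introspection -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # -- graph plumbing ------------------------------------------------------
    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            if grad.dtype != np.float32:
                grad = grad.astype(np.float32)
            self.grad = grad
        else:
            self.grad = self.grad + grad

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
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
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic ----------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        out = Tensor(
            self.data + other.data,
            self.requires_grad or other.requires_grad,
            (self, other),
        )

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.shape))

        out._backward = bw
        return out

    __radd__ = __add__

    def __mul__(self, other):
        other = as_tensor(other)
        out = Tensor(
            self.data * other.data,
            self.requires_grad or other.requires_grad,
            (self, other),
        )

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.shape))

        out._backward = bw
        return out

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __truediv__(self, other):
        return self * as_tensor(other) ** -1.0

    def __rtruediv__(self, other):
        return as_tensor(other) * self**-1.0

    def __pow__(self, p: float):
        p = float(p)
        out = Tensor(self.data**p, self.requires_grad, (self,))

        def bw(g):
            if self.requires_grad:
                self._accumulate(g * p * self.data ** (p - 1.0))

        out._backward = bw
        return out

    # -- reductions / shaping ------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), self.requires_grad, (self,))

        def bw(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.shape).astype(np.float32))
            else:
                if not keepdims:
                    g = np.expand_dims(g, axis)
                self._accumulate(np.broadcast_to(g, self.shape).astype(np.float32))

        out._backward = bw
        return out

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.shape
        out = Tensor(self.data.reshape(shape), self.requires_grad, (self,))

        def bw(g):
            if self.requires_grad:
                self._accumulate(g.reshape(old))

        out._backward = bw
        return out

    def transpose(self, axes):
        inv = np.argsort(axes)
        out = Tensor(self.data.transpose(axes), self.requires_grad, (self,))

        def bw(g):
            if self.requires_grad:
                self._accumulate(g.transpose(inv))

        out._backward = bw
        return out

    def matmul(self, other: "Tensor"):
        other = as_tensor(other)
        out = Tensor(
            self.data @ other.data,
            self.requires_grad or other.requires_grad,
            (self, other),
        )

        def bw(g):
            if self.requires_grad:
                self._accumulate(g @ other.data.T)
            if other.requires_grad:
                other._accumulate(self.data.T @ g)

        out._backward = bw
        return out


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# -- pointwise nonlinearities ------------------------------------------------

def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    out = Tensor(np.maximum(x.data, 0.0), x.requires_grad, (x,))

    def bw(g):
        if x.requires_grad:
            x._accumulate(g * mask)

    out._backward = bw
    return out


def sigmoid(x: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-x.data))
    out = Tensor(s, x.requires_grad, (x,))

    def bw(g):
        if x.requires_grad:
            x._accumulate(g * s * (1.0 - s))

    out._backward = bw
    return out


def softplus(x: Tensor) -> Tensor:
    # log(1 + e^x), numerically stable
    s = np.logaddexp(0.0, x.data)
    sig = 1.0 / (1.0 + np.exp(-x.data))
    out = Tensor(s, x.requires_grad, (x,))

    def bw(g):
        if x.requires_grad:
            x._accumulate(g * sig)

    out._backward = bw
    return out


def exp(x: Tensor) -> Tensor:
    e = np.exp(x.data)
    out = Tensor(e, x.requires_grad, (x,))

    def bw(g):
        if x.requires_grad:
            x._accumulate(g * e)

    out._backward = bw
    return out


# -- spatial operations ------------------------------------------------------

def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """Same-padding stride-1 2D convolution.

    ``x``: (N, C, H, W); ``w``: (O, C, kh, kw) with odd kh, kw;
    ``b``: (O,) or None.
    """
    N, C, H, W = x.shape
    O, C2, kh, kw = w.shape
    if C != C2:
        raise ValueError(f"channel mismatch: input {C}, weight {C2}")
    ph, pw = kh // 2, kw // 2
    if kh == 1 and kw == 1:
        # 1x1 convolution: a plain channel matmul, no patch extraction
        xmat = x.data.transpose(1, 0, 2, 3).reshape(C, N * H * W)
        wmat = w.data.reshape(O, C)
        ymat = wmat @ xmat
        if b is not None:
            ymat = ymat + b.data[:, None]
        y = ymat.reshape(O, N, H, W).transpose(1, 0, 2, 3)
        req = x.requires_grad or w.requires_grad or (b is not None and b.requires_grad)
        out = Tensor(y, req, (x, w) if b is None else (x, w, b))

        def bw1(g):
            gmat = g.transpose(1, 0, 2, 3).reshape(O, N * H * W)
            if w.requires_grad:
                w._accumulate((gmat @ xmat.T).reshape(w.shape))
            if b is not None and b.requires_grad:
                b._accumulate(gmat.sum(axis=1))
            if x.requires_grad:
                dx = (wmat.T @ gmat).reshape(C, N, H, W).transpose(1, 0, 2, 3)
                x._accumulate(np.ascontiguousarray(dx))

        out._backward = bw1
        return out

    xp = np.pad(x.data, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    # patch matrix A: (C*kh*kw, N*H*W), built by cheap shifted-slice copies
    A = np.empty((C * kh * kw, N * H * W), dtype=np.float32)
    xpt = xp.transpose(1, 0, 2, 3)  # (C, N, Hp, Wp) view
    idx = 0
    for i in range(kh):
        for j in range(kw):
            A[idx : idx + C] = xpt[:, :, i : i + H, j : j + W].reshape(C, N * H * W)
            idx += C
    wmat = w.data.transpose(2, 3, 1, 0).reshape(C * kh * kw, O)  # rows match A
    ymat = (wmat.T @ A)
    if b is not None:
        ymat += b.data[:, None]
    y = ymat.reshape(O, N, H, W).transpose(1, 0, 2, 3)
    req = x.requires_grad or w.requires_grad or (b is not None and b.requires_grad)
    parents = (x, w) if b is None else (x, w, b)
    out = Tensor(np.ascontiguousarray(y), req, parents)

    def bw(g):
        gmat = g.transpose(1, 0, 2, 3).reshape(O, N * H * W)
        if w.requires_grad:
            dwmat = A @ gmat.T  # (C*kh*kw, O)
            w._accumulate(
                dwmat.reshape(kh, kw, C, O).transpose(3, 2, 0, 1)
            )
        if b is not None and b.requires_grad:
            b._accumulate(gmat.sum(axis=1))
        if x.requires_grad:
            dA = wmat @ gmat  # (C*kh*kw, N*H*W)
            dxp = np.zeros(xpt.shape, dtype=np.float32)  # (C, N, Hp, Wp)
            idx2 = 0
            for i in range(kh):
                for j in range(kw):
                    dxp[:, :, i : i + H, j : j + W] += dA[idx2 : idx2 + C].reshape(
                        C, N, H, W
                    )
                    idx2 += C
            x._accumulate(
                np.ascontiguousarray(
                    dxp[:, :, ph : ph + H, pw : pw + W].transpose(1, 0, 2, 3)
                )
            )

    out._backward = bw
    return out


def avgpool2(x: Tensor) -> Tensor:
    """2x2 average pooling; H and W must be even."""
    N, C, H, W = x.shape
    if H % 2 or W % 2:
        raise ValueError("avgpool2 requires even spatial dimensions")
    y = x.data.reshape(N, C, H // 2, 2, W // 2, 2).mean(axis=(3, 5))
    out = Tensor(y, x.requires_grad, (x,))

    def bw(g):
        if x.requires_grad:
            gx = np.repeat(np.repeat(g, 2, axis=2), 2, axis=3) * 0.25
            x._accumulate(gx)

    out._backward = bw
    return out


def upsample2(x: Tensor) -> Tensor:
    """Nearest-neighbour 2x upsampling."""
    N, C, H, W = x.shape
    y = np.repeat(np.repeat(x.data, 2, axis=2), 2, axis=3)
    out = Tensor(y, x.requires_grad, (x,))

    def bw(g):
        if x.requires_grad:
            x._accumulate(g.reshape(N, C, H, 2, W, 2).sum(axis=(3, 5)))

    out._backward = bw
    return out


class Adam:
    """Adam optimizer over a list of parameter Tensors."""

    def __init__(self, params: list[Tensor], lr: float = 1e-4, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = float(lr)
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / b1t
            vhat = self.v[i] / b2t
            p.data -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(np.float32)
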