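"""Minimal reverse-mode automatic differentiation over numpy arrays.

Just enough machinery for the next-frame forecaster: broadcast-aware
elementwise arithmetic, matmul, the usual activations, reshape/concat,
a strided valid convolution, and a non-overlapping transposed convolution
(kernel size == stride).  Gradients are accumulated by topological-order
backward passes; correctness is checked against central finite differences
in the test suite.
"""

from __future__ import annotations

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum a broadcast gradient back down to ``shape``."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents = parents
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    # -- graph traversal --------------------------------------------------

    def backward(self, grad: np.ndarray | None = None) -> None:
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
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad = self.grad + grad

    # -- ops ---------------------------------------------------------------

    def _binary(self, other, out_data, back_self, back_other) -> "Tensor":
        other = other if isinstance(other, Tensor) else Tensor(other)

        def backward(g):
            self._accumulate(_unbroadcast(back_self(g, other), self.data.shape))
            other._accumulate(_unbroadcast(back_other(g, other), other.data.shape))

        return Tensor(
            out_data(other),
            requires_grad=self.requires_grad or other.requires_grad,
            parents=(self, other),
            backward=backward,
        )

    def __add__(self, other):
        return self._binary(
            other,
            lambda o: self.data + o.data,
            lambda g, o: g,
            lambda g, o: g,
        )

    __radd__ = __add__

    def __sub__(self, other):
        return self._binary(
            other,
            lambda o: self.data - o.data,
            lambda g, o: g,
            lambda g, o: -g,
        )

    def __mul__(self, other):
        return self._binary(
            other,
            lambda o: self.data * o.data,
            lambda g, o: g * o.data,
            lambda g, o: g * self.data,
        )

    __rmul__ = __mul__

    def __neg__(self):
        return self * -1.0

    def matmul(self, other: "Tensor") -> "Tensor":
        other = other if isinstance(other, Tensor) else Tensor(other)

        def backward(g):
            self._accumulate(g @ other.data.T)
            other._accumulate(self.data.T @ g)

        return Tensor(
            self.data @ other.data,
            requires_grad=self.requires_grad or other.requires_grad,
            parents=(self, other),
            backward=backward,
        )

    __matmul__ = matmul

    def _unary(self, out_data, dgrad) -> "Tensor":
        def backward(g):
            self._accumulate(g * dgrad(out_data))

        return Tensor(
            out_data,
            requires_grad=self.requires_grad,
            parents=(self,),
            backward=backward,
        )

    def sigmoid(self) -> "Tensor":
        out = 1.0 / (1.0 + np.exp(-self.data))
        return self._unary(out, lambda o: o * (1.0 - o))

    def tanh(self) -> "Tensor":
        out = np.tanh(self.data)
        return self._unary(out, lambda o: 1.0 - o * o)

    def relu(self) -> "Tensor":
        out = np.maximum(self.data, 0.0)
        return self._unary(out, lambda o: (self.data > 0).astype(np.float64))

    def exp(self) -> "Tensor":
        out = np.exp(self.data)
        return self._unary(out, lambda o: o)

    def square(self) -> "Tensor":
        return self._unary(self.data**2, lambda o: 2.0 * self.data)

    def sum(self) -> "Tensor":
        def backward(g):
            self._accumulate(np.broadcast_to(g, self.data.shape).copy())

        return Tensor(
            self.data.sum(),
            requires_grad=self.requires_grad,
            parents=(self,),
            backward=backward,
        )

    def mean(self) -> "Tensor":
        n = self.data.size

        def backward(g):
            self._accumulate(np.broadcast_to(g / n, self.data.shape).copy())

        return Tensor(
            self.data.mean(),
            requires_grad=self.requires_grad,
            parents=(self,),
            backward=backward,
        )

    def reshape(self, *shape) -> "Tensor":
        old = self.data.shape

        def backward(g):
            self._accumulate(g.reshape(old))

        return Tensor(
            self.data.reshape(*shape),
            requires_grad=self.requires_grad,
            parents=(self,),
            backward=backward,
        )


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            idx = [slice(None)] * g.ndim
            idx[axis] = slice(a, b)
            t._accumulate(g[tuple(idx)])

    return Tensor(
        np.concatenate([t.data for t in tensors], axis=axis),
        requires_grad=any(t.requires_grad for t in tensors),
        parents=tuple(tensors),
        backward=backward,
    )


def conv2d(x: Tensor, w: Tensor, b: Tensor, stride: int) -> Tensor:
    """Valid (no padding) strided 2-D convolution.

    ``x``: (N, C, H, W); ``w``: (F, C, k, k); ``b``: (F,).  Output
    (N, F, Ho, Wo) with Ho = (H - k)//stride + 1.
    """
    N, C, H, W = x.data.shape
    F, _, k, _ = w.data.shape
    s = stride
    Ho, Wo = (H - k) // s + 1, (W - k) // s + 1
    xs = x.data
    st = xs.strides
    cols = np.lib.stride_tricks.as_strided(
        xs,
        shape=(N, C, Ho, Wo, k, k),
        strides=(st[0], st[1], st[2] * s, st[3] * s, st[2], st[3]),
    )
    cols = cols.reshape(N, C, Ho * Wo, k * k)  # copies
    wf = w.data.reshape(F, C * k * k)
    cols2 = cols.transpose(0, 2, 1, 3).reshape(N, Ho * Wo, C * k * k)
    out = np.einsum("npk,fk->nfp", cols2, wf).reshape(N, F, Ho, Wo)
    out += b.data.reshape(1, F, 1, 1)

    def backward(g):
        gp = g.reshape(N, F, Ho * Wo)
        b._accumulate(g.sum(axis=(0, 2, 3)))
        dw = np.einsum("nfp,npk->fk", gp, cols2).reshape(w.data.shape)
        w._accumulate(dw)
        dcols2 = np.einsum("nfp,fk->npk", gp, wf)  # (N, Ho*Wo, C*k*k)
        dx = np.zeros_like(xs)
        dcols = dcols2.reshape(N, Ho, Wo, C, k, k)
        for di in range(k):
            for dj in range(k):
                dx[:, :, di : di + Ho * s : s, dj : dj + Wo * s : s] += dcols[
                    :, :, :, :, di, dj
                ].transpose(0, 3, 1, 2)
        x._accumulate(dx)

    return Tensor(
        out,
        requires_grad=x.requires_grad or w.requires_grad or b.requires_grad,
        parents=(x, w, b),
        backward=backward,
    )


def conv_transpose2d(x: Tensor, w: Tensor, b: Tensor, stride: int) -> Tensor:
    """Non-overlapping transposed convolution (kernel size == stride).

    ``x``: (N, C, H, W); ``w``: (C, F, s, s); ``b``: (F,).  Output
    (N, F, H*s, W*s): each input pixel paints one s x s patch.
    """
    N, C, H, W = x.data.shape
    _, F, s, _ = w.data.shape
    if s != stride:
        raise ValueError("conv_transpose2d requires kernel size == stride")
    out = np.einsum("nchw,cfij->nfhiwj", x.data, w.data).reshape(N, F, H * s, W * s)
    out += b.data.reshape(1, F, 1, 1)

    def backward(g):
        gr = g.reshape(N, F, H, s, W, s)
        b._accumulate(g.sum(axis=(0, 2, 3)))
        w._accumulate(np.einsum("nchw,nfhiwj->cfij", x.data, gr))
        x._accumulate(np.einsum("nfhiwj,cfij->nchw", gr, w.data))

    return Tensor(
        out,
        requires_grad=x.requires_grad or w.requires_grad or b.requires_grad,
        parents=(x, w, b),
        backward=backward,
    )


class Adam:
    """Adam optimizer over one parameter group."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3, betas=(0.9, 0.999), eps=1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
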