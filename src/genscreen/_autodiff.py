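"""Minimal reverse-mode tensor autodiff.

The model components (style-based generator, discriminator, latent
optimization, projection head) need gradients of scalar losses with respect
to parameters *and*, for the R1 gradient penalty, gradients of a gradient
norm — i.e. double backward. This module provides a small NumPy tensor
graph whose vector-Jacobian products are themselves built from the same
primitives, so ``grad(..., create_graph=True)`` composes.

Only the operations the models need are implemented: broadcast arithmetic,
matmul, reductions, elementwise nonlinearities, reshape/transpose, and the
linear image ops (im2col/col2im, 2x up/down-sampling, integer shifts) used
by the convolutional blocks.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32

_GRAD_ENABLED = True


class no_grad:
    """Context manager that disables graph construction (forward only)."""

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False
        return self

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev
        return False


def _as_data(x) -> np.ndarray:
    if isinstance(x, Tensor):
        raise TypeError("expected raw array, got Tensor")
    return np.asarray(x, dtype=DTYPE)


class Tensor:
    """A node in the computation graph.

    ``_parents`` is a list of ``(parent, vjp)`` pairs where ``vjp`` maps the
    upstream gradient (a Tensor) to this parent's gradient contribution,
    expressed in graph ops so that second derivatives exist.
    """

    __slots__ = ("data", "requires_grad", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = _as_data(data)
        self.requires_grad = bool(requires_grad)
        self._parents: list = []

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _result(data, parents) -> "Tensor":
        out = Tensor.__new__(Tensor)
        out.data = data
        if _GRAD_ENABLED:
            out._parents = [(p, fn) for p, fn in parents if p.requires_grad]
        else:
            out._parents = []
        out.requires_grad = bool(out._parents)
        return out

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    # -- arithmetic -----------------------------------------------------------
    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = Tensor._wrap(other)
        out = Tensor._result(
            self.data + other.data,
            [
                (self, lambda u, s=self.shape: _unbroadcast(u, s)),
                (other, lambda u, s=other.shape: _unbroadcast(u, s)),
            ],
        )
        return out

    __radd__ = __add__

    def __neg__(self):
        return Tensor._result(-self.data, [(self, lambda u: -u)])

    def __sub__(self, other):
        return self + (-Tensor._wrap(other))

    def __rsub__(self, other):
        return Tensor._wrap(other) + (-self)

    def __mul__(self, other):
        other = Tensor._wrap(other)
        out = Tensor._result(
            self.data * other.data,
            [
                (self, lambda u, o=other, s=self.shape: _unbroadcast(u * o, s)),
                (other, lambda u, o=self, s=other.shape: _unbroadcast(u * o, s)),
            ],
        )
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor._wrap(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return Tensor._wrap(other) * self ** -1.0

    def __pow__(self, c: float):
        c = float(c)
        out = Tensor._result(
            self.data ** c,
            [(self, lambda u, a=self: u * (c * a ** (c - 1.0)) if c != 1.0 else u)],
        )
        return out

    def __matmul__(self, other):
        other = Tensor._wrap(other)
        if self.ndim != 2 or other.ndim != 2:
            raise ValueError("matmul supports 2-D operands only")
        out = Tensor._result(
            self.data @ other.data,
            [
                (self, lambda u, o=other: u @ o.T()),
                (other, lambda u, o=self: o.T() @ u),
            ],
        )
        return out

    # -- shape ops ------------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.shape
        return Tensor._result(
            self.data.reshape(shape), [(self, lambda u: u.reshape(old))]
        )

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        if not axes:
            axes = tuple(reversed(range(self.ndim)))
        inv = tuple(np.argsort(axes))
        return Tensor._result(
            self.data.transpose(axes), [(self, lambda u: u.transpose(inv))]
        )

    def T(self):
        return self.transpose()

    def expand(self, shape):
        """Broadcast to ``shape`` (adjoint: sum over broadcast axes)."""
        old = self.shape
        return Tensor._result(
            np.broadcast_to(self.data, shape).copy(),
            [(self, lambda u: _unbroadcast(u, old))],
        )

    # -- reductions -----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        shape = self.shape

        def vjp(u):
            if axis is None:
                return u.expand(shape) if u.ndim == 0 else u.reshape(
                    (1,) * len(shape)
                ).expand(shape)
            ax = axis if isinstance(axis, tuple) else (axis,)
            ax = tuple(a % len(shape) for a in ax)
            if not keepdims:
                kshape = tuple(
                    1 if i in ax else s for i, s in enumerate(shape)
                )
                u = u.reshape(kshape)
            return u.expand(shape)

        return Tensor._result(
            self.data.sum(axis=axis, keepdims=keepdims, dtype=DTYPE), [(self, vjp)]
        )

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            ax = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.shape[a] for a in ax]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- elementwise nonlinearities -------------------------------------------
    def exp(self):
        out = Tensor._result(np.exp(self.data), [])
        if self.requires_grad and _GRAD_ENABLED:
            out._parents = [(self, lambda u, y=out: u * y)]
            out.requires_grad = True
        return out

    def log(self):
        return Tensor._result(
            np.log(self.data), [(self, lambda u, a=self: u * a ** -1.0)]
        )

    def sigmoid(self):
        y = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor._result(y, [])
        if self.requires_grad and _GRAD_ENABLED:
            out._parents = [(self, lambda u, t=out: u * t * (1.0 - t))]
            out.requires_grad = True
        return out

    def softplus(self):
        out = Tensor._result(
            np.logaddexp(0.0, self.data).astype(DTYPE),
            [(self, lambda u, a=self: u * a.sigmoid())],
        )
        return out

    def leaky_relu(self, alpha: float = 0.2):
        mask = np.where(self.data > 0, 1.0, alpha).astype(DTYPE)
        return Tensor._result(self.data * mask, [(self, lambda u: u * Tensor(mask))])

    def clip_norm_eps(self, eps: float = 1e-8):
        """sqrt(x + eps), used by pixel norm / demodulation."""
        return (self + eps) ** 0.5

    # -- linear image primitives ----------------------------------------------
    def im2col(self, k: int):
        """(B,C,H,W) -> (B, C*k*k, H*W) patches for a same-padded conv."""
        B, C, H, W = self.shape

        def vjp(u):
            # adjoint is col2im; its own adjoint (double backward) is im2col
            return Tensor._result(
                _col2im_data(u.data, (B, C, H, W), k),
                [(u, lambda v: v.im2col(k))],
            )

        return Tensor._result(_im2col_data(self.data, k), [(self, vjp)])

    def upsample2x(self):
        """Nearest-neighbour x2 in H and W; adjoint is 2x2 sum pooling."""
        out = self.data.repeat(2, axis=-2).repeat(2, axis=-1)
        return Tensor._result(out, [(self, lambda u: u.sumpool2x())])

    def sumpool2x(self):
        B, C, H, W = self.shape
        out = self.data.reshape(B, C, H // 2, 2, W // 2, 2).sum(axis=(3, 5))
        return Tensor._result(out.astype(DTYPE), [(self, lambda u: u.upsample2x())])

    def avgpool2x(self):
        return self.sumpool2x() * 0.25

    def shift2d(self, dy: int, dx: int):
        """Integer translation with zero fill (linear, exactly invertible vjp)."""
        out = np.zeros_like(self.data)
        H, W = self.shape[-2:]
        ys = slice(max(dy, 0), H + min(dy, 0))
        yt = slice(max(-dy, 0), H + min(-dy, 0))
        xs = slice(max(dx, 0), W + min(dx, 0))
        xt = slice(max(-dx, 0), W + min(-dx, 0))
        out[..., ys, xs] = self.data[..., yt, xt]
        return Tensor._result(out, [(self, lambda u: u.shift2d(-dy, -dx))])


def _unbroadcast(u: Tensor, shape) -> Tensor:
    """Sum ``u`` down to ``shape`` (adjoint of NumPy broadcasting)."""
    if u.shape == tuple(shape):
        return u
    extra = u.ndim - len(shape)
    if extra > 0:
        u = u.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and u.shape[i] != 1)
    if axes:
        u = u.sum(axis=axes, keepdims=True)
    return u.reshape(shape)


def _im2col_data(x: np.ndarray, k: int) -> np.ndarray:
    B, C, H, W = x.shape
    p = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    # (B, C, H, W, k, k) -> (B, C*k*k, H*W)
    return np.ascontiguousarray(
        win.transpose(0, 1, 4, 5, 2, 3).reshape(B, C * k * k, H * W)
    )


def _col2im_data(cols: np.ndarray, x_shape, k: int) -> np.ndarray:
    B, C, H, W = x_shape
    p = k // 2
    cols6 = cols.reshape(B, C, k, k, H, W)
    out = np.zeros((B, C, H + 2 * p, W + 2 * p), dtype=DTYPE)
    for u in range(k):
        for v in range(k):
            out[:, :, u : u + H, v : v + W] += cols6[:, :, u, v]
    return np.ascontiguousarray(out[:, :, p : p + H, p : p + W]) if p else out


# Convolution contraction, W (O,K) applied to patch matrices cols (B,K,P),
# as a closed family of three bilinear primitives so that arbitrary-order
# differentiation stays inside the family (each vjp is another member).


def conv_apply(W, cols) -> "Tensor":
    """(O,K) x (B,K,P) -> (B,O,P), i.e. W @ cols per batch item."""
    W = Tensor._wrap(W)
    cols = Tensor._wrap(cols)
    return Tensor._result(
        np.matmul(W.data, cols.data),
        [
            (W, lambda u: conv_weight_grad(u, cols)),
            (cols, lambda u: conv_cols_grad(W, u)),
        ],
    )


def conv_weight_grad(u, cols) -> "Tensor":
    """(B,O,P) x (B,K,P) -> (O,K): sum_b u_b @ cols_b^T."""
    u = Tensor._wrap(u)
    cols = Tensor._wrap(cols)
    data = np.matmul(u.data, cols.data.swapaxes(1, 2)).sum(axis=0)
    return Tensor._result(
        data,
        [
            (u, lambda g: conv_apply(g, cols)),
            (cols, lambda g: conv_cols_grad(g, u)),
        ],
    )


def conv_cols_grad(W, u) -> "Tensor":
    """(O,K) x (B,O,P) -> (B,K,P): W^T @ u per batch item."""
    W = Tensor._wrap(W)
    u = Tensor._wrap(u)
    return Tensor._result(
        np.matmul(W.data.T, u.data),
        [
            (W, lambda g: conv_weight_grad(u, g)),
            (u, lambda g: conv_apply(W, g)),
        ],
    )


def grad(output: Tensor, inputs, grad_output=None, create_graph: bool = False):
    """Gradients of a scalar ``output`` with respect to ``inputs``.

    With ``create_graph=True`` the returned tensors carry their own graph so
    expressions of them (e.g. a squared gradient norm) can be differentiated
    again.
    """
    if grad_output is None:
        if output.data.size != 1:
            raise ValueError("output must be scalar unless grad_output is given")
        grad_output = Tensor(np.ones_like(output.data))

    topo: list[Tensor] = []
    seen = set()

    def visit(t: Tensor):
        stack = [(t, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p, _ in node._parents:
                stack.append((p, False))

    visit(output)

    grads: dict[int, Tensor] = {id(output): grad_output}
    for node in reversed(topo):
        g = grads.get(id(node))
        if g is None:
            continue
        for parent, vjp in node._parents:
            contrib = vjp(g)
            prev = grads.get(id(parent))
            grads[id(parent)] = contrib if prev is None else prev + contrib

    out = []
    for t in inputs:
        g = grads.get(id(t))
        if g is None:
            g = Tensor(np.zeros_like(t.data))
        elif not create_graph:
            g = g.detach()
        out.append(g)
    return out
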