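"""Neural building blocks for the generator, discriminator and probe.

Layers hold parameters as graph leaves and expose ``state_dict`` /
``load_state_dict`` round-trips of plain NumPy arrays so checkpoints are
simple ``.npz``-able dictionaries.
"""

from __future__ import annotations

import hashlib
from contextlib import contextmanager

import numpy as np

from ._autodiff import DTYPE, Tensor, conv_apply


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=DTYPE), requires_grad=True)


class Module:
    """Base class: parameter discovery + flat state dicts."""

    def named_parameters(self, prefix: str = ""):
        for name, val in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(val, Parameter):
                yield key, val
            elif isinstance(val, Module):
                yield from val.named_parameters(prefix=key + ".")
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield from item.named_parameters(prefix=f"{key}.{i}.")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def state_dict(self):
        return {k: v.data.copy() for k, v in self.named_parameters()}

    def load_state_dict(self, state):
        own = dict(self.named_parameters())
        missing = set(own) ^ set(state)
        if missing:
            raise ValueError(f"state dict mismatch on keys: {sorted(missing)}")
        for k, p in own.items():
            arr = np.asarray(state[k], dtype=DTYPE)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {k}")
            p.data = arr.copy()

    def weight_hash(self) -> str:
        """SHA-256 over all parameters; used to assert frozen weights."""
        h = hashlib.sha256()
        for k, p in sorted(self.named_parameters()):
            h.update(k.encode())
            h.update(np.ascontiguousarray(p.data).tobytes())
        return h.hexdigest()


class Dense(Module):
    """Fully connected layer, x @ W + b, uniform fan-in init."""

    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator,
                 bias_init: float = 0.0):
        bound = 1.0 / np.sqrt(in_dim)
        self.W = Parameter(rng.uniform(-bound, bound, size=(in_dim, out_dim)))
        self.b = Parameter(np.full(out_dim, bias_init))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b


class Conv2d(Module):
    """Same-padded stride-1 convolution via im2col."""

    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator):
        fan_in = cin * k * k
        bound = 1.0 / np.sqrt(fan_in)
        self.W = Parameter(rng.uniform(-bound, bound, size=(cout, fan_in)))
        self.b = Parameter(np.zeros(cout))
        self.k = k
        self.cin = cin
        self.cout = cout

    def __call__(self, x: Tensor) -> Tensor:
        B, C, H, W = x.shape
        cols = x.im2col(self.k)                       # (B, C*k*k, H*W)
        out = conv_apply(self.W, cols) + self.b.reshape(1, self.cout, 1)
        return out.reshape(B, self.cout, H, W)


class ModulatedConv2d(Module):
    """Style-modulated convolution with weight demodulation.

    The per-sample style ``s = affine(w)`` scales input channels before the
    convolution; demodulation rescales each output channel to unit expected
    norm, as in style-based generators.
    """

    def __init__(self, cin: int, cout: int, k: int, w_dim: int,
                 rng: np.random.Generator, demodulate: bool = True):
        self.affine = Dense(w_dim, cin, rng, bias_init=1.0)
        fan_in = cin * k * k
        self.W = Parameter(rng.standard_normal((cout, fan_in)) / np.sqrt(fan_in))
        self.b = Parameter(np.zeros(cout))
        self.k = k
        self.cin = cin
        self.cout = cout
        self.demodulate = demodulate

    def __call__(self, x: Tensor, w: Tensor) -> Tensor:
        B, C, H, Wd = x.shape
        s = self.affine(w)                            # (B, cin)
        xm = x * s.reshape(B, C, 1, 1)
        cols = xm.im2col(self.k)
        out = conv_apply(self.W, cols)                # (B, cout, H*W)
        if self.demodulate:
            # d_j = 1 / sqrt(sum_i (W_ji * s_i)^2 + eps) per sample and out-channel
            w2 = (self.W ** 2.0).reshape(self.cout, self.cin, self.k * self.k).sum(
                axis=2
            )                                         # (cout, cin)
            denom = ((s ** 2.0) @ w2.T() + 1e-8) ** 0.5  # (B, cout)
            out = out * (denom ** -1.0).reshape(B, self.cout, 1)
        out = out + self.b.reshape(1, self.cout, 1)
        return out.reshape(B, self.cout, H, Wd)


@contextmanager
def frozen(*modules: Module):
    """Temporarily mark parameters as non-differentiable.

    Graph construction skips frozen leaves entirely, so backward passes
    that only need gradients w.r.t. activations (e.g. latent inversion
    against fixed weights) avoid the weight-gradient work.
    """
    params = [p for m in modules for p in m.parameters()]
    try:
        for p in params:
            p.requires_grad = False
        yield
    finally:
        for p in params:
            p.requires_grad = True


def pixel_norm(z: Tensor) -> Tensor:
    return z * (((z ** 2.0).mean(axis=1, keepdims=True) + 1e-8) ** -0.5)


class Adam:
    """Adam over graph-leaf parameters (decoupled from the graph)."""

    def __init__(self, params, lr: float, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self, grads):
        self.t += 1
        b1, b2 = self.b1, self.b2
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            gd = g.data if isinstance(g, Tensor) else g
            m *= b1
            m += (1 - b1) * gd
            v *= b2
            v += (1 - b2) * gd * gd
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
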