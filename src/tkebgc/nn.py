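"""Minimal reverse-mode automatic differentiation on NumPy arrays.

The controller and classifier networks in this package are small (a few
dense / 1-D convolution / attention / GRU layers over short histories), so
they run comfortably on a vectorized NumPy engine.  ``Tensor`` wraps an
ndarray, records the operations applied to it, and ``backward`` accumulates
gradients by topological traversal.  Gradients are verified against central
finite differences in the test suite.

Conventions
-----------
* Batched operands broadcast like NumPy; gradients are summed back to the
  parameter's shape (``_unbroadcast``).
* All floats are float64 — these models are tiny and determinism across
  platforms matters more than speed here.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "concat",
    "Adam",
    "Linear",
    "Conv1d",
    "LayerNorm",
    "GRU",
    "softmax",
    "log_softmax",
    "layer_norm",
    "cross_entropy",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- constructors -----------------------------------------------------
    @staticmethod
    def _make(data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad or p._parents for p in parents):
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    # -- arithmetic -------------------------------------------------------
    @staticmethod
    def _coerce(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = Tensor._coerce(other)

        def bw(g, out):
            return (_unbroadcast(g, self.shape), _unbroadcast(g, other.shape))

        return Tensor._make(self.data + other.data, (self, other), bw)

    __radd__ = __add__

    def __neg__(self):
        return Tensor._make(-self.data, (self,), lambda g, out: (-g,))

    def __sub__(self, other):
        return self + (-Tensor._coerce(other))

    def __rsub__(self, other):
        return Tensor._coerce(other) + (-self)

    def __mul__(self, other):
        other = Tensor._coerce(other)

        def bw(g, out):
            return (
                _unbroadcast(g * other.data, self.shape),
                _unbroadcast(g * self.data, other.shape),
            )

        return Tensor._make(self.data * other.data, (self, other), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor._coerce(other)

        def bw(g, out):
            return (
                _unbroadcast(g / other.data, self.shape),
                _unbroadcast(-g * self.data / other.data**2, other.shape),
            )

        return Tensor._make(self.data / other.data, (self, other), bw)

    def __matmul__(self, other):
        other = Tensor._coerce(other)

        def bw(g, out):
            ga = _unbroadcast(np.matmul(g, np.swapaxes(other.data, -1, -2)), self.shape)
            gb = _unbroadcast(np.matmul(np.swapaxes(self.data, -1, -2), g), other.shape)
            return ga, gb

        return Tensor._make(np.matmul(self.data, other.data), (self, other), bw)

    def pow(self, exponent: float) -> "Tensor":
        def bw(g, out):
            return (g * exponent * self.data ** (exponent - 1.0),)

        return Tensor._make(self.data**exponent, (self,), bw)

    # -- elementwise nonlinearities --------------------------------------
    def exp(self) -> "Tensor":
        def bw(g, out):
            return (g * out.data,)

        return Tensor._make(np.exp(self.data), (self,), bw)

    def log(self) -> "Tensor":
        def bw(g, out):
            return (g / self.data,)

        return Tensor._make(np.log(self.data), (self,), bw)

    def relu(self) -> "Tensor":
        mask = self.data > 0

        def bw(g, out):
            return (g * mask,)

        return Tensor._make(self.data * mask, (self,), bw)

    def tanh(self) -> "Tensor":
        def bw(g, out):
            return (g * (1.0 - out.data**2),)

        return Tensor._make(np.tanh(self.data), (self,), bw)

    def sigmoid(self) -> "Tensor":
        y = 1.0 / (1.0 + np.exp(-self.data))

        def bw(g, out):
            return (g * out.data * (1.0 - out.data),)

        return Tensor._make(y, (self,), bw)

    # -- reductions and shape ops ----------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        def bw(g, out):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return (np.broadcast_to(g, self.shape).copy(),)

        return Tensor._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), bw)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        if axis is None:
            n = self.data.size
        else:
            axes = (axis,) if isinstance(axis, int) else axis
            n = int(np.prod([self.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])

        def bw(g, out):
            return (g.reshape(self.shape),)

        return Tensor._make(self.data.reshape(shape), (self,), bw)

    def transpose(self, *axes) -> "Tensor":
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)

        def bw(g, out):
            return (g.transpose(inv),)

        return Tensor._make(self.data.transpose(axes), (self,), bw)

    def __getitem__(self, idx) -> "Tensor":
        def bw(g, out):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            return (full,)

        return Tensor._make(self.data[idx], (self,), bw)

    # -- graph traversal --------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
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
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=np.float64)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.requires_grad:
                node.grad = g if node.grad is None else node.grad + g
            if node._backward is None:
                continue
            for parent, pg in zip(node._parents, node._backward(g, node)):
                if pg is None:
                    continue
                key = id(parent)
                grads[key] = pg if key not in grads else grads[key] + pg


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    tensors = [Tensor._coerce(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bw(g, out):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor._make(
        np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), bw
    )


def unfold1d(x: Tensor, kernel: int) -> Tensor:
    """Extract same-padded sliding windows along axis 1.

    [B, T, C] -> [B, T, kernel * C]; backward scatters window gradients
    back onto the padded sequence.
    """
    pad = kernel // 2
    B, T, C = x.shape
    xp = np.pad(x.data, ((0, 0), (pad, pad), (0, 0)))
    win = np.lib.stride_tricks.sliding_window_view(xp, kernel, axis=1)  # [B,T,C,k]
    out_data = np.ascontiguousarray(win.transpose(0, 1, 3, 2)).reshape(B, T, kernel * C)

    def bw(g, out):
        g4 = g.reshape(B, T, kernel, C)
        gxp = np.zeros_like(xp)
        for i in range(kernel):
            gxp[:, i : i + T, :] += g4[:, :, i, :]
        return (gxp[:, pad : pad + T, :],)

    return Tensor._make(out_data, (x,), bw)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    shift = x - Tensor(x.data.max(axis=axis, keepdims=True))
    e = shift.exp()
    return e / e.sum(axis=axis, keepdims=True)


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    shift = x - Tensor(x.data.max(axis=axis, keepdims=True))
    return shift - shift.exp().sum(axis=axis, keepdims=True).log()


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    mu = x.mean(axis=-1, keepdims=True)
    xc = x - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    return xc / (var + eps).pow(0.5) * gamma + beta


def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean negative log-likelihood of integer ``labels`` under ``logits``."""
    lp = log_softmax(logits, axis=-1)
    n = logits.shape[0]
    picked = lp[(np.arange(n), np.asarray(labels))]
    return -picked.mean()


def dropout(x: Tensor, rate: float, rng: np.random.Generator | None) -> Tensor:
    """Inverted dropout; identity when rate == 0 or rng is None (inference)."""
    if rate <= 0.0 or rng is None:
        return x
    mask = (rng.random(x.shape) >= rate) / (1.0 - rate)
    return x * Tensor(mask)


# -- layers ---------------------------------------------------------------


class Module:
    def parameters(self) -> list[Tensor]:
        out: list[Tensor] = []
        for v in vars(self).values():
            if isinstance(v, Tensor) and v.requires_grad:
                out.append(v)
            elif isinstance(v, Module):
                out.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out.extend(item.parameters())
        return out


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape) -> Tensor:
    lim = np.sqrt(6.0 / (fan_in + fan_out))
    return Tensor(rng.uniform(-lim, lim, size=shape), requires_grad=True)


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator, bias: bool = True):
        self.W = _glorot(rng, d_in, d_out, (d_in, d_out))
        self.b = Tensor(np.zeros(d_out), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        y = x @ self.W
        return y + self.b if self.b is not None else y


class Conv1d(Module):
    """Same-padded 1-D convolution over [B, T, C_in] -> [B, T, C_out]."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        self.kernel = kernel
        self.W = _glorot(rng, kernel * c_in, c_out, (kernel * c_in, c_out))
        self.b = Tensor(np.zeros(c_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return unfold1d(x, self.kernel) @ self.W + self.b


def avg_pool1d(x: Tensor, kernel: int) -> Tensor:
    """Same-padded stride-1 average pooling along axis 1 (length preserved)."""
    B, T, C = x.shape
    u = unfold1d(x, kernel).reshape(B, T, kernel, C)
    return u.mean(axis=2)


class LayerNorm(Module):
    def __init__(self, dim: int):
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return layer_norm(x, self.gamma, self.beta)


class GRU(Module):
    """Single-layer gated recurrent unit over [B, T, C]; returns final hidden."""

    def __init__(self, d_in: int, d_hidden: int, rng: np.random.Generator):
        self.d_hidden = d_hidden
        self.Wx = _glorot(rng, d_in, 3 * d_hidden, (d_in, 3 * d_hidden))
        self.Wh = _glorot(rng, d_hidden, 3 * d_hidden, (d_hidden, 3 * d_hidden))
        self.b = Tensor(np.zeros(3 * d_hidden), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        B, T, _ = x.shape
        d = self.d_hidden
        h = Tensor(np.zeros((B, d)))
        for t in range(T):
            xt = x[(slice(None), t)]
            gx = xt @ self.Wx + self.b
            gh = h @ self.Wh
            z = (gx[:, 0:d] + gh[(slice(None), slice(0, d))]).sigmoid()
            r = (gx[:, d : 2 * d] + gh[(slice(None), slice(d, 2 * d))]).sigmoid()
            n = (gx[:, 2 * d : 3 * d] + r * gh[(slice(None), slice(2 * d, 3 * d))]).tanh()
            h = (1.0 - z) * n + z * h
        return h


class Adam:
    """Adam optimizer (beta1=0.9, beta2=0.999) over a fixed parameter list."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def clip_grad_norm(self, max_norm: float) -> float:
        """Scale all gradients so their global L2 norm is at most ``max_norm``."""
        total = np.sqrt(sum(float((p.grad**2).sum()) for p in self.params
                            if p.grad is not None))
        if total > max_norm:
            scale = max_norm / (total + 1e-12)
            for p in self.params:
                if p.grad is not None:
                    p.grad = p.grad * scale
        return total

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
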