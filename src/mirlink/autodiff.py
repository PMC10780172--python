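"""Minimal reverse-mode automatic differentiation over numpy arrays.

The neural components of this package (graph autoencoders, cascade attention
classifier) are small dense models; this module provides just the tensor
operations they need, with gradients verified against finite differences in
the test suite. Broadcasting follows numpy semantics; gradients of broadcast
operands are summed back to the operand's shape.

Only float64 is used: the models are small and determinism across platforms
matters more than speed here.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "tensor",
    "parameter",
    "concat",
    "stack",
    "bce_with_logits",
    "bce",
    "Adam",
]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing numpy broadcasting."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    # sum over axes that were size-1 in the original
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, parents=(), requires_grad=False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self._parents = tuple(parents)
        self._backward = None
        self.requires_grad = requires_grad or any(
            p.requires_grad for p in self._parents
        )

    # -- construction helpers -------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- arithmetic -----------------------------------------------------------

    def __add__(self, other):
        other = tensor(other)
        out = Tensor(self.data + other.data, (self, other))

        def backward(g):
            return _unbroadcast(g, self.shape), _unbroadcast(g, other.shape)

        out._backward = backward
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, (self,))
        out._backward = lambda g: (-g,)
        return out

    def __sub__(self, other):
        return self + (-tensor(other))

    def __rsub__(self, other):
        return tensor(other) + (-self)

    def __mul__(self, other):
        other = tensor(other)
        out = Tensor(self.data * other.data, (self, other))

        def backward(g):
            return (
                _unbroadcast(g * other.data, self.shape),
                _unbroadcast(g * self.data, other.shape),
            )

        out._backward = backward
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        if isinstance(other, Tensor):
            raise TypeError("division by a Tensor is not supported; multiply by a constant reciprocal")
        return self * (1.0 / other)

    def __matmul__(self, other):
        other = tensor(other)
        out = Tensor(self.data @ other.data, (self, other))
        a, b = self.data, other.data

        def backward(g):
            if a.ndim == 1 or b.ndim == 1:
                raise ValueError("matmul requires >=2-D operands")
            ga = g @ np.swapaxes(b, -1, -2)
            gb = np.swapaxes(a, -1, -2) @ g
            return _unbroadcast(ga, self.shape), _unbroadcast(gb, other.shape)

        out._backward = backward
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], (self,))

        def backward(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            return (full,)

        out._backward = backward
        return out

    # -- shape ops ------------------------------------------------------------

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), (self,))
        out._backward = lambda g: (g.reshape(self.shape),)
        return out

    def transpose(self):
        out = Tensor(np.swapaxes(self.data, -1, -2), (self,))
        out._backward = lambda g: (np.swapaxes(g, -1, -2),)
        return out

    @property
    def T(self):
        return self.transpose()

    # -- reductions -----------------------------------------------------------

    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), (self,))

        def backward(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return (np.broadcast_to(g, self.shape).copy(),)

        out._backward = backward
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- elementwise nonlinearities -------------------------------------------

    def relu(self):
        out = Tensor(np.maximum(self.data, 0.0), (self,))
        out._backward = lambda g: (g * (self.data > 0.0),)
        return out

    def sigmoid(self):
        s = _sigmoid(self.data)
        out = Tensor(s, (self,))
        out._backward = lambda g: (g * s * (1.0 - s),)
        return out

    def log(self):
        out = Tensor(np.log(self.data), (self,))
        out._backward = lambda g: (g / self.data,)
        return out

    def exp(self):
        e = np.exp(self.data)
        out = Tensor(e, (self,))
        out._backward = lambda g: (g * e,)
        return out

    def softmax(self, axis=-1):
        """Numerically stable softmax along `axis`."""
        x = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(x)
        s = e / e.sum(axis=axis, keepdims=True)
        out = Tensor(s, (self,))

        def backward(g):
            dot = (g * s).sum(axis=axis, keepdims=True)
            return (s * (g - dot),)

        out._backward = backward
        return out

    # -- autodiff driver ------------------------------------------------------

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        # iterative post-order traversal (avoids recursion limits)
        order: list[Tensor] = []
        state: dict[int, bool] = {}
        work: list[tuple[Tensor, bool]] = [(self, False)]
        while work:
            node, processed = work.pop()
            if processed:
                order.append(node)
                continue
            if state.get(id(node)):
                continue
            state[id(node)] = True
            work.append((node, True))
            for p in node._parents:
                if not state.get(id(p)):
                    work.append((p, False))

        grads: dict[int, np.ndarray] = {id(self): np.ones_like(self.data)}
        for node in reversed(order):
            g = grads.pop(id(node), None)
            if g is None or not node.requires_grad:
                continue
            if node._backward is None:  # trainable leaf
                node.grad = g if node.grad is None else node.grad + g
                continue
            for p, pg in zip(node._parents, node._backward(g)):
                if not p.requires_grad:
                    continue
                if id(p) in grads:
                    grads[id(p)] = grads[id(p)] + pg
                else:
                    grads[id(p)] = pg


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=np.float64)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    e = np.exp(x[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def tensor(x) -> Tensor:
    """Wrap `x` as a constant Tensor (no-op if already a Tensor)."""
    return x if isinstance(x, Tensor) else Tensor(x)


def parameter(x) -> Tensor:
    """Wrap `x` as a trainable leaf Tensor."""
    return Tensor(np.array(x, dtype=np.float64), requires_grad=True)


def concat(tensors, axis=-1) -> Tensor:
    tensors = [tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), tensors)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=axis))

    out._backward = backward
    return out


def stack(tensors, axis=0) -> Tensor:
    tensors = [tensor(t) for t in tensors]
    out = Tensor(np.stack([t.data for t in tensors], axis=axis), tensors)

    def backward(g):
        return tuple(np.moveaxis(g, axis, 0))

    out._backward = backward
    return out


def bce_with_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean binary cross-entropy computed stably from logits.

    Uses max(z,0) - z*t + log(1+exp(-|z|)); the gradient is
    (sigmoid(z) - t)/N, implemented as a primitive for stability.
    """
    t = np.asarray(targets, dtype=np.float64)
    z = logits.data
    val = np.maximum(z, 0.0) - z * t + np.log1p(np.exp(-np.abs(z)))
    out = Tensor(val.mean(), (logits,))
    n = z.size

    def backward(g):
        return (g * (_sigmoid(z) - t) / n,)

    out._backward = backward
    return out


def bce(probs: Tensor, targets: np.ndarray, eps: float = 1e-12) -> Tensor:
    """Mean binary cross-entropy from probabilities (clipped at eps)."""
    t = tensor(np.asarray(targets, dtype=np.float64))
    p = probs
    logp = Tensor(np.log(np.clip(p.data, eps, 1.0)), (p,))
    logp._backward = lambda g: (g / np.clip(p.data, eps, 1.0),)
    log1mp = Tensor(np.log(np.clip(1.0 - p.data, eps, 1.0)), (p,))
    log1mp._backward = lambda g: (-g / np.clip(1.0 - p.data, eps, 1.0),)
    return -(t * logp + (1.0 - t) * log1mp).mean()


class Adam:
    """Adam optimizer over a list of parameter Tensors."""

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
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
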