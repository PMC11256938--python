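"""Minimal reverse-mode automatic differentiation over numpy arrays.

The model's four multilayer perceptrons and the variational objective are
small enough that a tape-based engine in float64 is fast, exactly
gradient-checkable, and keeps the whole training path free of heavyweight
framework dependencies.  Only the operations the objective needs are
implemented; every op registers a closure that maps the output cotangent to
parent cotangents, and :meth:`Tensor.backward` replays the tape in reverse
topological order.

Broadcasting follows numpy semantics; gradients are summed back over
broadcast axes by :func:`_unbroadcast`.
"""

from __future__ import annotations

import numpy as np
from scipy import special as _sp

__all__ = ["Tensor", "Parameter", "Adam", "concat", "logsumexp"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` over axes that were broadcast to reach ``grad.shape``."""
    if grad.shape == shape:
        return grad
    # leading axes added by broadcasting
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # axes of size 1 that were stretched
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


def _as_tensor(x) -> "Tensor":
    if isinstance(x, Tensor):
        return x
    return Tensor(np.asarray(x, dtype=np.float64), requires_grad=False)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_grad_fns")

    # make numpy defer `ndarray <op> Tensor` to the reflected Tensor ops
    __array_priority__ = 1000

    def __init__(self, data, requires_grad: bool = False, parents=(), grad_fns=()):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self.grad: np.ndarray | None = None
        self._parents = tuple(parents)
        self._grad_fns = tuple(grad_fns)

    # -- tape -------------------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar output")
            grad = np.ones_like(self.data)
        # iterative topological sort (graphs can be deep for many-layer chains)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
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
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=np.float64)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if not node._parents:
                # leaf (Parameter or input): materialize the gradient
                node.grad = g if node.grad is None else node.grad + g
                continue
            for parent, fn in zip(node._parents, node._grad_fns):
                if not parent.requires_grad:
                    continue
                pg = fn(g)
                if id(parent) in grads:
                    grads[id(parent)] = grads[id(parent)] + pg
                else:
                    grads[id(parent)] = pg

    # -- arithmetic -------------------------------------------------------

    def __add__(self, other):
        other = _as_tensor(other)
        return Tensor(
            self.data + other.data,
            parents=(self, other),
            grad_fns=(
                lambda g, s=self.data.shape: _unbroadcast(g, s),
                lambda g, s=other.data.shape: _unbroadcast(g, s),
            ),
        )

    __radd__ = __add__

    def __neg__(self):
        return Tensor(-self.data, parents=(self,), grad_fns=(lambda g: -g,))

    def __sub__(self, other):
        return self + (-_as_tensor(other))

    def __rsub__(self, other):
        return _as_tensor(other) + (-self)

    def __mul__(self, other):
        other = _as_tensor(other)
        return Tensor(
            self.data * other.data,
            parents=(self, other),
            grad_fns=(
                lambda g, o=other.data, s=self.data.shape: _unbroadcast(g * o, s),
                lambda g, o=self.data, s=other.data.shape: _unbroadcast(g * o, s),
            ),
        )

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = _as_tensor(other)
        return Tensor(
            self.data / other.data,
            parents=(self, other),
            grad_fns=(
                lambda g, o=other.data, s=self.data.shape: _unbroadcast(g / o, s),
                lambda g, a=self.data, o=other.data, s=other.data.shape: _unbroadcast(
                    -g * a / (o * o), s
                ),
            ),
        )

    def __rtruediv__(self, other):
        return _as_tensor(other) / self

    def __matmul__(self, other):
        other = _as_tensor(other)
        return Tensor(
            self.data @ other.data,
            parents=(self, other),
            grad_fns=(
                lambda g, o=other.data: g @ o.T,
                lambda g, a=self.data: a.T @ g,
            ),
        )

    def __pow__(self, exponent: float):
        return Tensor(
            self.data ** exponent,
            parents=(self,),
            grad_fns=(lambda g, a=self.data, e=exponent: g * e * a ** (e - 1),),
        )

    # -- elementwise nonlinearities ---------------------------------------

    def exp(self):
        out = np.exp(self.data)
        return Tensor(out, parents=(self,), grad_fns=(lambda g, o=out: g * o,))

    def log(self):
        return Tensor(
            np.log(self.data), parents=(self,), grad_fns=(lambda g, a=self.data: g / a,)
        )

    def sigmoid(self):
        out = _sp.expit(self.data)
        return Tensor(
            out, parents=(self,), grad_fns=(lambda g, o=out: g * o * (1.0 - o),)
        )

    def softplus(self):
        out = np.logaddexp(0.0, self.data)
        return Tensor(
            out,
            parents=(self,),
            grad_fns=(lambda g, a=self.data: g * _sp.expit(a),),
        )

    def relu(self):
        mask = self.data > 0
        return Tensor(
            self.data * mask, parents=(self,), grad_fns=(lambda g, m=mask: g * m,)
        )

    def lgamma(self):
        return Tensor(
            _sp.gammaln(self.data),
            parents=(self,),
            grad_fns=(lambda g, a=self.data: g * _sp.digamma(a),),
        )

    def square(self):
        return Tensor(
            self.data * self.data,
            parents=(self,),
            grad_fns=(lambda g, a=self.data: 2.0 * g * a,),
        )

    # -- reductions / shape ops -------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out = self.data.sum(axis=axis, keepdims=keepdims)

        def grad_fn(g, axis=axis, keepdims=keepdims, shape=self.data.shape):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return np.broadcast_to(g, shape).copy()

        return Tensor(out, parents=(self,), grad_fns=(grad_fn,))

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def softmax(self, axis: int = -1):
        shifted = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(shifted)
        out = e / e.sum(axis=axis, keepdims=True)

        def grad_fn(g, o=out, axis=axis):
            dot = (g * o).sum(axis=axis, keepdims=True)
            return o * (g - dot)

        return Tensor(out, parents=(self,), grad_fns=(grad_fn,))

    def log_softmax(self, axis: int = -1):
        shifted = self.data - self.data.max(axis=axis, keepdims=True)
        lse = np.log(np.exp(shifted).sum(axis=axis, keepdims=True))
        out = shifted - lse
        sm = np.exp(out)

        def grad_fn(g, sm=sm, axis=axis):
            return g - sm * g.sum(axis=axis, keepdims=True)

        return Tensor(out, parents=(self,), grad_fns=(grad_fn,))

    def __getitem__(self, idx):
        def grad_fn(g, idx=idx, shape=self.data.shape):
            out = np.zeros(shape)
            np.add.at(out, idx, g)
            return out

        return Tensor(self.data[idx], parents=(self,), grad_fns=(grad_fn,))

    def reshape(self, *shape):
        return Tensor(
            self.data.reshape(*shape),
            parents=(self,),
            grad_fns=(lambda g, s=self.data.shape: g.reshape(s),),
        )


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def make_fn(i):
        def grad_fn(g):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(offsets[i], offsets[i + 1])
            return g[tuple(sl)]

        return grad_fn

    return Tensor(
        np.concatenate([t.data for t in tensors], axis=axis),
        parents=tuple(tensors),
        grad_fns=tuple(make_fn(i) for i in range(len(tensors))),
    )


def logsumexp(t: Tensor, axis: int = -1, keepdims: bool = False) -> Tensor:
    out = _sp.logsumexp(t.data, axis=axis, keepdims=keepdims)
    sm = np.exp(t.data - _sp.logsumexp(t.data, axis=axis, keepdims=True))

    def grad_fn(g, sm=sm, axis=axis, keepdims=keepdims):
        g = np.asarray(g)
        if not keepdims:
            g = np.expand_dims(g, axis)
        return sm * g

    return Tensor(out, parents=(t,), grad_fns=(grad_fn,))


class Parameter(Tensor):
    __slots__ = ()

    def __init__(self, data):
        super().__init__(np.array(data, dtype=np.float64), requires_grad=True)


class Adam:
    """Adam optimizer (Kingma & Ba) over a list of Parameters."""

    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            g = p.grad
            if g is None:
                continue
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def state_dict(self) -> dict:
        return {"t": self.t, "m": self.m, "v": self.v}

    def load_state_dict(self, state: dict) -> None:
        self.t = state["t"]
        self.m = [np.asarray(x) for x in state["m"]]
        self.v = [np.asarray(x) for x in state["v"]]
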