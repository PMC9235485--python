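"""Minimal reverse-mode automatic differentiation on numpy arrays.

The training objective couples a message-passing encoder, a trilinear
tensor decoder and shrinkage priors, so gradients are taken through a
small dynamically built computation graph.  Only the operations this
package needs are provided; all of them are dense numpy (or
scipy.sparse-times-dense) kernels, and every backward rule is exercised
against central finite differences in the test suite.

Conventions
-----------
* ``Tensor`` wraps a float64 ``ndarray``.  Graph leaves created with
  ``Tensor(value, requires_grad=True)`` are parameters; ``wrap`` turns
  plain arrays into constants.
* ``backward`` may only be called on scalar outputs.
* Broadcasting is supported for elementwise ``+``/``-``/``*`` (gradients
  are summed over broadcast axes).
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

__all__ = [
    "Tensor",
    "wrap",
    "matmul",
    "sparse_matmul",
    "gather_rows",
    "vconcat",
    "hconcat",
    "relu",
    "softplus",
    "exp",
    "log",
    "square",
    "absolute",
    "total",
    "reshape",
    "transpose",
    "rms_normalize_columns",
    "trilinear_scores",
    "Adam",
]


class Tensor:
    """A node in the computation graph holding a value and a gradient."""

    __slots__ = ("value", "grad", "requires_grad", "_parents", "_backward",
                 "_grad_owned")

    # make numpy defer to the reflected operators instead of broadcasting
    __array_ufunc__ = None

    def __init__(self, value, requires_grad=False, _parents=(), _backward=None):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = None
        self.requires_grad = requires_grad
        self._parents = _parents
        self._backward = _backward
        self._grad_owned = False

    @property
    def shape(self):
        return self.value.shape

    def item(self) -> float:
        return float(self.value)

    # -- graph traversal ------------------------------------------------
    def backward(self) -> None:
        if self.value.ndim != 0:
            raise ValueError("backward() requires a scalar output")
        order: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative topological sort (graphs can be deep)
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        for node in order:
            node.grad = None
            node._grad_owned = False
        self.grad = np.ones_like(self.value)
        for node in reversed(order):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accumulate(self, g: np.ndarray) -> None:
        # copy-on-write: keep a reference until a second gradient arrives
        # (backward closures may hand the same array to several parents)
        if self.grad is None:
            self.grad = g
            self._grad_owned = False
        elif self._grad_owned:
            self.grad += g
        else:
            self.grad = self.grad + g
            self._grad_owned = True

    # -- operators ------------------------------------------------------
    def __add__(self, other):
        return _elementwise_add(self, wrap(other), 1.0)

    __radd__ = __add__

    def __sub__(self, other):
        return _elementwise_add(self, wrap(other), -1.0)

    def __rsub__(self, other):
        return wrap(other) - self

    def __mul__(self, other):
        return _elementwise_mul(self, wrap(other))

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __matmul__(self, other):
        return matmul(self, wrap(other))

    def sum(self):
        return total(self)


def wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``g`` over axes that were broadcast to reach ``g.shape``."""
    if g.shape == shape:
        return g
    extra = g.ndim - len(shape)
    if extra > 0:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, n in enumerate(shape) if n == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g


def _elementwise_add(a: Tensor, b: Tensor, sign: float) -> Tensor:
    out = Tensor(a.value + sign * b.value, _parents=(a, b))

    def bw(g):
        a._accumulate(_unbroadcast(g, a.value.shape))
        b._accumulate(_unbroadcast(sign * g, b.value.shape))

    out._backward = bw
    return out


def _elementwise_mul(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.value * b.value, _parents=(a, b))

    def bw(g):
        a._accumulate(_unbroadcast(g * b.value, a.value.shape))
        b._accumulate(_unbroadcast(g * a.value, b.value.shape))

    out._backward = bw
    return out


def matmul(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.value @ b.value, _parents=(a, b))

    def bw(g):
        a._accumulate(g @ b.value.T)
        b._accumulate(a.value.T @ g)

    out._backward = bw
    return out


def sparse_matmul(s: sp.spmatrix, x: Tensor) -> Tensor:
    """``s @ x`` for a constant sparse matrix ``s`` (e.g. incidence maps)."""
    s = sp.csr_matrix(s)
    out = Tensor(s @ x.value, _parents=(x,))
    st = sp.csr_matrix(s.T)

    def bw(g):
        x._accumulate(st @ g)

    out._backward = bw
    return out


def gather_rows(x: Tensor, idx: np.ndarray) -> Tensor:
    idx = np.asarray(idx, dtype=np.intp)
    out = Tensor(x.value[idx], _parents=(x,))
    n_rows = x.value.shape[0]

    def bw(g):
        # scatter-add via a one-hot sparse selection (faster than ufunc.at)
        sel = sp.csr_matrix(
            (np.ones(len(idx)), idx, np.arange(len(idx) + 1)),
            shape=(len(idx), n_rows))
        x._accumulate(sel.T @ g)

    out._backward = bw
    return out


def vconcat(parts: list[Tensor]) -> Tensor:
    out = Tensor(np.concatenate([p.value for p in parts], axis=0),
                 _parents=tuple(parts))
    sizes = [p.value.shape[0] for p in parts]

    def bw(g):
        o = 0
        for p, n in zip(parts, sizes):
            p._accumulate(g[o:o + n])
            o += n

    out._backward = bw
    return out


def hconcat(parts: list[Tensor]) -> Tensor:
    out = Tensor(np.concatenate([p.value for p in parts], axis=1),
                 _parents=tuple(parts))
    sizes = [p.value.shape[1] for p in parts]

    def bw(g):
        o = 0
        for p, n in zip(parts, sizes):
            p._accumulate(g[:, o:o + n])
            o += n

    out._backward = bw
    return out


def relu(x: Tensor) -> Tensor:
    mask = x.value > 0
    out = Tensor(np.where(mask, x.value, 0.0), _parents=(x,))

    def bw(g):
        x._accumulate(g * mask)

    out._backward = bw
    return out


def softplus(x: Tensor) -> Tensor:
    # log(1 + e^x) computed stably; derivative is the logistic sigmoid.
    out = Tensor(np.logaddexp(0.0, x.value), _parents=(x,))

    def bw(g):
        x._accumulate(g * _sigmoid(x.value))

    out._backward = bw
    return out


def _sigmoid(v: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * v))


def exp(x: Tensor) -> Tensor:
    ev = np.exp(x.value)
    out = Tensor(ev, _parents=(x,))

    def bw(g):
        x._accumulate(g * ev)

    out._backward = bw
    return out


def log(x: Tensor) -> Tensor:
    out = Tensor(np.log(x.value), _parents=(x,))

    def bw(g):
        x._accumulate(g / x.value)

    out._backward = bw
    return out


def square(x: Tensor) -> Tensor:
    out = Tensor(x.value ** 2, _parents=(x,))

    def bw(g):
        x._accumulate(2.0 * g * x.value)

    out._backward = bw
    return out


def absolute(x: Tensor) -> Tensor:
    out = Tensor(np.abs(x.value), _parents=(x,))
    sgn = np.sign(x.value)

    def bw(g):
        x._accumulate(g * sgn)

    out._backward = bw
    return out


def total(x: Tensor) -> Tensor:
    out = Tensor(x.value.sum(), _parents=(x,))

    def bw(g):
        x._accumulate(np.full_like(x.value, float(g)))

    out._backward = bw
    return out


def reshape(x: Tensor, shape: tuple[int, ...]) -> Tensor:
    out = Tensor(x.value.reshape(shape), _parents=(x,))
    orig = x.value.shape

    def bw(g):
        x._accumulate(g.reshape(orig))

    out._backward = bw
    return out


def trilinear_scores(B: Tensor, hu: Tensor, hv: Tensor, ht: Tensor) -> Tensor:
    """Batched trilinear form ``s_b = sum_ijk B[i,j,k] hu[b,i] hv[b,j] ht[b,k]``.

    This is the three-fold n-mode contraction used as the hyperedge score,
    evaluated for a batch of triples at once.  All contractions are
    arranged as matrix products so BLAS does the heavy lifting.
    """
    Bv, Hu, Hv, Ht = B.value, hu.value, hv.value, ht.value
    d1, d2, d3 = Bv.shape
    n = Hu.shape[0]
    P = (Hu[:, :, None] * Hv[:, None, :]).reshape(n, d1 * d2)  # pair factors
    Q = P @ Bv.reshape(d1 * d2, d3)                            # (n, d3)
    out = Tensor((Q * Ht).sum(axis=1), _parents=(B, hu, hv, ht))

    def bw(g):
        gt = g[:, None] * Ht                                    # (n, d3)
        B._accumulate((P.T @ gt).reshape(d1, d2, d3))
        # T[b, i, j] = Σ_k B[i,j,k] g_b Ht[b,k] serves both drug gradients
        T = (gt @ Bv.reshape(d1 * d2, d3).T).reshape(n, d1, d2)
        hu._accumulate((T * Hv[:, None, :]).sum(axis=2))
        hv._accumulate((T * Hu[:, :, None]).sum(axis=1))
        ht._accumulate(g[:, None] * Q)

    out._backward = bw
    return out


def rms_normalize_columns(x: Tensor, eps: float = 1e-3) -> Tensor:
    """Divide each column by its root-mean-square (plus a floor).

    Pins the scale of latent-feature columns so that magnitude lives in
    the interaction tensor rather than drifting into the representations,
    which would otherwise defeat any shrinkage prior on the tensor.
    """
    X = x.value
    n = X.shape[0]
    r = np.sqrt((X ** 2).mean(axis=0)) + eps   # (d,)
    out = Tensor(X / r, _parents=(x,))

    def bw(g):
        # y = x/r with r = m + eps, m = sqrt(mean_u x²):
        # dy_uk/dx_vk = δ_uv/r_k - x_uk x_vk / (n m_k r_k²)
        m = np.maximum(r - eps, 1e-300)
        coef = (g * X).sum(axis=0) / (n * m * r ** 2)
        x._accumulate(g / r - X * coef)

    out._backward = bw
    return out


def transpose(x: Tensor, axes: tuple[int, ...]) -> Tensor:
    out = Tensor(np.transpose(x.value, axes), _parents=(x,))
    inv = tuple(np.argsort(axes))

    def bw(g):
        x._accumulate(np.transpose(g, inv))

    out._backward = bw
    return out


class Adam:
    """Adam optimizer over a list of parameter Tensors (maximization is done
    by passing the negated objective's gradients, i.e. minimizing a loss)."""

    def __init__(self, params: list[Tensor], lr: float = 1e-2,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 clip_norm: float | None = 100.0):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.clip_norm = clip_norm
        self.t = 0
        self._m = [np.zeros_like(p.value) for p in params]
        self._v = [np.zeros_like(p.value) for p in params]

    def step(self) -> None:
        self.t += 1
        if self.clip_norm is not None:
            sq = sum(float((p.grad ** 2).sum()) for p in self.params
                     if p.grad is not None)
            scale = self.clip_norm / max(np.sqrt(sq), self.clip_norm)
            if scale < 1.0:
                for p in self.params:
                    if p.grad is not None:
                        p.grad *= scale
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1 ** self.t)
            vhat = v / (1 - self.b2 ** self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
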