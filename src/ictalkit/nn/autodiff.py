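"""A compact reverse-mode automatic differentiation core on numpy arrays.

Implements exactly the operations the package's two classifiers need:
broadcast arithmetic, matrix products, ReLU/sigmoid/tanh, stride-1 2D
convolution (via im2col), 2x2 max pooling, batch normalization, dropout,
slicing/reshaping, and a fused weighted softmax cross-entropy. Gradients flow
to any leaf marked ``requires_grad`` — model parameters during training, the
input tensor during activation maximization.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "no_grad",
    "add", "sub", "mul", "neg", "scale", "matmul",
    "relu", "sigmoid", "tanh",
    "reshape", "slice_", "mean_all", "sum_all",
    "conv2d", "maxpool2x2", "batchnorm", "dropout",
    "softmax", "softmax_cross_entropy",
]


_GRAD_ENABLED = True


class no_grad:
    """Context manager disabling graph construction (inference mode).

    Inside the context every new Tensor is a constant: no parents are
    retained, so intermediate activations are freed as soon as possible.
    """

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev, _GRAD_ENABLED = _GRAD_ENABLED, False
        return self

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev
        return False


class Tensor:
    """A node in the computation graph wrapping a float ndarray."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad=False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=float)
        if parents and not _GRAD_ENABLED:
            requires_grad, parents = False, ()
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self.grad = None
        self._parents = parents if self.requires_grad else ()
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    def backward(self, seed_grad=None):
        """Accumulate gradients of this (scalar or seeded) node into leaves."""
        topo, seen = [], set()

        def visit(node):
            if id(node) in seen or not node.requires_grad:
                return
            seen.add(id(node))
            for p in node._parents:
                visit(p)
            topo.append(node)

        visit(self)
        for node in topo:
            node.grad = None
        self.grad = (
            np.ones_like(self.data) if seed_grad is None else np.asarray(seed_grad)
        )
        for node in reversed(topo):
            if node._backward is None or node.grad is None:
                continue
            grads = node._backward(node.grad)
            for parent, g in zip(node._parents, grads):
                if g is None or not parent.requires_grad:
                    continue
                # rebinding (never in-place) keeps aliased views safe
                parent.grad = g if parent.grad is None else parent.grad + g


def _unbroadcast(grad, shape):
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
    extra = grad.ndim - len(shape)
    if extra:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


# ---------------------------------------------------------------------------
# arithmetic
# ---------------------------------------------------------------------------


def add(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data + b.data
    return Tensor(
        out_data, parents=(a, b),
        backward=lambda g: (_unbroadcast(g, a.shape), _unbroadcast(g, b.shape)),
    )


def sub(a: Tensor, b: Tensor) -> Tensor:
    return Tensor(
        a.data - b.data, parents=(a, b),
        backward=lambda g: (_unbroadcast(g, a.shape), _unbroadcast(-g, b.shape)),
    )


def mul(a: Tensor, b: Tensor) -> Tensor:
    return Tensor(
        a.data * b.data, parents=(a, b),
        backward=lambda g: (
            _unbroadcast(g * b.data, a.shape),
            _unbroadcast(g * a.data, b.shape),
        ),
    )


def neg(a: Tensor) -> Tensor:
    return Tensor(-a.data, parents=(a,), backward=lambda g: (-g,))


def scale(a: Tensor, c: float) -> Tensor:
    return Tensor(a.data * c, parents=(a,), backward=lambda g: (g * c,))


def matmul(a: Tensor, b: Tensor) -> Tensor:
    return Tensor(
        a.data @ b.data, parents=(a, b),
        backward=lambda g: (g @ b.data.T, a.data.T @ g),
    )


# ---------------------------------------------------------------------------
# nonlinearities
# ---------------------------------------------------------------------------


def relu(a: Tensor) -> Tensor:
    mask = a.data > 0
    return Tensor(a.data * mask, parents=(a,), backward=lambda g: (g * mask,))


def sigmoid(a: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-np.clip(a.data, -60, 60)))
    return Tensor(s, parents=(a,), backward=lambda g: (g * s * (1 - s),))


def tanh(a: Tensor) -> Tensor:
    t = np.tanh(a.data)
    return Tensor(t, parents=(a,), backward=lambda g: (g * (1 - t * t),))


# ---------------------------------------------------------------------------
# shape ops
# ---------------------------------------------------------------------------


def reshape(a: Tensor, shape) -> Tensor:
    old = a.shape
    return Tensor(
        a.data.reshape(shape), parents=(a,), backward=lambda g: (g.reshape(old),)
    )


def slice_(a: Tensor, key) -> Tensor:
    def back(g):
        out = np.zeros_like(a.data)
        out[key] = g
        return (out,)

    return Tensor(a.data[key], parents=(a,), backward=back)


def sum_all(a: Tensor) -> Tensor:
    return Tensor(
        a.data.sum(), parents=(a,), backward=lambda g: (g * np.ones_like(a.data),)
    )


def mean_all(a: Tensor) -> Tensor:
    n = a.data.size
    return Tensor(
        a.data.mean(), parents=(a,),
        backward=lambda g: (g * np.ones_like(a.data) / n,),
    )


# ---------------------------------------------------------------------------
# convolution / pooling / normalization
# ---------------------------------------------------------------------------


def _im2col(x: np.ndarray, kh: int, kw: int, pad: int) -> np.ndarray:
    """(N, C, H, W) -> (N, C*kh*kw, OH*OW), stride 1."""
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    v = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    oh, ow = v.shape[2], v.shape[3]
    return (
        np.ascontiguousarray(v.transpose(0, 1, 4, 5, 2, 3)).reshape(
            n, c * kh * kw, oh * ow
        ),
        oh,
        ow,
    )


def _col2im(dcol, xshape, kh, kw, pad, oh, ow):
    n, c, h, w = xshape
    dxp = np.zeros((n, c, h + 2 * pad, w + 2 * pad))
    d6 = dcol.reshape(n, c, kh, kw, oh, ow)
    for i in range(kh):
        for j in range(kw):
            dxp[:, :, i : i + oh, j : j + ow] += d6[:, :, i, j]
    return dxp[:, :, pad : pad + h, pad : pad + w]


def conv2d(x: Tensor, weight: Tensor, bias: Tensor, pad: int = 1) -> Tensor:
    """Stride-1 2D convolution (cross-correlation), ``pad`` on both sides.

    ``x``: (N, C, H, W); ``weight``: (F, C, kh, kw); ``bias``: (F,).
    """
    f, c, kh, kw = weight.shape
    col, oh, ow = _im2col(x.data, kh, kw, pad)
    wm = weight.data.reshape(f, -1)
    out = np.einsum("fk,nkp->nfp", wm, col, optimize=True)
    out = out.reshape(x.shape[0], f, oh, ow) + bias.data[None, :, None, None]
    del col  # recomputed in backward; retaining it would dominate memory

    def back(g):
        gf = g.reshape(g.shape[0], f, oh * ow)
        col_b, _, _ = _im2col(x.data, kh, kw, pad)
        dw = np.einsum("nfp,nkp->fk", gf, col_b, optimize=True).reshape(weight.shape)
        db = gf.sum(axis=(0, 2))
        dcol = np.einsum("fk,nfp->nkp", wm, gf, optimize=True)
        dx = _col2im(dcol, x.shape, kh, kw, pad, oh, ow)
        return (dx, dw, db)

    return Tensor(out, parents=(x, weight, bias), backward=back)


def maxpool2x2(x: Tensor) -> Tensor:
    """2x2 max pooling, stride 2; odd trailing rows/columns are dropped."""
    n, c, h, w = x.shape
    h2, w2 = h // 2, w // 2
    v = x.data[:, :, : 2 * h2, : 2 * w2].reshape(n, c, h2, 2, w2, 2)
    patches = v.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h2, w2, 4)
    arg = patches.argmax(axis=-1)
    out = np.take_along_axis(patches, arg[..., None], axis=-1)[..., 0]

    def back(g):
        dpatch = np.zeros_like(patches)
        np.put_along_axis(dpatch, arg[..., None], g[..., None], axis=-1)
        dx = np.zeros_like(x.data)
        dx[:, :, : 2 * h2, : 2 * w2] = (
            dpatch.reshape(n, c, h2, w2, 2, 2)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(n, c, 2 * h2, 2 * w2)
        )
        return (dx,)

    return Tensor(out, parents=(x,), backward=back)


def batchnorm(
    x: Tensor,
    gamma: Tensor,
    beta: Tensor,
    running: dict,
    train: bool,
    momentum: float = 0.1,
    eps: float = 1e-5,
) -> Tensor:
    """Per-channel batch normalization for (N, C, H, W) input.

    ``running`` carries ``mean``/``var`` arrays updated in training mode and
    used verbatim in evaluation mode.
    """
    if train:
        mu = x.data.mean(axis=(0, 2, 3))
        var = x.data.var(axis=(0, 2, 3))
        running["mean"] = (1 - momentum) * running["mean"] + momentum * mu
        running["var"] = (1 - momentum) * running["var"] + momentum * var
    else:
        mu, var = running["mean"], running["var"]
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu[None, :, None, None]) * inv[None, :, None, None]
    out = gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None]

    def back(g):
        dgamma = (g * xhat).sum(axis=(0, 2, 3))
        dbeta = g.sum(axis=(0, 2, 3))
        dxhat = g * gamma.data[None, :, None, None]
        if train:
            m = g.shape[0] * g.shape[2] * g.shape[3]
            s1 = dxhat.sum(axis=(0, 2, 3), keepdims=True)
            s2 = (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
            dx = (inv[None, :, None, None] / m) * (m * dxhat - s1 - xhat * s2)
        else:
            dx = dxhat * inv[None, :, None, None]
        return (dx, dgamma, dbeta)

    return Tensor(out, parents=(x, gamma, beta), backward=back)


def dropout(x: Tensor, rate: float, rng: np.random.Generator, train: bool) -> Tensor:
    if not train or rate <= 0:
        return x
    keep = 1.0 - rate
    mask = (rng.random(x.shape) < keep) / keep
    return Tensor(x.data * mask, parents=(x,), backward=lambda g: (g * mask,))


# ---------------------------------------------------------------------------
# output layer
# ---------------------------------------------------------------------------


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(
    logits: Tensor, y_index: np.ndarray, sample_weights: np.ndarray
) -> Tensor:
    """Weighted mean cross-entropy; returns a scalar Tensor."""
    p = softmax(logits.data)
    n = logits.shape[0]
    w = np.asarray(sample_weights, dtype=float)
    wsum = max(w.sum(), 1e-12)
    nll = -np.log(np.maximum(p[np.arange(n), y_index], 1e-12))
    loss = float((w * nll).sum() / wsum)

    def back(g):
        d = p.copy()
        d[np.arange(n), y_index] -= 1.0
        return (g * d * (w / wsum)[:, None],)

    return Tensor(loss, parents=(logits,), backward=back)
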