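"""Minimal reverse-mode automatic differentiation on numpy arrays.

The segmentation model in this package is a hierarchical vision transformer
trained end to end on CPU.  Rather than depending on a large deep-learning
framework, the forward/backward machinery is a small tape-based engine: a
:class:`Tensor` wraps an ``ndarray``, every primitive records a closure that
propagates the upstream gradient to its parents, and :meth:`Tensor.backward`
walks the tape in reverse topological order.

Only the primitives the architecture actually needs are implemented (matmul,
broadcasting add/mul, softmax, layer norm, GELU, depthwise 3x3 convolution,
patch extraction, bilinear resize, table gather, concat, reductions).  Each
backward rule is exercised against central finite differences in the test
suite.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np
from scipy.special import erf

__all__ = [
    "Tensor",
    "as_tensor",
    "add",
    "sub",
    "mul",
    "matmul",
    "reshape",
    "transpose",
    "tsum",
    "tmean",
    "power",
    "exp",
    "log",
    "clip",
    "gelu",
    "softmax",
    "layer_norm",
    "gather_rows",
    "depthwise_conv3x3",
    "extract_patches",
    "bilinear_resize",
    "concat",
    "global_norm",
    "clip_by_global_norm",
    "Adam",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` by summing over broadcast axes."""
    if grad.shape == shape:
        return grad
    # leading axes added by broadcasting
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # axes that were size 1 in the original
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """A numpy array plus an optional gradient and backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        parents: Sequence["Tensor"] = (),
        backward: Callable[[np.ndarray], None] | None = None,
    ):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._backward = backward
        self._parents = tuple(parents)

    # -- convenience -------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # operators
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __sub__(self, other):
        return sub(self, other)

    def __rsub__(self, other):
        return sub(other, self)

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __neg__(self):
        return mul(self, -1.0)

    def __matmul__(self, other):
        return matmul(self, other)

    def reshape(self, *shape):
        return reshape(self, shape if len(shape) > 1 else shape[0])

    def transpose(self, *axes):
        return transpose(self, axes if len(axes) > 1 else axes[0])

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis=axis, keepdims=keepdims)

    # -- autodiff ----------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this tensor through the recorded tape."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS; deep graphs overflow recursion limits
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
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def accumulate(self, grad: np.ndarray) -> None:
        # never mutate in place: the first accumulation may alias a child's
        # gradient buffer, so the second allocates a fresh array instead
        if self.grad is None:
            self.grad = grad
        else:
            self.grad = self.grad + grad


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# ---------------------------------------------------------------------------
# primitives
# ---------------------------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data + b.data

    def bwd(g):
        if a.requires_grad:
            a.accumulate(_unbroadcast(g, a.shape))
        if b.requires_grad:
            b.accumulate(_unbroadcast(g, b.shape))

    return Tensor(out_data, parents=(a, b), backward=bwd)


def sub(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data - b.data

    def bwd(g):
        if a.requires_grad:
            a.accumulate(_unbroadcast(g, a.shape))
        if b.requires_grad:
            b.accumulate(_unbroadcast(-g, b.shape))

    return Tensor(out_data, parents=(a, b), backward=bwd)


def mul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data * b.data

    def bwd(g):
        if a.requires_grad:
            a.accumulate(_unbroadcast(g * b.data, a.shape))
        if b.requires_grad:
            b.accumulate(_unbroadcast(g * a.data, b.shape))

    return Tensor(out_data, parents=(a, b), backward=bwd)


def matmul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data @ b.data

    def bwd(g):
        if a.requires_grad:
            ga = g @ np.swapaxes(b.data, -1, -2)
            a.accumulate(_unbroadcast(ga, a.shape))
        if b.requires_grad:
            gb = np.swapaxes(a.data, -1, -2) @ g
            b.accumulate(_unbroadcast(gb, b.shape))

    return Tensor(out_data, parents=(a, b), backward=bwd)


def reshape(a, shape) -> Tensor:
    a = as_tensor(a)
    out_data = a.data.reshape(shape)

    def bwd(g):
        if a.requires_grad:
            a.accumulate(g.reshape(a.shape))

    return Tensor(out_data, parents=(a,), backward=bwd)


def transpose(a, axes) -> Tensor:
    a = as_tensor(a)
    axes = tuple(axes)
    out_data = a.data.transpose(axes)
    inv = np.argsort(axes)

    def bwd(g):
        if a.requires_grad:
            a.accumulate(g.transpose(inv))

    return Tensor(out_data, parents=(a,), backward=bwd)


def tsum(a, axis=None, keepdims=False) -> Tensor:
    a = as_tensor(a)
    out_data = a.data.sum(axis=axis, keepdims=keepdims)

    def bwd(g):
        if not a.requires_grad:
            return
        if axis is None:
            a.accumulate(np.broadcast_to(g, a.shape).copy())
            return
        if not keepdims:
            g = np.expand_dims(g, axis)
        a.accumulate(np.broadcast_to(g, a.shape).copy())

    return Tensor(out_data, parents=(a,), backward=bwd)


def tmean(a, axis=None, keepdims=False) -> Tensor:
    a = as_tensor(a)
    if axis is None:
        count = a.data.size
    else:
        ax = axis if isinstance(axis, tuple) else (axis,)
        count = int(np.prod([a.shape[i] for i in ax]))
    return mul(tsum(a, axis=axis, keepdims=keepdims), 1.0 / count)


def power(a, p: float) -> Tensor:
    a = as_tensor(a)
    out_data = a.data ** p

    def bwd(g):
        if a.requires_grad:
            a.accumulate(g * p * a.data ** (p - 1))

    return Tensor(out_data, parents=(a,), backward=bwd)


def exp(a) -> Tensor:
    a = as_tensor(a)
    out_data = np.exp(a.data)

    def bwd(g):
        if a.requires_grad:
            a.accumulate(g * out_data)

    return Tensor(out_data, parents=(a,), backward=bwd)


def log(a) -> Tensor:
    a = as_tensor(a)
    out_data = np.log(a.data)

    def bwd(g):
        if a.requires_grad:
            a.accumulate(g / a.data)

    return Tensor(out_data, parents=(a,), backward=bwd)


def clip(a, lo: float, hi: float) -> Tensor:
    """Clip values; gradient passes through inside [lo, hi], zero outside."""
    a = as_tensor(a)
    out_data = np.clip(a.data, lo, hi)
    mask = (a.data >= lo) & (a.data <= hi)

    def bwd(g):
        if a.requires_grad:
            a.accumulate(g * mask)

    return Tensor(out_data, parents=(a,), backward=bwd)


_SQRT2 = np.sqrt(2.0)
_INV_SQRT_2PI = 1.0 / np.sqrt(2.0 * np.pi)


def gelu(a) -> Tensor:
    """Exact (erf-based) Gaussian error linear unit."""
    a = as_tensor(a)
    cdf = 0.5 * (1.0 + erf(a.data / _SQRT2))
    out_data = a.data * cdf

    def bwd(g):
        if a.requires_grad:
            pdf = _INV_SQRT_2PI * np.exp(-0.5 * a.data**2)
            a.accumulate(g * (cdf + a.data * pdf))

    return Tensor(out_data, parents=(a,), backward=bwd)


def softmax(a, axis: int = -1) -> Tensor:
    a = as_tensor(a)
    shifted = a.data - a.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    out_data = e / e.sum(axis=axis, keepdims=True)

    def bwd(g):
        if a.requires_grad:
            dot = (g * out_data).sum(axis=axis, keepdims=True)
            a.accumulate(out_data * (g - dot))

    return Tensor(out_data, parents=(a,), backward=bwd)


def layer_norm(x, gamma, beta, eps: float = 1e-6) -> Tensor:
    """Normalize over the last axis, then scale/shift: gamma*(x-mu)/sqrt(var+eps)+beta."""
    x, gamma, beta = as_tensor(x), as_tensor(gamma), as_tensor(beta)
    mu = x.data.mean(axis=-1, keepdims=True)
    xc = x.data - mu
    var = (xc**2).mean(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv
    out_data = gamma.data * xhat + beta.data
    n = x.shape[-1]

    def bwd(g):
        if gamma.requires_grad:
            gamma.accumulate(_unbroadcast(g * xhat, gamma.shape))
        if beta.requires_grad:
            beta.accumulate(_unbroadcast(g, beta.shape))
        if x.requires_grad:
            gx = g * gamma.data
            # standard layer-norm backward over the last axis
            dx = (
                gx - gx.mean(axis=-1, keepdims=True)
                - xhat * (gx * xhat).mean(axis=-1, keepdims=True)
            ) * inv
            x.accumulate(dx)

    return Tensor(out_data, parents=(x, gamma, beta), backward=bwd)


def gather_rows(table, idx: np.ndarray) -> Tensor:
    """``table[idx]`` for a 2-D table and integer index array; scatter-add backward."""
    table = as_tensor(table)
    idx = np.asarray(idx)
    out_data = table.data[idx]

    def bwd(g):
        if table.requires_grad:
            gt = np.zeros_like(table.data)
            np.add.at(gt, idx.ravel(), g.reshape(-1, table.shape[-1]))
            table.accumulate(gt)

    return Tensor(out_data, parents=(table,), backward=bwd)


def depthwise_conv3x3(x, kernel) -> Tensor:
    """Per-channel 3x3 cross-correlation, same zero padding, stride 1.

    ``x``: (B, H, W, C); ``kernel``: (3, 3, C).  No cross-channel mixing.
    """
    x, kernel = as_tensor(x), as_tensor(kernel)
    if kernel.shape[:2] != (3, 3):
        raise ValueError(f"depthwise kernel must be 3x3, got {kernel.shape[:2]}")
    B, H, W, C = x.shape
    if kernel.shape[2] != C:
        raise ValueError(f"kernel channels {kernel.shape[2]} != input channels {C}")
    xp = np.pad(x.data, ((0, 0), (1, 1), (1, 1), (0, 0)))
    out_data = np.zeros_like(x.data)
    for k in range(3):
        for l in range(3):
            out_data += xp[:, k : k + H, l : l + W, :] * kernel.data[k, l]

    def bwd(g):
        if kernel.requires_grad:
            gk = np.empty_like(kernel.data)
            for k in range(3):
                for l in range(3):
                    gk[k, l] = (xp[:, k : k + H, l : l + W, :] * g).sum(axis=(0, 1, 2))
            kernel.accumulate(gk)
        if x.requires_grad:
            gp = np.zeros_like(xp)
            for k in range(3):
                for l in range(3):
                    gp[:, k : k + H, l : l + W, :] += g * kernel.data[k, l]
            x.accumulate(gp[:, 1 : 1 + H, 1 : 1 + W, :])

    return Tensor(out_data, parents=(x, kernel), backward=bwd)


def extract_patches(x, kernel: int, stride: int, padding: int = 0) -> Tensor:
    """im2col: (B, H, W, C) -> (B, N, kernel*kernel*C) row-major over the output grid."""
    x = as_tensor(x)
    B, H, W, C = x.shape
    Hp, Wp = H + 2 * padding, W + 2 * padding
    if (Hp - kernel) % stride or (Wp - kernel) % stride:
        raise ValueError(
            f"image {H}x{W} (pad {padding}) not divisible by kernel {kernel} stride {stride}"
        )
    Ho, Wo = (Hp - kernel) // stride + 1, (Wp - kernel) // stride + 1
    xp = np.pad(x.data, ((0, 0), (padding, padding), (padding, padding), (0, 0)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (kernel, kernel), axis=(1, 2))
    # win: (B, Hp-k+1, Wp-k+1, C, k, k) -> subsample by stride, reorder to (k,k,C)
    win = win[:, ::stride, ::stride]
    win = win.transpose(0, 1, 2, 4, 5, 3)
    out_data = win.reshape(B, Ho * Wo, kernel * kernel * C).copy()

    def bwd(g):
        if not x.requires_grad:
            return
        g6 = g.reshape(B, Ho, Wo, kernel, kernel, C)
        gp = np.zeros((B, Hp, Wp, C))
        for k in range(kernel):
            for l in range(kernel):
                gp[:, k : k + Ho * stride : stride, l : l + Wo * stride : stride, :] += g6[
                    :, :, :, k, l, :
                ]
        if padding:
            gp = gp[:, padding:-padding, padding:-padding, :]
        x.accumulate(gp)

    out = Tensor(out_data, parents=(x,), backward=bwd)
    return out


def _bilinear_matrix(n_out: int, n_in: int) -> np.ndarray:
    """Interpolation matrix (n_out, n_in) with half-pixel (align_corners=False) centers."""
    A = np.zeros((n_out, n_in))
    if n_in == 1:
        A[:, 0] = 1.0
        return A
    src = (np.arange(n_out) + 0.5) * n_in / n_out - 0.5
    src = np.clip(src, 0.0, n_in - 1.0)
    lo = np.floor(src).astype(int)
    hi = np.minimum(lo + 1, n_in - 1)
    w = src - lo
    A[np.arange(n_out), lo] += 1.0 - w
    A[np.arange(n_out), hi] += w
    return A


def bilinear_resize(x, out_h: int, out_w: int) -> Tensor:
    """Bilinear resample of (B, H, W, C) to (B, out_h, out_w, C)."""
    x = as_tensor(x)
    B, H, W, C = x.shape
    Ah = _bilinear_matrix(out_h, H)
    Aw = _bilinear_matrix(out_w, W)
    out_data = np.einsum("ph,bhwc->bpwc", Ah, x.data)
    out_data = np.einsum("qw,bpwc->bpqc", Aw, out_data)

    def bwd(g):
        if x.requires_grad:
            gx = np.einsum("qw,bpqc->bpwc", Aw, g)
            gx = np.einsum("ph,bpwc->bhwc", Ah, gx)
            x.accumulate(gx)

    return Tensor(out_data, parents=(x,), backward=bwd)


def concat(tensors: Sequence, axis: int = -1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t.accumulate(g[tuple(sl)])

    return Tensor(out_data, parents=tuple(tensors), backward=bwd)


# ---------------------------------------------------------------------------
# optimisation helpers
# ---------------------------------------------------------------------------

def global_norm(grads: Iterable[np.ndarray]) -> float:
    return float(np.sqrt(sum(float((g**2).sum()) for g in grads)))


def clip_by_global_norm(grads: list[np.ndarray], clipnorm: float) -> list[np.ndarray]:
    """Scale the gradient list so its global L2 norm is at most ``clipnorm``."""
    norm = global_norm(grads)
    if norm > clipnorm > 0:
        scale = clipnorm / norm
        return [g * scale for g in grads]
    return grads


class Adam:
    """Adam optimizer over a dict of named parameter Tensors."""

    def __init__(
        self,
        params: dict[str, Tensor],
        lr: float = 1e-4,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-7,
        clipnorm: float | None = 1.0,
    ):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.clipnorm = clipnorm
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def step(self) -> None:
        self.t += 1
        keys = list(self.params)
        grads = [
            self.params[k].grad
            if self.params[k].grad is not None
            else np.zeros_like(self.params[k].data)
            for k in keys
        ]
        if self.clipnorm is not None:
            grads = clip_by_global_norm(grads, self.clipnorm)
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for k, g in zip(keys, grads):
            self.m[k] = self.beta1 * self.m[k] + (1.0 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1.0 - self.beta2) * g**2
            mhat = self.m[k] / b1t
            vhat = self.v[k] / b2t
            self.params[k].data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None
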