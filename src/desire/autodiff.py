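"""Minimal reverse-mode automatic differentiation on numpy arrays.

A tape-based engine purpose-built for the dose-prediction network: it covers
exactly the operations the architecture and its losses need — 3-D convolution
(stride 1/2, "same" padding), instance normalization, ReLU/sigmoid/log/abs,
trilinear upsampling, channel dropout, concatenation, reductions and
elementwise arithmetic with broadcasting.  Convolutions are evaluated as one
matrix product per kernel offset (k^3 GEMMs of shape (Cout, Cin) x (Cin, N)),
which keeps memory flat and exploits BLAS on a single CPU core.

Gradients are accumulated by topological traversal from the loss; every op's
backward rule is verified against finite differences in the test suite.
"""

from __future__ import annotations

from itertools import product
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np
from scipy.special import expit as _expit

from .grids import _axis_resize_matrix

__all__ = ["Tensor", "concat", "conv3d", "instance_norm", "upsample_trilinear",
           "channel_dropout", "global_avg_pool"]


def _unbroadcast(grad: np.ndarray, shape: Tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverses numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """An n-d array node on the autodiff tape."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    # make `ndarray <op> Tensor` dispatch to the Tensor's reflected operator
    # instead of silently collapsing the graph to a plain array
    __array_ufunc__ = None

    def __init__(self, data, requires_grad: bool = False,
                 parents: Tuple["Tensor", ...] = (),
                 backward: Optional[Callable[[np.ndarray], None]] = None):
        self.data = np.asarray(data, dtype=np.float64) if not isinstance(data, np.ndarray) \
            else data
        self.grad: Optional[np.ndarray] = None
        self.requires_grad = requires_grad
        self._parents = parents
        self._backward = backward

    # -- array-like conveniences -------------------------------------------
    @property
    def shape(self) -> Tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def numpy(self) -> np.ndarray:
        return self.data

    def __array__(self, dtype=None, copy=None):
        return np.asarray(self.data, dtype=dtype)

    def item(self) -> float:
        return float(self.data)

    def __float__(self) -> float:
        return float(self.data)

    def __repr__(self) -> str:
        return f"Tensor(shape={self.shape}, grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- graph machinery ----------------------------------------------------
    def backward(self, grad: Optional[np.ndarray] = None) -> None:
        """Backpropagate from this node (defaults to d(self)/d(self) = 1)."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without an explicit gradient "
                                 "requires a scalar output")
            grad = np.ones_like(self.data)
        topo: List[Tensor] = []
        seen = set()

        def visit(node: "Tensor") -> None:
            stack = [(node, iter(node._parents))]
            seen.add(id(node))
            while stack:
                cur, it = stack[-1]
                advanced = False
                for p in it:
                    if id(p) not in seen and (p.requires_grad or p._parents):
                        seen.add(id(p))
                        stack.append((p, iter(p._parents)))
                        advanced = True
                        break
                if not advanced:
                    topo.append(cur)
                    stack.pop()

        visit(self)
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accumulate(self, grad: np.ndarray) -> None:
        # copy on first write: incoming gradients may alias a child's buffer
        if self.grad is None:
            self.grad = np.array(grad, copy=True)
        else:
            self.grad += grad

    def zero_grad(self) -> None:
        self.grad = None

    # -- elementwise arithmetic ---------------------------------------------
    def _wrap(self, other) -> "Tensor":
        if isinstance(other, Tensor):
            return other
        arr = np.asarray(other)
        # python scalars / 0-d follow this tensor's dtype so float32 graphs
        # are not silently promoted to float64
        if arr.ndim == 0:
            arr = arr.astype(self.data.dtype)
        return Tensor(arr)

    def _binary(self, other, fwd, bwd_self, bwd_other) -> "Tensor":
        other = self._wrap(other)
        out_data = fwd(self.data, other.data)
        track = self.requires_grad or other.requires_grad or self._parents or other._parents

        def backward(g: np.ndarray) -> None:
            self._accumulate(_unbroadcast(bwd_self(g, self.data, other.data), self.shape))
            other._accumulate(_unbroadcast(bwd_other(g, self.data, other.data), other.shape))

        return Tensor(out_data, parents=(self, other) if track else (),
                      backward=backward if track else None)

    def __add__(self, other):
        return self._binary(other, lambda a, b: a + b,
                            lambda g, a, b: g, lambda g, a, b: g)

    __radd__ = __add__

    def __sub__(self, other):
        return self._binary(other, lambda a, b: a - b,
                            lambda g, a, b: g, lambda g, a, b: -g)

    def __rsub__(self, other):
        return self._wrap(other).__sub__(self)

    def __mul__(self, other):
        return self._binary(other, lambda a, b: a * b,
                            lambda g, a, b: g * b, lambda g, a, b: g * a)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self._binary(other, lambda a, b: a / b,
                            lambda g, a, b: g / b,
                            lambda g, a, b: -g * a / (b * b))

    def __rtruediv__(self, other):
        return self._wrap(other).__truediv__(self)

    def __neg__(self):
        return self * -1.0

    def __pow__(self, exponent: float):
        e = float(exponent)
        out_data = self.data ** e

        def backward(g: np.ndarray) -> None:
            self._accumulate(g * e * self.data ** (e - 1.0))

        return Tensor(out_data, parents=(self,), backward=backward)

    # -- elementwise nonlinearities -----------------------------------------
    def relu(self) -> "Tensor":
        out_data = np.maximum(self.data, 0.0)

        def backward(g: np.ndarray) -> None:
            self._accumulate(g * (self.data > 0))

        return Tensor(out_data, parents=(self,), backward=backward)

    def sigmoid(self) -> "Tensor":
        out_data = _expit(self.data)

        def backward(g: np.ndarray) -> None:
            self._accumulate(g * out_data * (1.0 - out_data))

        return Tensor(out_data, parents=(self,), backward=backward)

    def exp(self) -> "Tensor":
        out_data = np.exp(self.data)

        def backward(g: np.ndarray) -> None:
            self._accumulate(g * out_data)

        return Tensor(out_data, parents=(self,), backward=backward)

    def log(self) -> "Tensor":
        out_data = np.log(self.data)

        def backward(g: np.ndarray) -> None:
            self._accumulate(g / self.data)

        return Tensor(out_data, parents=(self,), backward=backward)

    def abs(self) -> "Tensor":
        out_data = np.abs(self.data)

        def backward(g: np.ndarray) -> None:
            self._accumulate(g * np.sign(self.data))

        return Tensor(out_data, parents=(self,), backward=backward)

    def clip(self, lo: float, hi: float) -> "Tensor":
        out_data = np.clip(self.data, lo, hi)

        def backward(g: np.ndarray) -> None:
            self._accumulate(g * ((self.data >= lo) & (self.data <= hi)))

        return Tensor(out_data, parents=(self,), backward=backward)

    # -- reductions ----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g: np.ndarray) -> None:
            gg = np.asarray(g)
            if axis is not None and not keepdims:
                gg = np.expand_dims(gg, axis)
            self._accumulate(np.broadcast_to(gg, self.shape).copy())

        return Tensor(out_data, parents=(self,), backward=backward)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        if axis is None:
            n = self.data.size
        else:
            axes = (axis,) if np.isscalar(axis) else tuple(axis)
            n = int(np.prod([self.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape) -> "Tensor":
        out_data = self.data.reshape(*shape)
        orig = self.shape

        def backward(g: np.ndarray) -> None:
            self._accumulate(g.reshape(orig))

        return Tensor(out_data, parents=(self,), backward=backward)


# ---------------------------------------------------------------------------
# structural / network operations
# ---------------------------------------------------------------------------

def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = list(tensors)
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g: np.ndarray) -> None:
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            idx = [slice(None)] * g.ndim
            idx[axis] = slice(lo, hi)
            t._accumulate(g[tuple(idx)])

    return Tensor(out_data, parents=tuple(tensors), backward=backward)


def conv3d(x: Tensor, weight: Tensor, bias: Optional[Tensor] = None,
           stride: int = 1) -> Tensor:
    """3-D convolution, NCDHW without the batch axis: x is (Cin, Z, Y, X).

    Kernel is cubic (k, from weight shape), padding = k // 2 ("same" for
    stride 1, exact halving for stride 2 on even inputs).
    """
    c_out, c_in, k, _, _ = weight.shape
    if x.shape[0] != c_in:
        raise ValueError(f"conv3d channel mismatch: input {x.shape[0]} vs weight {c_in}")
    p = k // 2
    s = int(stride)
    zi, yi, xi = x.shape[1:]
    zo, yo, xo = ((zi + 2 * p - k) // s + 1, (yi + 2 * p - k) // s + 1,
                  (xi + 2 * p - k) // s + 1)
    n = zo * yo * xo
    kk = k * k * k
    w2 = weight.data.reshape(c_out, c_in * kk)

    if k == 1 and s == 1:
        # pointwise convolution: a plain channel-mixing GEMM, no gather
        xflat = x.data.reshape(c_in, n)
        out_data = (w2 @ xflat).reshape(c_out, zo, yo, xo)
        if bias is not None:
            out_data = out_data + bias.data.reshape(c_out, 1, 1, 1)

        def backward_1x1(g: np.ndarray) -> None:
            g2 = g.reshape(c_out, n)
            weight._accumulate((g2 @ xflat.T).reshape(weight.shape))
            if bias is not None:
                bias._accumulate(g.sum(axis=(1, 2, 3)))
            x._accumulate((w2.T @ g2).reshape(x.shape))

        parents = (x, weight) + ((bias,) if bias is not None else ())
        return Tensor(out_data, parents=parents, backward=backward_1x1)

    w3 = weight.data.reshape(c_out, c_in, kk)
    xpad = np.pad(x.data, ((0, 0), (p, p), (p, p), (p, p))) if p else x.data
    out2 = np.zeros((c_out, n), dtype=x.data.dtype)
    patches = []
    for i, (dz, dy, dx) in enumerate(product(range(k), repeat=3)):
        patch = np.ascontiguousarray(
            xpad[:, dz:dz + s * zo:s, dy:dy + s * yo:s, dx:dx + s * xo:s]
        ).reshape(c_in, n)
        patches.append(patch)
        out2 += w3[:, :, i] @ patch
    out_data = out2.reshape(c_out, zo, yo, xo)
    if bias is not None:
        out_data = out_data + bias.data.reshape(c_out, 1, 1, 1)

    def backward(g: np.ndarray) -> None:
        g2 = g.reshape(c_out, n)
        dw = np.empty_like(weight.data).reshape(c_out, c_in, kk)
        dxpad = np.zeros_like(xpad)
        for i, (dz, dy, dx) in enumerate(product(range(k), repeat=3)):
            dw[:, :, i] = g2 @ patches[i].T
            contrib = (w3[:, :, i].T @ g2).reshape(c_in, zo, yo, xo)
            dxpad[:, dz:dz + s * zo:s, dy:dy + s * yo:s, dx:dx + s * xo:s] += contrib
        weight._accumulate(dw.reshape(weight.shape))
        if bias is not None:
            bias._accumulate(g.sum(axis=(1, 2, 3)))
        x._accumulate(dxpad[:, p:p + zi, p:p + yi, p:p + xi] if p else dxpad)

    parents = (x, weight) + ((bias,) if bias is not None else ())
    return Tensor(out_data, parents=parents, backward=backward)


def instance_norm(x: Tensor, gain: Tensor, bias: Tensor, eps: float = 1e-5) -> Tensor:
    """Per-channel normalization over the spatial axes, with affine parameters."""
    axes = (1, 2, 3)
    n = int(np.prod(x.shape[1:]))
    mu = x.data.mean(axis=axes, keepdims=True)
    var = x.data.var(axis=axes, keepdims=True)
    ivar = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * ivar
    g4 = gain.data.reshape(-1, 1, 1, 1)
    b4 = bias.data.reshape(-1, 1, 1, 1)
    out_data = g4 * xhat + b4

    def backward(g: np.ndarray) -> None:
        gain._accumulate((g * xhat).sum(axis=axes))
        bias._accumulate(g.sum(axis=axes))
        dxhat = g * g4
        # standard normalization backward, fused
        dx = ivar / n * (n * dxhat
                         - dxhat.sum(axis=axes, keepdims=True)
                         - xhat * (dxhat * xhat).sum(axis=axes, keepdims=True))
        x._accumulate(dx)

    return Tensor(out_data, parents=(x, gain, bias), backward=backward)


def _apply_axis_matrices(data: np.ndarray, mats: Sequence[np.ndarray]) -> np.ndarray:
    out = data
    for ax, mat in enumerate(mats):
        axis = ax + (out.ndim - 3)
        out = np.moveaxis(np.tensordot(mat, np.moveaxis(out, axis, 0), axes=(1, 0)),
                          0, axis)
    return out


def upsample_trilinear(x: Tensor, target_shape: Sequence[int]) -> Tensor:
    """Trilinear resize of (C, Z, Y, X) features (half-voxel convention)."""
    target_shape = tuple(int(t) for t in target_shape)
    mats = [_axis_resize_matrix(n_in, n_out).astype(x.data.dtype)
            for n_in, n_out in zip(x.shape[1:], target_shape)]
    out_data = _apply_axis_matrices(x.data, mats)

    def backward(g: np.ndarray) -> None:
        x._accumulate(_apply_axis_matrices(g, [m.T for m in mats]))

    return Tensor(out_data, parents=(x,), backward=backward)


def channel_dropout(x: Tensor, rate: float, rng: np.random.Generator) -> Tensor:
    """Spatial (channel-wise) dropout with inverse scaling; training-time only."""
    if not 0.0 < rate < 1.0:
        raise ValueError(f"dropout rate must be in (0, 1), got {rate}")
    keep = (rng.random(x.shape[0]) >= rate).astype(x.data.dtype)
    scale = keep.reshape(-1, 1, 1, 1) / (1.0 - rate)
    out_data = x.data * scale

    def backward(g: np.ndarray) -> None:
        x._accumulate(g * scale)

    return Tensor(out_data, parents=(x,), backward=backward)


def global_avg_pool(x: Tensor) -> Tensor:
    """Mean over the spatial axes -> (C, 1, 1, 1)."""
    return x.mean(axis=(1, 2, 3), keepdims=True)
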