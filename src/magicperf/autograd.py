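"""Minimal reverse-mode automatic differentiation on numpy arrays.

This engine provides exactly the primitives the perfusion-synthesis
networks need: strided/padded 2-D convolution and transposed convolution
(im2col / col2im based), parameter-free instance normalization, the usual
pointwise nonlinearities, channel concatenation, and the reductions used
by the loss terms.  Gradients are accumulated by a topological backward
sweep over a dynamically recorded tape.

Arrays are float32 by default for model weights and float64 for loss
arithmetic tests; both work.  min/max reductions use tie-splitting
subgradients (gradient divided equally among extremal elements).
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "conv2d", "conv_transpose2d", "instance_norm"]


class Tensor:
    """A numpy array plus gradient bookkeeping."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple = ()

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def as_tensor(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @property
    def shape(self):
        return self.data.shape

    @property
    def size(self):
        return self.data.size

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- graph machinery ------------------------------------------------------
    def _accumulate(self, g) -> None:
        if self.grad is None:
            self.grad = np.array(g, dtype=self.data.dtype, copy=True)
        else:
            self.grad += g

    def backward(self, grad=None) -> None:
        """Backpropagate from this tensor (scalar unless grad is given)."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
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
                if id(p) not in seen:
                    stack.append((p, False))
        self._accumulate(grad)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        return _binary(self, other, np.add, lambda g, a, b: (g, g))

    __radd__ = __add__

    def __sub__(self, other):
        return _binary(self, other, np.subtract, lambda g, a, b: (g, -g))

    def __rsub__(self, other):
        return Tensor.as_tensor(other) - self

    def __mul__(self, other):
        return _binary(self, other, np.multiply,
                       lambda g, a, b: (g * b.data, g * a.data))

    __rmul__ = __mul__

    def __truediv__(self, other):
        return _binary(self, other, np.divide,
                       lambda g, a, b: (g / b.data,
                                        -g * a.data / (b.data * b.data)))

    def __neg__(self):
        return self * (-1.0)

    def square(self):
        return self * self

    def abs(self):
        out = _node(np.abs(self.data), (self,))
        if out._parents:
            sign = np.sign(self.data)
            out._backward = lambda g: self._accumulate(g * sign)
        return out

    def log(self):
        out = _node(np.log(self.data), (self,))
        if out._parents:
            out._backward = lambda g: self._accumulate(g / self.data)
        return out

    def clip(self, lo: float, hi: float):
        """Clip values; gradient is zero outside [lo, hi] (hard clip)."""
        out = _node(np.clip(self.data, lo, hi), (self,))
        if out._parents:
            inside = ((self.data >= lo) & (self.data <= hi)).astype(self.data.dtype)
            out._backward = lambda g: self._accumulate(g * inside)
        return out

    # -- activations ----------------------------------------------------------
    def relu(self):
        out = _node(np.maximum(self.data, 0), (self,))
        if out._parents:
            mask = (self.data > 0).astype(self.data.dtype)
            out._backward = lambda g: self._accumulate(g * mask)
        return out

    def leaky_relu(self, slope: float = 0.2):
        out = _node(np.where(self.data > 0, self.data, slope * self.data), (self,))
        if out._parents:
            grad_mask = np.where(self.data > 0, 1.0, slope).astype(self.data.dtype)
            out._backward = lambda g: self._accumulate(g * grad_mask)
        return out

    def tanh(self):
        y = np.tanh(self.data)
        out = _node(y, (self,))
        if out._parents:
            out._backward = lambda g: self._accumulate(g * (1.0 - y * y))
        return out

    def sigmoid(self):
        y = 1.0 / (1.0 + np.exp(-self.data))
        out = _node(y, (self,))
        if out._parents:
            out._backward = lambda g: self._accumulate(g * y * (1.0 - y))
        return out

    # -- reductions -----------------------------------------------------------
    def mean(self):
        n = self.data.size
        out = _node(np.asarray(self.data.mean()), (self,))
        if out._parents:
            out._backward = lambda g: self._accumulate(
                np.broadcast_to(g / n, self.data.shape))
        return out

    def sum(self):
        out = _node(np.asarray(self.data.sum()), (self,))
        if out._parents:
            out._backward = lambda g: self._accumulate(
                np.broadcast_to(g, self.data.shape))
        return out

    def amin_spatial(self):
        """Per-(sample, channel) minimum over the spatial axes, keepdims."""
        return _extremum(self, np.min)

    def amax_spatial(self):
        return _extremum(self, np.max)


def _node(data, parents) -> Tensor:
    out = Tensor(data)
    parents = tuple(p for p in parents if p.requires_grad or p._parents)
    if parents:
        out._parents = parents
        out.requires_grad = True
    return out


def _unbroadcast(g, shape):
    """Reduce gradient g to the given (broadcast-source) shape."""
    if g.shape == shape:
        return g
    extra = g.ndim - len(shape)
    if extra > 0:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g


def _binary(a, b, fwd, bwd) -> Tensor:
    a = Tensor.as_tensor(a)
    b = Tensor.as_tensor(b)
    out = _node(fwd(a.data, b.data), (a, b))
    if out._parents:
        def _back(g):
            ga, gb = bwd(g, a, b)
            if a.requires_grad or a._parents:
                a._accumulate(_unbroadcast(ga, a.data.shape))
            if b.requires_grad or b._parents:
                b._accumulate(_unbroadcast(gb, b.data.shape))
        out._backward = _back
    return out


def _extremum(x: Tensor, reducer) -> Tensor:
    val = reducer(x.data, axis=(-2, -1), keepdims=True)
    out = _node(val, (x,))
    if out._parents:
        mask = (x.data == val).astype(x.data.dtype)
        counts = mask.sum(axis=(-2, -1), keepdims=True)
        def _back(g):
            x._accumulate(g * mask / counts)
        out._backward = _back
    return out


def concat(tensors, axis: int = 1) -> Tensor:
    tensors = [Tensor.as_tensor(t) for t in tensors]
    out = _node(np.concatenate([t.data for t in tensors], axis=axis), tensors)
    if out._parents:
        sizes = [t.data.shape[axis] for t in tensors]
        splits = np.cumsum(sizes)[:-1]
        def _back(g):
            for t, gpart in zip(tensors, np.split(g, splits, axis=axis)):
                if t.requires_grad or t._parents:
                    t._accumulate(gpart)
        out._backward = _back
    return out


# ---------------------------------------------------------------------------
# im2col machinery
# ---------------------------------------------------------------------------

def _im2col(x, k, s, p):
    """(N,C,H,W) -> (N, C*k*k, L) patch matrix, L = Ho*Wo."""
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
    windows = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    windows = windows[:, :, ::s, ::s, :, :]          # (N,C,Ho,Wo,k,k)
    ho, wo = windows.shape[2], windows.shape[3]
    cols = windows.transpose(0, 1, 4, 5, 2, 3).reshape(n, c * k * k, ho * wo)
    return np.ascontiguousarray(cols), ho, wo


def _col2im(cols, x_shape, k, s, p, ho, wo):
    """Adjoint of _im2col: scatter-add patches back to (N,C,H,W)."""
    n, c, h, w = x_shape
    hp, wp = h + 2 * p, w + 2 * p
    cols6 = cols.reshape(n, c, k, k, ho, wo)
    xp = np.zeros((n, c, hp, wp), dtype=cols.dtype)
    for i in range(k):
        for j in range(k):
            xp[:, :, i:i + s * ho:s, j:j + s * wo:s] += cols6[:, :, i, j]
    return xp[:, :, p:p + h, p:p + w] if p else xp


def conv2d(x, weight: Tensor, bias: Tensor | None, stride: int, padding: int) -> Tensor:
    """2-D convolution (cross-correlation), weight (Cout, Cin, k, k)."""
    x = Tensor.as_tensor(x)
    co, ci, k, _ = weight.data.shape
    n = x.data.shape[0]
    cols, ho, wo = _im2col(x.data, k, stride, padding)
    wmat = weight.data.reshape(co, ci * k * k)
    y = np.einsum("oc,ncl->nol", wmat, cols, optimize=True)
    if bias is not None:
        y = y + bias.data.reshape(1, co, 1)
    y = y.reshape(n, co, ho, wo)
    parents = (x, weight) + (() if bias is None else (bias,))
    out = _node(y, parents)
    if out._parents:
        def _back(g):
            gflat = g.reshape(n, co, ho * wo)
            if weight.requires_grad or weight._parents:
                gw = np.einsum("nol,ncl->oc", gflat, cols, optimize=True)
                weight._accumulate(gw.reshape(weight.data.shape))
            if bias is not None and (bias.requires_grad or bias._parents):
                bias._accumulate(gflat.sum(axis=(0, 2)))
            if x.requires_grad or x._parents:
                gcols = np.einsum("oc,nol->ncl", wmat, gflat, optimize=True)
                x._accumulate(_col2im(gcols, x.data.shape, k, stride, padding, ho, wo))
        out._backward = _back
    return out


def conv_transpose2d(x, weight: Tensor, bias: Tensor | None,
                     stride: int, padding: int) -> Tensor:
    """Transposed 2-D convolution, weight (Cin, Cout, k, k).

    Output spatial size = stride*(H-1) + k - 2*padding; the forward pass is
    the adjoint (col2im) of the matching convolution, so conv/conv_transpose
    form an exact primal/adjoint pair.
    """
    x = Tensor.as_tensor(x)
    ci, co, k, _ = weight.data.shape
    n, _, h, w = x.data.shape
    ho = stride * (h - 1) + k - 2 * padding
    wo = stride * (w - 1) + k - 2 * padding
    wmat = weight.data.reshape(ci, co * k * k)
    xflat = x.data.reshape(n, ci, h * w)
    cols = np.einsum("cf,ncl->nfl", wmat, xflat, optimize=True)
    y = _col2im(cols, (n, co, ho, wo), k, stride, padding, h, w)
    if bias is not None:
        y = y + bias.data.reshape(1, co, 1, 1)
    parents = (x, weight) + (() if bias is None else (bias,))
    out = _node(y, parents)
    if out._parents:
        def _back(g):
            gcols, _, _ = _im2col(g, k, stride, padding)   # (N, co*k*k, h*w)
            if weight.requires_grad or weight._parents:
                gw = np.einsum("ncl,nfl->cf", xflat, gcols, optimize=True)
                weight._accumulate(gw.reshape(weight.data.shape))
            if bias is not None and (bias.requires_grad or bias._parents):
                bias._accumulate(g.sum(axis=(0, 2, 3)))
            if x.requires_grad or x._parents:
                gx = np.einsum("cf,nfl->ncl", wmat, gcols, optimize=True)
                x._accumulate(gx.reshape(x.data.shape))
        out._backward = _back
    return out


def instance_norm(x, eps: float = 1e-5) -> Tensor:
    """Parameter-free instance normalization over spatial axes."""
    x = Tensor.as_tensor(x)
    mu = x.data.mean(axis=(-2, -1), keepdims=True)
    var = x.data.var(axis=(-2, -1), keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    y = (x.data - mu) * inv
    out = _node(y, (x,))
    if out._parents:
        def _back(g):
            gm = g.mean(axis=(-2, -1), keepdims=True)
            gym = (g * y).mean(axis=(-2, -1), keepdims=True)
            x._accumulate(inv * (g - gm - y * gym))
        out._backward = _back
    return out
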