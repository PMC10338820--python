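"""Minimal reverse-mode automatic differentiation on numpy arrays.

Supports exactly the operator set needed by the correction pipeline:
elementwise arithmetic with broadcasting, exp/log/sqrt, ReLU, matrix
product, axis reductions (sum/mean/max/min), reshape/transpose/concat,
row gather, stride-1 "same" 2-D convolution and 2x2 max pooling.

Gradients are accumulated by a tape: every operation records its parents
and a closure that maps the output cotangent to parent cotangents.
`Tensor.backward()` walks the tape in reverse topological order.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "concat",
    "take_rows",
    "conv2d",
    "maxpool2d",
    "gradcheck",
]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing numpy broadcasting."""
    if grad.shape == shape:
        return grad
    # sum leading broadcast axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad



def _acc(d: dict, key, val):
    if key in d:
        d[key] = d[key] + val
    else:
        d[key] = val


class Tensor:
    """A numpy array plus an optional gradient tape node."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in parents)
        self.grad = None
        self._parents = tuple(p for p in parents if p.requires_grad)
        self._backward = backward if self.requires_grad else None

    # -- construction helpers ------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- arithmetic ----------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data + other.data, parents=(self, other))
        if out.requires_grad:
            def backward(g, a=self, b=other):
                grads = {}
                if a.requires_grad:
                    _acc(grads, id(a), _unbroadcast(g, a.data.shape))
                if b.requires_grad:
                    _acc(grads, id(b), _unbroadcast(g, b.data.shape))
                return grads
            out._backward = backward
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, parents=(self,))
        if out.requires_grad:
            out._backward = lambda g, a=self: {id(a): -g}
        return out

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data * other.data, parents=(self, other))
        if out.requires_grad:
            def backward(g, a=self, b=other):
                grads = {}
                if a.requires_grad:
                    _acc(grads, id(a), _unbroadcast(g * b.data, a.data.shape))
                if b.requires_grad:
                    _acc(grads, id(b), _unbroadcast(g * a.data, b.data.shape))
                return grads
            out._backward = backward
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data / other.data, parents=(self, other))
        if out.requires_grad:
            def backward(g, a=self, b=other):
                grads = {}
                if a.requires_grad:
                    _acc(grads, id(a), _unbroadcast(g / b.data, a.data.shape))
                if b.requires_grad:
                    _acc(grads, id(b), _unbroadcast(-g * a.data / b.data ** 2, b.data.shape))
                return grads
            out._backward = backward
        return out

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, p: float):
        out = Tensor(self.data ** p, parents=(self,))
        if out.requires_grad:
            out._backward = lambda g, a=self: {id(a): g * p * a.data ** (p - 1)}
        return out

    def __matmul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data @ other.data, parents=(self, other))
        if out.requires_grad:
            def backward(g, a=self, b=other):
                grads = {}
                if a.requires_grad:
                    _acc(grads, id(a), g @ b.data.T)
                if b.requires_grad:
                    _acc(grads, id(b), a.data.T @ g)
                return grads
            out._backward = backward
        return out

    # -- elementwise nonlinearities ------------------------------------------
    def exp(self):
        y = np.exp(self.data)
        out = Tensor(y, parents=(self,))
        if out.requires_grad:
            out._backward = lambda g, a=self, y=y: {id(a): g * y}
        return out

    def log(self):
        out = Tensor(np.log(self.data), parents=(self,))
        if out.requires_grad:
            out._backward = lambda g, a=self: {id(a): g / a.data}
        return out

    def sqrt(self):
        y = np.sqrt(self.data)
        out = Tensor(y, parents=(self,))
        if out.requires_grad:
            out._backward = lambda g, a=self, y=y: {id(a): g / (2.0 * y)}
        return out

    def relu(self):
        mask = self.data > 0
        out = Tensor(np.where(mask, self.data, 0.0), parents=(self,))
        if out.requires_grad:
            out._backward = lambda g, a=self, m=mask: {id(a): g * m}
        return out

    # -- reductions ----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,))
        if out.requires_grad:
            def backward(g, a=self, axis=axis, keepdims=keepdims):
                if axis is not None and not keepdims:
                    g = np.expand_dims(g, axis)
                return {id(a): np.broadcast_to(g, a.data.shape).copy()}
            out._backward = backward
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis: int, keepdims: bool = False):
        y = self.data.max(axis=axis, keepdims=True)
        # gradient split equally across ties so the check against finite
        # differences stays exact on tied inputs
        mask = (self.data == y)
        mask = mask / mask.sum(axis=axis, keepdims=True)
        out = Tensor(y if keepdims else y.squeeze(axis=axis), parents=(self,))
        if out.requires_grad:
            def backward(g, a=self, m=mask, axis=axis, keepdims=keepdims):
                if not keepdims:
                    g = np.expand_dims(g, axis)
                return {id(a): g * m}
            out._backward = backward
        return out

    def min(self, axis: int, keepdims: bool = False):
        return -((-self).max(axis=axis, keepdims=keepdims))

    # -- shape ops -----------------------------------------------------------
    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), parents=(self,))
        if out.requires_grad:
            out._backward = lambda g, a=self: {id(a): g.reshape(a.data.shape)}
        return out

    def transpose(self, *axes):
        axes = axes or tuple(reversed(range(self.data.ndim)))
        inv = np.argsort(axes)
        out = Tensor(self.data.transpose(axes), parents=(self,))
        if out.requires_grad:
            out._backward = lambda g, a=self, inv=tuple(inv): {id(a): g.transpose(inv)}
        return out

    @property
    def T(self):
        return self.transpose()

    # -- autograd driver -----------------------------------------------------
    def backward(self, grad=None):
        if not self.requires_grad:
            raise RuntimeError("backward() on a tensor that does not require grad")
        if grad is None:
            if self.data.size != 1:
                raise RuntimeError("grad must be supplied for non-scalar outputs")
            grad = np.ones_like(self.data)

        # reverse topological order over the tape
        topo, seen = [], set()
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

        grads = {id(self): np.asarray(grad, dtype=np.float64)}
        nodes = {id(self): self}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node._backward is None:
                # leaf: accumulate
                node.grad = g if node.grad is None else node.grad + g
                continue
            for pid, pg in node._backward(g).items():
                if pid in grads:
                    grads[pid] = grads[pid] + pg
                else:
                    grads[pid] = pg
            for p in node._parents:
                nodes[id(p)] = p
        # leaves reached exactly once are handled above via _backward None;
        # interior nodes with requires_grad but no external reference simply drop


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), parents=tuple(tensors))
    if out.requires_grad:
        sizes = [t.data.shape[axis] for t in tensors]
        splits = np.cumsum(sizes)[:-1]

        def backward(g, ts=tensors, splits=splits, axis=axis):
            pieces = np.split(g, splits, axis=axis)
            grads = {}
            for t, piece in zip(ts, pieces):
                if t.requires_grad:
                    if id(t) in grads:
                        grads[id(t)] = grads[id(t)] + piece
                    else:
                        grads[id(t)] = piece
            return grads
        out._backward = backward
    return out


def take_rows(x: Tensor, idx) -> Tensor:
    """Gather rows of a 2-D tensor; backward scatter-adds into place."""
    idx = np.asarray(idx, dtype=np.intp)
    out = Tensor(x.data[idx], parents=(x,))
    if out.requires_grad:
        def backward(g, a=x, idx=idx):
            full = np.zeros_like(a.data)
            np.add.at(full, idx, g)
            return {id(a): full}
        out._backward = backward
    return out


def _im2col(xp: np.ndarray, k: int, H: int, W: int) -> np.ndarray:
    """(C, H+k-1, W+k-1) padded input -> (C*k*k, H*W) patch matrix."""
    C = xp.shape[0]
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(1, 2))
    # win: (C, H, W, k, k) -> (C, k, k, H, W)
    return win.transpose(0, 3, 4, 1, 2).reshape(C * k * k, H * W)


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """Stride-1 same-padding 2-D convolution (cross-correlation).

    x: (C_in, H, W); w: (C_out, C_in, k, k); b: (C_out,) or None.
    """
    C_in, H, W = x.data.shape
    C_out, C_in_w, k, k2 = w.data.shape
    if C_in_w != C_in:
        raise ValueError(f"conv2d channel mismatch: input has {C_in}, kernel expects {C_in_w}")
    if k != k2 or k % 2 != 1:
        raise ValueError("conv2d requires odd square kernels")
    p = k // 2
    xp = np.pad(x.data, ((0, 0), (p, p), (p, p)))
    col = _im2col(xp, k, H, W)                     # (C_in*k*k, H*W)
    wmat = w.data.reshape(C_out, C_in * k * k)
    y = wmat @ col                                  # (C_out, H*W)
    if b is not None:
        y = y + b.data[:, None]
    parents = (x, w) if b is None else (x, w, b)
    out = Tensor(y.reshape(C_out, H, W), parents=parents)
    if out.requires_grad:
        def backward(g, x=x, w=w, b=b, col=col, wmat=wmat, k=k, p=p, H=H, W=W,
                     C_in=C_in, C_out=C_out):
            gmat = g.reshape(C_out, H * W)
            grads = {}
            if w.requires_grad:
                grads[id(w)] = (gmat @ col.T).reshape(w.data.shape)
            if b is not None and b.requires_grad:
                grads[id(b)] = gmat.sum(axis=1)
            if x.requires_grad:
                gcol = (wmat.T @ gmat).reshape(C_in, k, k, H, W)
                gxp = np.zeros((C_in, H + 2 * p, W + 2 * p))
                for i in range(k):
                    for j in range(k):
                        gxp[:, i:i + H, j:j + W] += gcol[:, i, j]
                grads[id(x)] = gxp[:, p:p + H, p:p + W] if p else gxp
            return grads
        out._backward = backward
    return out


def maxpool2d(x: Tensor, factor: int = 2) -> Tensor:
    """Non-overlapping max pooling; spatial dims must divide the factor."""
    C, H, W = x.data.shape
    f = factor
    if H % f or W % f:
        raise ValueError(f"maxpool2d: {H}x{W} not divisible by {f}")
    blocks = x.data.reshape(C, H // f, f, W // f, f)
    y = blocks.max(axis=(2, 4))
    out = Tensor(y, parents=(x,))
    if out.requires_grad:
        ymax = y[:, :, None, :, None]
        mask = (blocks == ymax)
        mask = mask / mask.sum(axis=(2, 4), keepdims=True)

        def backward(g, a=x, m=mask, C=C, H=H, W=W, f=f):
            gb = g[:, :, None, :, None] * m
            return {id(a): gb.reshape(C, H, W)}
        out._backward = backward
    return out


def gradcheck(fn, tensors, eps: float = 1e-6, rtol: float = 1e-5, atol: float = 1e-7) -> bool:
    """Compare analytic gradients of scalar `fn(*tensors)` with central differences."""
    for t in tensors:
        t.grad = None
    out = fn(*tensors)
    out.backward()
    ok = True
    for t in tensors:
        num = np.zeros_like(t.data)
        flat = t.data.reshape(-1)
        numf = num.reshape(-1)
        for i in range(flat.size):
            orig = flat[i]
            flat[i] = orig + eps
            hi = fn(*tensors).data.item()
            flat[i] = orig - eps
            lo = fn(*tensors).data.item()
            flat[i] = orig
            numf[i] = (hi - lo) / (2 * eps)
        ana = t.grad if t.grad is not None else np.zeros_like(t.data)
        if not np.allclose(ana, num, rtol=rtol, atol=atol):
            ok = False
    return ok
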