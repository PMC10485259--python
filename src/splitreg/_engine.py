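"""Reverse-mode automatic differentiation on numpy arrays.

A minimal tape: each :class:`Tensor` wraps an ``ndarray`` plus an optional
closure producing parent gradients.  Only the operations the registration
networks and losses need are provided — elementwise arithmetic, reductions,
n-dimensional strided/dilated convolution, nearest-neighbor upsampling,
channel concatenation, leaky rectification, clipped box-window sums (for the
local cross-correlation loss), forward spatial differences, and a linear
grid-sampling (warp) operator differentiable in the displacement field.

Dtype follows the input arrays: float64 inputs give float64 graphs.
"""

from __future__ import annotations

import itertools

import numpy as np

__all__ = [
    "Tensor",
    "astensor",
    "add",
    "sub",
    "mul",
    "div",
    "tsum",
    "tmean",
    "leaky_relu",
    "concat",
    "conv_nd",
    "upsample_nearest",
    "box_sum",
    "forward_diff",
    "grid_sample",
]


class Tensor:
    """An array node in the computation graph."""

    __slots__ = ("data", "grad", "needs_grad", "_parents", "_grad_fn")

    def __init__(self, data, needs_grad: bool = False, parents=(), grad_fn=None):
        self.data = data if isinstance(data, np.ndarray) else np.asarray(data, dtype=float)
        self.grad = None
        self.needs_grad = needs_grad
        self._parents = parents
        self._grad_fn = grad_fn

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def backward(self) -> None:
        """Accumulate gradients of this scalar node into the graph's leaves."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar node")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded:
                topo.append(node)
                continue
            if id(node) in seen or not node.needs_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._grad_fn is None:
                continue
            for parent, g in zip(node._parents, node._grad_fn(node.grad)):
                if g is None or not parent.needs_grad:
                    continue
                parent.grad = g if parent.grad is None else parent.grad + g

    # -- operator sugar -------------------------------------------------
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

    def __truediv__(self, other):
        return div(self, other)

    def __neg__(self):
        return mul(self, -1.0)

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, needs_grad={self.needs_grad})"


def astensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x))


def _node(data: np.ndarray, parents, grad_fn) -> Tensor:
    if any(p.needs_grad for p in parents):
        return Tensor(data, True, tuple(parents), grad_fn)
    return Tensor(data)


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``g`` down to ``shape`` (adjoint of numpy broadcasting)."""
    if g.shape == shape:
        return g
    extra = g.ndim - len(shape)
    if extra:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, (gs, s) in enumerate(zip(g.shape, shape)) if s == 1 and gs != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g


def add(a, b) -> Tensor:
    a, b = astensor(a), astensor(b)
    return _node(
        a.data + b.data,
        (a, b),
        lambda g: (_unbroadcast(g, a.data.shape), _unbroadcast(g, b.data.shape)),
    )


def sub(a, b) -> Tensor:
    a, b = astensor(a), astensor(b)
    return _node(
        a.data - b.data,
        (a, b),
        lambda g: (_unbroadcast(g, a.data.shape), _unbroadcast(-g, b.data.shape)),
    )


def mul(a, b) -> Tensor:
    a, b = astensor(a), astensor(b)
    return _node(
        a.data * b.data,
        (a, b),
        lambda g: (
            _unbroadcast(g * b.data, a.data.shape),
            _unbroadcast(g * a.data, b.data.shape),
        ),
    )


def div(a, b) -> Tensor:
    a, b = astensor(a), astensor(b)
    out = a.data / b.data
    return _node(
        out,
        (a, b),
        lambda g: (
            _unbroadcast(g / b.data, a.data.shape),
            _unbroadcast(-g * out / b.data, b.data.shape),
        ),
    )


def tsum(a) -> Tensor:
    a = astensor(a)
    return _node(
        np.asarray(a.data.sum()),
        (a,),
        lambda g: (np.full(a.data.shape, float(g), dtype=a.data.dtype),),
    )


def tmean(a) -> Tensor:
    a = astensor(a)
    n = a.data.size
    return _node(
        np.asarray(a.data.mean()),
        (a,),
        lambda g: (np.full(a.data.shape, float(g) / n, dtype=a.data.dtype),),
    )


def leaky_relu(a, slope: float = 0.2) -> Tensor:
    a = astensor(a)
    scale = np.where(a.data >= 0, 1.0, slope).astype(a.data.dtype)
    return _node(a.data * scale, (a,), lambda g: (g * scale,))


def concat(tensors, axis: int = 1) -> Tensor:
    tensors = [astensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def grad_fn(g):
        return tuple(np.split(g, splits, axis=axis))

    return _node(np.concatenate([t.data for t in tensors], axis=axis), tensors, grad_fn)


# ---------------------------------------------------------------------------
# convolution
# ---------------------------------------------------------------------------


def _as_tuple(v, d: int) -> tuple:
    if np.isscalar(v):
        return (int(v),) * d
    return tuple(int(x) for x in v)


def conv_nd(x, w, b=None, stride=1, dilation=1, padding=0) -> Tensor:
    """n-D cross-correlation, ``x`` (B, Cin, *S), ``w`` (Cout, Cin, *K).

    Zero padding; output spatial size follows the usual
    ``(n + 2p - dil*(k-1) - 1) // s + 1`` rule.
    """
    x, w = astensor(x), astensor(w)
    bt = astensor(b) if b is not None else None
    d = x.data.ndim - 2
    stride = _as_tuple(stride, d)
    dilation = _as_tuple(dilation, d)
    padding = _as_tuple(padding, d)
    K = w.data.shape[2:]
    S = x.data.shape[2:]
    out_shape = tuple(
        (S[a] + 2 * padding[a] - dilation[a] * (K[a] - 1) - 1) // stride[a] + 1
        for a in range(d)
    )
    if any(n <= 0 for n in out_shape):
        raise ValueError(f"input {S} too small for kernel {K} with dilation {dilation}")
    B, cin = x.data.shape[:2]
    cout = w.data.shape[0]
    pad_width = [(0, 0), (0, 0)] + [(p, p) for p in padding]
    xp = np.pad(x.data, pad_width) if any(padding) else x.data

    def k_slices(kidx):
        return tuple(
            slice(
                kidx[a] * dilation[a],
                kidx[a] * dilation[a] + stride[a] * out_shape[a],
                stride[a],
            )
            for a in range(d)
        )

    acc = np.zeros((cout, B) + out_shape, dtype=x.data.dtype)
    all2 = (slice(None), slice(None))
    for kidx in itertools.product(*(range(k) for k in K)):
        xs = xp[all2 + k_slices(kidx)]
        # (Cout, Cin) x (B, Cin, *out) -> (Cout, B, *out)
        acc += np.tensordot(w.data[all2 + kidx], xs, axes=([1], [1]))
    y = np.ascontiguousarray(np.moveaxis(acc, 0, 1))
    if bt is not None:
        y += bt.data.reshape((1, cout) + (1,) * d)

    def grad_fn(g):
        sum_axes = (0,) + tuple(range(2, 2 + d))
        gw = np.zeros_like(w.data)
        gxp = np.zeros_like(xp)
        for kidx in itertools.product(*(range(k) for k in K)):
            sl = all2 + k_slices(kidx)
            xs = xp[sl]
            gw[all2 + kidx] = np.tensordot(g, xs, axes=(sum_axes, sum_axes))
            # (Cin, Cout) x (B, Cout, *out) -> (Cin, B, *out)
            contrib = np.tensordot(w.data[all2 + kidx].T, g, axes=([1], [1]))
            gxp[sl] += np.moveaxis(contrib, 0, 1)
        if any(padding):
            crop = all2 + tuple(slice(p, p + S[a]) for a, p in enumerate(padding))
            gx = gxp[crop]
        else:
            gx = gxp
        gb = g.sum(axis=sum_axes) if bt is not None else None
        return (gx, gw, gb) if bt is not None else (gx, gw)

    parents = (x, w, bt) if bt is not None else (x, w)
    return _node(y, parents, grad_fn)


def upsample_nearest(x, factor: int = 2) -> Tensor:
    """Repeat each spatial sample ``factor`` times along every spatial axis."""
    x = astensor(x)
    d = x.data.ndim - 2
    y = x.data
    for a in range(2, 2 + d):
        y = np.repeat(y, factor, axis=a)

    def grad_fn(g):
        # fold each spatial axis into (n, factor) blocks and sum the blocks
        shape = []
        for a, s in enumerate(g.shape):
            if a >= 2:
                shape.extend([s // factor, factor])
            else:
                shape.append(s)
        gr = g.reshape(shape)
        axes = tuple(3 + 2 * a for a in range(d))
        return (gr.sum(axis=axes),)

    return _node(y, (x,), grad_fn)


# ---------------------------------------------------------------------------
# windowed sums, finite differences
# ---------------------------------------------------------------------------


def _slide_sum(x: np.ndarray, win: int, axis: int) -> np.ndarray:
    """Clipped centered sliding-window sum along one axis (window ``win`` odd)."""
    h = win // 2
    n = x.shape[axis]
    c = np.cumsum(x, axis=axis)
    zero_shape = list(x.shape)
    zero_shape[axis] = 1
    c0 = np.concatenate([np.zeros(zero_shape, dtype=x.dtype), c], axis=axis)
    i = np.arange(n)
    hi = np.minimum(i + h, n - 1) + 1
    lo = np.maximum(i - h, 0)
    return np.take(c0, hi, axis=axis) - np.take(c0, lo, axis=axis)


def box_sum_array(x: np.ndarray, window: int, spatial_ndim: int) -> np.ndarray:
    y = x
    for a in range(x.ndim - spatial_ndim, x.ndim):
        y = _slide_sum(y, window, a)
    return y


def box_sum(x, window: int, spatial_ndim: int) -> Tensor:
    """Centered box-window sum over the last ``spatial_ndim`` axes.

    Windows are clipped at the array borders (no padding), so the operator is
    self-adjoint and the gradient is the same box sum applied to ``g``.
    """
    x = astensor(x)
    return _node(
        box_sum_array(x.data, window, spatial_ndim),
        (x,),
        lambda g: (box_sum_array(g, window, spatial_ndim),),
    )


def forward_diff(x, axis: int) -> Tensor:
    """Forward difference along ``axis``; the trailing entry is 0 (Neumann)."""
    x = astensor(x)
    n = x.data.shape[axis]
    y = np.zeros_like(x.data)
    head = [slice(None)] * x.data.ndim
    head[axis] = slice(0, n - 1)
    tail = [slice(None)] * x.data.ndim
    tail[axis] = slice(1, n)
    y[tuple(head)] = x.data[tuple(tail)] - x.data[tuple(head)]

    def grad_fn(g):
        gx = np.zeros_like(g)
        gx[tuple(tail)] += g[tuple(head)]
        gx[tuple(head)] -= g[tuple(head)]
        return (gx,)

    return _node(y, (x,), grad_fn)


# ---------------------------------------------------------------------------
# differentiable warping
# ---------------------------------------------------------------------------


def grid_sample(moving: np.ndarray, disp) -> Tensor:
    """Linearly sample ``moving`` (B, *S) at ``x + disp`` with border clamping.

    ``disp`` has shape (B, d, *S) in voxel units.  Differentiable with respect
    to the displacement; the moving image is data, not a graph node.
    """
    disp = astensor(disp)
    B = moving.shape[0]
    S = moving.shape[1:]
    d = len(S)
    if disp.data.shape != (B, d) + S:
        raise ValueError(f"displacement shape {disp.data.shape} != {(B, d) + S}")
    dtype = disp.data.dtype
    grids = np.meshgrid(*[np.arange(n, dtype=dtype) for n in S], indexing="ij")
    pos = np.stack(
        [grids[a][None] + disp.data[:, a] for a in range(d)], axis=1
    )  # (B, d, *S)
    inside = [(pos[:, a] >= 0) & (pos[:, a] <= S[a] - 1) for a in range(d)]
    pos_c = np.stack(
        [np.clip(pos[:, a], 0, S[a] - 1) for a in range(d)], axis=1
    )
    base = np.floor(pos_c).astype(np.int64)
    for a in range(d):
        np.clip(base[:, a], 0, S[a] - 2, out=base[:, a])
    frac = pos_c - base

    flat = moving.reshape(B, -1)
    strides = np.ones(d, dtype=np.int64)
    for a in range(d - 2, -1, -1):
        strides[a] = strides[a + 1] * S[a + 1]

    corners = list(itertools.product((0, 1), repeat=d))
    vals = {}
    out = np.zeros((B,) + S, dtype=dtype)
    for c in corners:
        idx = np.zeros((B,) + S, dtype=np.int64)
        for a in range(d):
            idx += (base[:, a] + c[a]) * strides[a]
        v = np.take_along_axis(flat, idx.reshape(B, -1), axis=1).reshape((B,) + S)
        vals[c] = v
        wgt = np.ones((B,) + S, dtype=dtype)
        for a in range(d):
            wgt = wgt * (frac[:, a] if c[a] else 1.0 - frac[:, a])
        out += v * wgt

    def grad_fn(g):
        gd = np.zeros_like(disp.data)
        for a in range(d):
            acc = np.zeros((B,) + S, dtype=dtype)
            for c in corners:
                dw = np.ones((B,) + S, dtype=dtype)
                for a2 in range(d):
                    if a2 == a:
                        dw = dw * (1.0 if c[a2] else -1.0)
                    else:
                        dw = dw * (frac[:, a2] if c[a2] else 1.0 - frac[:, a2])
                acc += vals[c] * dw
            gd[:, a] = g * acc * inside[a]
        return (gd,)

    return _node(out, (disp,), grad_fn)
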