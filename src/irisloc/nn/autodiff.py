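"""Minimal reverse-mode automatic differentiation on numpy arrays.

Just enough machinery for a small fully-convolutional network: elementwise
arithmetic with broadcasting, relu/sigmoid/log/abs/clamp/power, full
reductions, 2-D convolution (im2col + BLAS), batch normalization, exact
factor-2 bilinear upsampling, and a zero-padded spatial crop. Gradients are
accumulated by topological traversal from a scalar loss.

Arrays follow the (N, C, H, W) layout. The engine preserves the input dtype,
so float64 graphs can be used for finite-difference gradient checks while
training runs in float32.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "relu",
    "sigmoid",
    "log",
    "clamp",
    "absolute",
    "sum_",
    "mean_",
    "conv2d",
    "batch_norm",
    "upsample2x",
    "crop2d",
    "concat",
    "permute",
    "slice_channels",
]


class Tensor:
    """A numpy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    # make ndarray <op> Tensor dispatch to the reflected Tensor methods
    __array_ufunc__ = None

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data)
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self.grad = None
        self._parents = parents
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    @property
    def dtype(self):
        return self.data.dtype

    def item(self) -> float:
        return float(self.data)

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.astype(self.data.dtype, copy=True)
        else:
            self.grad += grad

    def backward(self) -> None:
        """Backpropagate from a scalar tensor."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        topo, seen = [], set()

        def visit(t: "Tensor") -> None:
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)

    # -- elementwise arithmetic ------------------------------------------
    def __add__(self, other):
        other = _as_tensor(other, self.dtype)
        out = Tensor(self.data + other.data, parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.shape))

        out._backward = bwd
        return out

    __radd__ = __add__

    def __mul__(self, other):
        other = _as_tensor(other, self.dtype)
        out = Tensor(self.data * other.data, parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.shape))

        out._backward = bwd
        return out

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-_as_tensor(other, self.dtype))

    def __rsub__(self, other):
        return _as_tensor(other, self.dtype) + (-self)

    def __truediv__(self, scalar):
        if isinstance(scalar, Tensor):
            raise TypeError("tensor/tensor division is not supported")
        return self * (1.0 / float(scalar))

    def __pow__(self, exponent: float):
        out = Tensor(self.data**exponent, parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g * exponent * self.data ** (exponent - 1))

        out._backward = bwd
        return out


def _as_tensor(value, dtype) -> Tensor:
    if isinstance(value, Tensor):
        return value
    return Tensor(np.asarray(value, dtype=dtype))


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce a broadcast gradient back to the operand's shape."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, dim in enumerate(shape):
        if dim == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


# -- nonlinearities and pointwise functions ------------------------------

def relu(x: Tensor) -> Tensor:
    out = Tensor(np.maximum(x.data, 0), parents=(x,))

    def bwd(g):
        if x.requires_grad:
            x._accumulate(g * (x.data > 0))

    out._backward = bwd
    return out


def sigmoid(x: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-x.data))
    out = Tensor(s, parents=(x,))

    def bwd(g):
        if x.requires_grad:
            x._accumulate(g * s * (1.0 - s))

    out._backward = bwd
    return out


def log(x: Tensor) -> Tensor:
    out = Tensor(np.log(x.data), parents=(x,))

    def bwd(g):
        if x.requires_grad:
            x._accumulate(g / x.data)

    out._backward = bwd
    return out


def clamp(x: Tensor, lo: float, hi: float) -> Tensor:
    """Clip values; the gradient passes only where no clipping occurred."""
    out = Tensor(np.clip(x.data, lo, hi), parents=(x,))
    inside = (x.data > lo) & (x.data < hi)

    def bwd(g):
        if x.requires_grad:
            x._accumulate(g * inside)

    out._backward = bwd
    return out


def absolute(x: Tensor) -> Tensor:
    out = Tensor(np.abs(x.data), parents=(x,))

    def bwd(g):
        if x.requires_grad:
            x._accumulate(g * np.sign(x.data))

    out._backward = bwd
    return out


def sum_(x: Tensor) -> Tensor:
    out = Tensor(x.data.sum(), parents=(x,))

    def bwd(g):
        if x.requires_grad:
            x._accumulate(np.broadcast_to(g, x.shape))

    out._backward = bwd
    return out


def mean_(x: Tensor) -> Tensor:
    return sum_(x) / x.data.size


# -- convolution ----------------------------------------------------------

def _out_size(n: int, k: int, stride: int, padding: int) -> int:
    return (n + 2 * padding - k) // stride + 1


def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, padding: int):
    """(N, C, H, W) -> (C*kh*kw, N*Ho*Wo) patch matrix.

    Filled by kh*kw large block copies (one per kernel offset), which is far
    cheaper than gathering per-pixel patches.
    """
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    ho = _out_size(h, kh, stride, padding)
    wo = _out_size(w, kw, stride, padding)
    cols = np.empty((c, kh, kw, n, ho, wo), dtype=x.dtype)
    for i in range(kh):
        for j in range(kw):
            cols[:, i, j] = xp[:, :, i:i + stride * ho:stride,
                               j:j + stride * wo:stride].transpose(1, 0, 2, 3)
    return cols.reshape(c * kh * kw, n * ho * wo), ho, wo


def conv2d(x: Tensor, weight: Tensor, bias: Tensor, stride: int = 1,
           padding: int = 1) -> Tensor:
    """2-D convolution (cross-correlation) via im2col and one BLAS matmul."""
    n, c, h, w = x.shape
    co, ci, kh, kw = weight.shape
    if ci != c:
        raise ValueError(f"input has {c} channels, weight expects {ci}")
    one_by_one = (kh == kw == 1 and stride == 1 and padding == 0)
    if one_by_one:
        ho, wo = h, w
        cols = x.data.transpose(1, 0, 2, 3).reshape(c, -1)
    else:
        cols, ho, wo = _im2col(x.data, kh, kw, stride, padding)
    wmat = weight.data.reshape(co, -1)
    y = wmat @ cols  # (Co, N*Ho*Wo)
    if bias is not None:
        y += bias.data[:, None]
    out = Tensor(
        np.ascontiguousarray(y.reshape(co, n, ho, wo).transpose(1, 0, 2, 3)),
        parents=tuple(t for t in (x, weight, bias) if t is not None),
    )

    def bwd(g):
        gy = np.ascontiguousarray(g.transpose(1, 0, 2, 3)).reshape(co, -1)
        if bias is not None and bias.requires_grad:
            bias._accumulate(gy.sum(axis=1))
        if weight.requires_grad:
            # the forward patch matrix is kept in the closure: the second
            # im2col pass costs more than the extra memory at this scale
            weight._accumulate((gy @ cols.T).reshape(weight.shape))
        if x.requires_grad:
            gcols = (wmat.T @ gy).reshape(c, kh, kw, n, ho, wo)
            if one_by_one:
                gx = np.ascontiguousarray(
                    gcols.reshape(c, n, h, w).transpose(1, 0, 2, 3))
            else:
                gxp = np.zeros((n, c, h + 2 * padding, w + 2 * padding), dtype=g.dtype)
                for i in range(kh):
                    for j in range(kw):
                        gxp[:, :, i:i + stride * ho:stride, j:j + stride * wo:stride] += \
                            gcols[:, i, j].transpose(1, 0, 2, 3)
                gx = gxp[:, :, padding:-padding, padding:-padding] if padding else gxp
            x._accumulate(gx)

    out._backward = bwd
    return out


# -- batch normalization --------------------------------------------------

def batch_norm(x: Tensor, gamma: Tensor, beta: Tensor,
               mean: np.ndarray, var: np.ndarray, eps: float = 1e-5,
               use_batch_stats: bool = True) -> Tensor:
    """Per-channel normalization over (N, H, W).

    With ``use_batch_stats`` the batch moments are used (training); otherwise
    ``mean``/``var`` are treated as fixed running statistics (evaluation).
    """
    if use_batch_stats:
        m = x.data.mean(axis=(0, 2, 3))
        v = x.data.var(axis=(0, 2, 3))
    else:
        m, v = mean, var
    mb = m.reshape(1, -1, 1, 1)
    ivstd = 1.0 / np.sqrt(v + eps)
    ivb = ivstd.reshape(1, -1, 1, 1)
    xhat = (x.data - mb) * ivb
    out = Tensor(gamma.data.reshape(1, -1, 1, 1) * xhat + beta.data.reshape(1, -1, 1, 1),
                 parents=(x, gamma, beta))

    def bwd(g):
        if gamma.requires_grad:
            gamma._accumulate((g * xhat).sum(axis=(0, 2, 3)))
        if beta.requires_grad:
            beta._accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gxhat = g * gamma.data.reshape(1, -1, 1, 1)
            if use_batch_stats:
                nm = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
                sum_gxhat = gxhat.sum(axis=(0, 2, 3), keepdims=True)
                sum_gxhat_xhat = (gxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
                gx = (gxhat - sum_gxhat / nm - xhat * sum_gxhat_xhat / nm) * ivb
            else:
                gx = gxhat * ivb
            x._accumulate(gx)

    out._backward = bwd
    return out, m, v


# -- bilinear 2x upsampling ----------------------------------------------

def _up2_axis(a: np.ndarray, axis: int) -> np.ndarray:
    """Exact bilinear factor-2 upsampling along one axis (half-pixel centers).

    out[2i] = 0.25*a[i-1] + 0.75*a[i]; out[2i+1] = 0.75*a[i] + 0.25*a[i+1],
    with edge clamping.
    """
    a = np.moveaxis(a, axis, -1)
    n = a.shape[-1]
    out = np.empty(a.shape[:-1] + (2 * n,), dtype=a.dtype)
    prev = np.concatenate([a[..., :1], a[..., :-1]], axis=-1)
    nxt = np.concatenate([a[..., 1:], a[..., -1:]], axis=-1)
    out[..., 0::2] = 0.25 * prev + 0.75 * a
    out[..., 1::2] = 0.75 * a + 0.25 * nxt
    return np.moveaxis(out, -1, axis)


def _up2_axis_T(g: np.ndarray, axis: int) -> np.ndarray:
    """Transpose (adjoint) of :func:`_up2_axis`."""
    g = np.moveaxis(g, axis, -1)
    n = g.shape[-1] // 2
    ge, go = g[..., 0::2], g[..., 1::2]
    out = 0.75 * (ge + go)
    out[..., :-1] += 0.25 * ge[..., 1:]
    out[..., 1:] += 0.25 * go[..., :-1]
    out[..., 0] += 0.25 * ge[..., 0]
    out[..., -1] += 0.25 * go[..., -1]
    return np.moveaxis(out, -1, axis)


def upsample2x(x: Tensor) -> Tensor:
    """Bilinear x2 spatial upsampling of an (N, C, H, W) tensor."""
    out = Tensor(_up2_axis(_up2_axis(x.data, 2), 3), parents=(x,))

    def bwd(g):
        if x.requires_grad:
            x._accumulate(_up2_axis_T(_up2_axis_T(g, 3), 2))

    out._backward = bwd
    return out


# -- structural ops --------------------------------------------------------

def concat(tensors: list, axis: int = 1) -> Tensor:
    """Concatenate tensors along an axis; the gradient is split back."""
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 parents=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(a, b)
                t._accumulate(g[tuple(idx)])

    out._backward = bwd
    return out


def slice_channels(x: Tensor, a: int, b: int) -> Tensor:
    """Select channels [a, b) of an (N, C, H, W) tensor (view, no copy)."""
    out = Tensor(x.data[:, a:b], parents=(x,))

    def bwd(g):
        if x.requires_grad:
            # accumulate in place into the slice instead of materializing a
            # full-size sparse gradient
            if x.grad is None:
                x.grad = np.zeros_like(x.data)
            x.grad[:, a:b] += g

    out._backward = bwd
    return out


def permute(x: Tensor, axes: tuple) -> Tensor:
    """Transpose axes; the gradient is transposed by the inverse permutation."""
    out = Tensor(np.ascontiguousarray(x.data.transpose(axes)), parents=(x,))
    inv = tuple(np.argsort(axes))

    def bwd(g):
        if x.requires_grad:
            x._accumulate(g.transpose(inv))

    out._backward = bwd
    return out


# -- spatial crop with zero padding ---------------------------------------

def crop2d(x: Tensor, y0: int, x0: int, size: int,
           batch: int | None = None) -> Tensor:
    """Crop a ``size`` x ``size`` window at (row y0, col x0), zero-padded
    where the window leaves the image; ``batch`` restricts the crop to one
    batch element (keeping a singleton batch axis)."""
    n, c, h, w = x.shape
    bsel = slice(None) if batch is None else slice(batch, batch + 1)
    nb = n if batch is None else 1
    ys, ye = max(y0, 0), min(y0 + size, h)
    xs, xe = max(x0, 0), min(x0 + size, w)
    data = np.zeros((nb, c, size, size), dtype=x.dtype)
    if ys < ye and xs < xe:
        data[:, :, ys - y0:ye - y0, xs - x0:xe - x0] = x.data[bsel, :, ys:ye, xs:xe]
    out = Tensor(data, parents=(x,))

    def bwd(g):
        if x.requires_grad:
            gx = np.zeros_like(x.data)
            if ys < ye and xs < xe:
                gx[bsel, :, ys:ye, xs:xe] = g[:, :, ys - y0:ye - y0, xs - x0:xe - x0]
            x._accumulate(gx)

    out._backward = bwd
    return out
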