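"""Minimal reverse-mode automatic differentiation on numpy arrays.

Supports exactly the operations the segmentation network and its losses
need: broadcasting arithmetic, matmul, 2-D convolution, batch norm,
separable bilinear resizing, reductions, and pointwise nonlinearities.
Gradients are accumulated by a topological-order backward sweep.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "as_tensor", "set_default_dtype", "get_default_dtype",
           "no_grad"]

DTYPE = np.dtype(np.float32)


def set_default_dtype(dtype) -> None:
    """Set the dtype used for all new tensors (float32 for speed,
    float64 for finite-difference gradient checks).  Set this before
    building any modules; existing parameters are not converted."""
    global DTYPE
    DTYPE = np.dtype(dtype)


def get_default_dtype():
    return DTYPE


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` by summing over broadcast axes."""
    if grad.shape == shape:
        return grad
    # sum leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, (g, s) in enumerate(zip(grad.shape, shape)):
        if s == 1 and g != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward", "name")
    __array_priority__ = 100  # make numpy defer to our __r*__ operators

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None,
                 name: str | None = None):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad: np.ndarray | None = None
        if _NO_GRAD:
            requires_grad, parents, backward = False, (), None
        self.requires_grad = bool(requires_grad)
        self._parents = tuple(parents)
        self._backward = backward
        self.name = name

    # ------------------------------------------------------------------ basics
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -------------------------------------------------------------- backward
    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar")
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
        self.grad = np.asarray(grad, dtype=DTYPE)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad = self.grad + grad

    # ------------------------------------------------------------- arithmetic
    def __add__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data + other.data,
                     requires_grad=self.requires_grad or other.requires_grad,
                     parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))
        out._backward = bw
        return out

    __radd__ = __add__

    def __mul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data * other.data,
                     requires_grad=self.requires_grad or other.requires_grad,
                     parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))
        out._backward = bw
        return out

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __truediv__(self, other):
        other = as_tensor(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return as_tensor(other) * self ** -1.0

    def __pow__(self, exponent: float):
        out = Tensor(self.data ** exponent, requires_grad=self.requires_grad,
                     parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accum(g * exponent * self.data ** (exponent - 1.0))
        out._backward = bw
        return out

    def __matmul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data @ other.data,
                     requires_grad=self.requires_grad or other.requires_grad,
                     parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g @ np.swapaxes(other.data, -1, -2),
                                         self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(np.swapaxes(self.data, -1, -2) @ g,
                                          other.data.shape))
        out._backward = bw
        return out

    # ------------------------------------------------------------- pointwise
    def relu(self):
        mask = self.data > 0
        out = Tensor(self.data * mask, requires_grad=self.requires_grad,
                     parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accum(g * mask)
        out._backward = bw
        return out

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-np.clip(self.data, -500, 500)))
        out = Tensor(s, requires_grad=self.requires_grad, parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accum(g * s * (1.0 - s))
        out._backward = bw
        return out

    def exp(self):
        e = np.exp(self.data)
        out = Tensor(e, requires_grad=self.requires_grad, parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accum(g * e)
        out._backward = bw
        return out

    def log(self, eps: float = 1e-12):
        clipped = np.maximum(self.data, eps)
        out = Tensor(np.log(clipped), requires_grad=self.requires_grad,
                     parents=(self,))

        def bw(g):
            if self.requires_grad:
                # no gradient where the clip is active
                self._accum(g * (self.data >= eps) / clipped)
        out._backward = bw
        return out

    # ------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims),
                     requires_grad=self.requires_grad, parents=(self,))

        def bw(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).copy()
                            if np.ndim(g) else np.full_like(self.data, g))
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accum(np.broadcast_to(gg, self.data.shape).copy())
        out._backward = bw
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # ------------------------------------------------------------- structural
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape), requires_grad=self.requires_grad,
                     parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accum(g.reshape(self.data.shape))
        out._backward = bw
        return out

    def transpose(self, *axes):
        out = Tensor(self.data.transpose(axes), requires_grad=self.requires_grad,
                     parents=(self,))
        inv = np.argsort(axes)

        def bw(g):
            if self.requires_grad:
                self._accum(g.transpose(inv))
        out._backward = bw
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], requires_grad=self.requires_grad,
                     parents=(self,))

        def bw(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accum(full)
        out._backward = bw
        return out

    def pad2d(self, pad: int, mode: str = "constant"):
        """Pad the last two axes by ``pad`` on each side."""
        if pad == 0:
            return self
        width = [(0, 0)] * (self.data.ndim - 2) + [(pad, pad), (pad, pad)]
        out = Tensor(np.pad(self.data, width, mode=mode),
                     requires_grad=self.requires_grad, parents=(self,))

        def bw(g):
            if self.requires_grad:
                sl = (Ellipsis, slice(pad, g.shape[-2] - pad),
                      slice(pad, g.shape[-1] - pad))
                if mode == "constant":
                    self._accum(g[sl])
                else:  # pragma: no cover - reflect pad is inference-only
                    raise NotImplementedError
        out._backward = bw
        return out

    # ------------------------------------------------------------ softmax etc.
    def log_softmax(self, axis: int = 1):
        x = self.data
        m = x.max(axis=axis, keepdims=True)
        z = x - m
        lse = np.log(np.exp(z).sum(axis=axis, keepdims=True))
        ls = z - lse
        out = Tensor(ls, requires_grad=self.requires_grad, parents=(self,))
        sm = np.exp(ls)

        def bw(g):
            if self.requires_grad:
                self._accum(g - sm * g.sum(axis=axis, keepdims=True))
        out._backward = bw
        return out

    def softmax(self, axis: int = 1):
        return self.log_softmax(axis=axis).exp()


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


_NO_GRAD = False


class no_grad:
    """Context manager: tensors created inside carry no graph, so nothing
    inside can receive gradients (used for pseudo-label forwards)."""

    def __enter__(self):
        global _NO_GRAD
        self._prev = _NO_GRAD
        _NO_GRAD = True
        return self

    def __exit__(self, *exc):
        global _NO_GRAD
        _NO_GRAD = self._prev
        return False


# --------------------------------------------------------------------- conv2d
def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None, stride: int = 1,
           padding: int = 0) -> Tensor:
    """2-D convolution (cross-correlation), NCHW layout, square kernel."""
    xd = x.data
    if padding:
        xd = np.pad(xd, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    n, c, hp, wp = xd.shape
    f, cw, kh, kw = weight.data.shape
    if cw != c:
        raise ValueError(f"channel mismatch: input {c}, weight {cw}")
    ho = (hp - kh) // stride + 1
    wo = (wp - kw) // stride + 1
    win = np.lib.stride_tricks.sliding_window_view(xd, (kh, kw), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]            # (n, c, ho, wo, kh, kw)
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, c * kh * kw)
    wmat = weight.data.reshape(f, c * kh * kw)
    out_mat = cols @ wmat.T
    if bias is not None:
        out_mat = out_mat + bias.data
    out_data = out_mat.reshape(n, ho, wo, f).transpose(0, 3, 1, 2)
    req = x.requires_grad or weight.requires_grad or (
        bias is not None and bias.requires_grad)
    parents = (x, weight) + ((bias,) if bias is not None else ())
    out = Tensor(out_data, requires_grad=req, parents=parents)

    def bw(g):
        gm = g.transpose(0, 2, 3, 1).reshape(n * ho * wo, f)
        if weight.requires_grad:
            weight._accum((gm.T @ cols).reshape(f, c, kh, kw))
        if bias is not None and bias.requires_grad:
            bias._accum(gm.sum(axis=0))
        if x.requires_grad:
            dcols = (gm @ wmat).reshape(n, ho, wo, c, kh, kw)
            dxp = np.zeros((n, c, hp, wp), dtype=DTYPE)
            for i in range(kh):
                for j in range(kw):
                    dxp[:, :, i:i + stride * ho:stride,
                        j:j + stride * wo:stride] += dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
            if padding:
                dxp = dxp[:, :, padding:hp - padding, padding:wp - padding]
            x._accum(dxp)
    out._backward = bw
    return out


# ------------------------------------------------------------------ batchnorm
def batch_norm2d(x: Tensor, gamma: Tensor, beta: Tensor, running_mean: np.ndarray,
                 running_var: np.ndarray, training: bool, momentum: float = 0.1,
                 eps: float = 1e-5) -> Tensor:
    """Batch normalization over (N, H, W) per channel; updates running stats
    in place when ``training``."""
    xd = x.data
    c = xd.shape[1]
    if training:
        mu = xd.mean(axis=(0, 2, 3))
        var = xd.var(axis=(0, 2, 3))
        running_mean *= (1.0 - momentum)
        running_mean += momentum * mu
        running_var *= (1.0 - momentum)
        running_var += momentum * var
    else:
        mu, var = running_mean, running_var
    mu = mu.astype(xd.dtype)
    inv_std = (1.0 / np.sqrt(var + eps)).astype(xd.dtype)
    xhat = (xd - mu.reshape(1, c, 1, 1)) * inv_std.reshape(1, c, 1, 1)
    out_data = gamma.data.reshape(1, c, 1, 1) * xhat + beta.data.reshape(1, c, 1, 1)
    req = x.requires_grad or gamma.requires_grad or beta.requires_grad
    out = Tensor(out_data, requires_grad=req, parents=(x, gamma, beta))

    def bw(g):
        if gamma.requires_grad:
            gamma._accum((g * xhat).sum(axis=(0, 2, 3)))
        if beta.requires_grad:
            beta._accum(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gsc = g * gamma.data.reshape(1, c, 1, 1)
            if training:
                m = xd.shape[0] * xd.shape[2] * xd.shape[3]
                s1 = gsc.sum(axis=(0, 2, 3), keepdims=True)
                s2 = (gsc * xhat).sum(axis=(0, 2, 3), keepdims=True)
                dx = (gsc - s1 / m - xhat * s2 / m) * inv_std.reshape(1, c, 1, 1)
            else:
                dx = gsc * inv_std.reshape(1, c, 1, 1)
            x._accum(dx)
    out._backward = bw
    return out


# ------------------------------------------------------------ bilinear resize
def _interp_matrix(n_out: int, n_in: int) -> np.ndarray:
    """Row-stochastic matrix mapping n_in samples to n_out via linear
    interpolation with top-left grid alignment: src = dst * n_in / n_out.

    With integer upsampling factor s, out[k*s] == in[k] exactly.
    """
    A = np.zeros((n_out, n_in), dtype=DTYPE)
    src = np.arange(n_out) * (n_in / n_out)
    lo = np.clip(np.floor(src).astype(int), 0, n_in - 1)
    hi = np.minimum(lo + 1, n_in - 1)
    frac = src - lo
    A[np.arange(n_out), lo] += 1.0 - frac
    A[np.arange(n_out), hi] += frac
    return A


def resize_bilinear(x: Tensor, out_hw: tuple[int, int]) -> Tensor:
    """Separable bilinear resize of the last two axes to ``out_hw``."""
    h_in, w_in = x.data.shape[-2:]
    h_out, w_out = out_hw
    if (h_in, w_in) == (h_out, w_out):
        return x
    Ah = _interp_matrix(h_out, h_in)
    Aw = _interp_matrix(w_out, w_in)
    out_data = np.einsum("ij,...jk,lk->...il", Ah, x.data, Aw, optimize=True)
    out = Tensor(out_data, requires_grad=x.requires_grad, parents=(x,))

    def bw(g):
        if x.requires_grad:
            x._accum(np.einsum("ij,...jk,lk->...il", Ah.T, g, Aw.T, optimize=True))
    out._backward = bw
    return out


def dropout_channels(x: Tensor, drop_rate: float, rng: np.random.Generator) -> Tensor:
    """Channel-wise dropout with inverse-rate rescaling (expectation-preserving)."""
    if drop_rate == 0.0:
        return x
    if not 0.0 <= drop_rate < 1.0:
        raise ValueError("drop_rate must be in [0, 1)")
    n, c = x.data.shape[:2]
    keep = (rng.random((n, c)) >= drop_rate).astype(DTYPE)
    scale = keep.reshape(n, c, 1, 1) / (1.0 - drop_rate)
    out = Tensor(x.data * scale, requires_grad=x.requires_grad, parents=(x,))

    def bw(g):
        if x.requires_grad:
            x._accum(g * scale)
    out._backward = bw
    return out
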