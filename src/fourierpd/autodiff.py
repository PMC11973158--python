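"""Minimal reverse-mode automatic differentiation over real numpy arrays.

The unrolled primal-dual models need gradients through 2D convolutions,
split nonlinearities, channel concatenation/slicing, residual additions and
centered Fourier transforms.  This module provides exactly those operations
on a small :class:`Tensor` graph, in float64.

Complex-valued feature maps are represented as *pairs* of real tensors
(real part, imaginary part); the complex layers in :mod:`fourierpd.complexnn`
compose the real operations below.  The centered FFT is complex-linear, so
its reverse-mode rule is its adjoint — the inverse centered FFT — applied to
the complex cotangent.
"""

from __future__ import annotations

import numpy as np

from .kspace import fft2c, ifft2c

__all__ = [
    "Tensor",
    "add",
    "sub",
    "scale",
    "mul_const",
    "conv2d",
    "relu",
    "concat",
    "channel_slice",
    "avg_pool2",
    "upsample2",
    "abs_sum",
    "fft2c_pair",
    "ifft2c_pair",
    "Adam",
]


class Tensor:
    """A node in the computation graph holding a float64 array.

    ``_backward(grad)`` accumulates the cotangent into the parents' ``.grad``.
    """

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(grad, dtype=np.float64)
        else:
            self.grad += grad

    def backward(self) -> None:
        """Backpropagate from this (scalar) tensor through the graph."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss tensor")
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
                if id(p) not in seen and p.requires_grad:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None


def _unary(x, data, bwd):
    return Tensor(data, parents=(x,), backward=bwd)


def add(a: Tensor, b: Tensor) -> Tensor:
    if a.shape != b.shape:
        raise ValueError(f"add: shape mismatch {a.shape} vs {b.shape}")

    def bwd(g):
        if a.requires_grad:
            a._accumulate(g)
        if b.requires_grad:
            b._accumulate(g)

    return Tensor(a.data + b.data, parents=(a, b), backward=bwd)


def sub(a: Tensor, b: Tensor) -> Tensor:
    if a.shape != b.shape:
        raise ValueError(f"sub: shape mismatch {a.shape} vs {b.shape}")

    def bwd(g):
        if a.requires_grad:
            a._accumulate(g)
        if b.requires_grad:
            b._accumulate(-g)

    return Tensor(a.data - b.data, parents=(a, b), backward=bwd)


def scale(x: Tensor, s: float) -> Tensor:
    return _unary(x, x.data * s, lambda g: x.requires_grad and x._accumulate(g * s))


def mul_const(x: Tensor, c: np.ndarray) -> Tensor:
    """Elementwise product with a constant (non-differentiated) array."""
    c = np.asarray(c, dtype=np.float64)
    return _unary(x, x.data * c, lambda g: x.requires_grad and x._accumulate(g * c))


def relu(x: Tensor) -> Tensor:
    pos = x.data > 0
    return _unary(x, np.where(pos, x.data, 0.0), lambda g: x.requires_grad and x._accumulate(g * pos))


def abs_sum(x: Tensor) -> Tensor:
    """Sum of absolute values (building block of the complex L1 loss)."""
    sgn = np.sign(x.data)
    return _unary(
        x, np.array(np.abs(x.data).sum()), lambda g: x.requires_grad and x._accumulate(g * sgn)
    )


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(lo, hi)
                t._accumulate(g[tuple(idx)])

    return Tensor(data, parents=tuple(tensors), backward=bwd)


def channel_slice(x: Tensor, lo: int, hi: int) -> Tensor:
    """Slice channels ``lo:hi`` of an (N, C, H, W) tensor."""

    def bwd(g):
        if x.requires_grad:
            full = np.zeros_like(x.data)
            full[:, lo:hi] = g
            x._accumulate(full)

    return Tensor(x.data[:, lo:hi], parents=(x,), backward=bwd)


# ---------------------------------------------------------------------------
# Convolution (stride 1, symmetric zero padding) via im2col
# ---------------------------------------------------------------------------


def _im2col(xp: np.ndarray, kh: int, kw: int) -> np.ndarray:
    """View of padded input as (N, C, kh, kw, Ho, Wo) sliding windows."""
    n, c, h, w = xp.shape
    ho, wo = h - kh + 1, w - kw + 1
    s = xp.strides
    return np.lib.stride_tricks.as_strided(
        xp, (n, c, kh, kw, ho, wo), (s[0], s[1], s[2], s[3], s[2], s[3])
    )


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, padding: int = 0) -> Tensor:
    """2D cross-correlation: out[n,o] = sum_{c,u,v} w[o,c,u,v] * x[n,c,i+u,j+v].

    ``x``: (N, Cin, H, W); ``w``: (Cout, Cin, kh, kw); ``b``: (Cout,) or None.
    """
    n, cin, h, wdt = x.shape
    cout, cin_w, kh, kw = w.shape
    if cin != cin_w:
        raise ValueError(f"conv2d: input has {cin} channels, kernel expects {cin_w}")
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    cols = _im2col(xp, kh, kw)  # (N, C, kh, kw, Ho, Wo)
    ho, wo = cols.shape[4], cols.shape[5]
    cols2 = cols.reshape(n, cin * kh * kw, ho * wo)
    wmat = w.data.reshape(cout, cin * kh * kw)
    out = np.matmul(wmat, cols2).reshape(n, cout, ho, wo)
    if b is not None:
        out = out + b.data[None, :, None, None]

    parents = (x, w) if b is None else (x, w, b)

    def bwd(g):
        gmat = g.reshape(n, cout, ho * wo)
        if w.requires_grad:
            gw = np.matmul(gmat, cols2.transpose(0, 2, 1)).sum(axis=0).reshape(w.shape)
            w._accumulate(gw)
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            # scatter W^T g back through the sliding windows (col2im)
            dcols = np.matmul(wmat.T, gmat).reshape(n, cin, kh, kw, ho, wo)
            dxp = np.zeros_like(xp)
            for u in range(kh):
                for v in range(kw):
                    dxp[:, :, u : u + ho, v : v + wo] += dcols[:, :, u, v]
            if padding:
                dxp = dxp[:, :, padding:-padding, padding:-padding]
            x._accumulate(dxp)

    return Tensor(out, parents=parents, backward=bwd)


def avg_pool2(x: Tensor) -> Tensor:
    """2x2 average pooling (even spatial dims required)."""
    n, c, h, w = x.shape
    if h % 2 or w % 2:
        raise ValueError(f"avg_pool2 needs even spatial dims, got {h}x{w}")
    out = x.data.reshape(n, c, h // 2, 2, w // 2, 2).mean(axis=(3, 5))

    def bwd(g):
        if x.requires_grad:
            x._accumulate(np.repeat(np.repeat(g, 2, axis=2), 2, axis=3) * 0.25)

    return Tensor(out, parents=(x,), backward=bwd)


def upsample2(x: Tensor) -> Tensor:
    """Nearest-neighbour 2x upsampling."""
    out = np.repeat(np.repeat(x.data, 2, axis=2), 2, axis=3)

    def bwd(g):
        if x.requires_grad:
            n, c, h, w = x.shape
            x._accumulate(g.reshape(n, c, h, 2, w, 2).sum(axis=(3, 5)))

    return Tensor(out, parents=(x,), backward=bwd)


# ---------------------------------------------------------------------------
# Centered orthonormal FFT on (real, imag) tensor pairs
# ---------------------------------------------------------------------------


def _fft_pair(xr: Tensor, xi: Tensor, inverse: bool) -> tuple[Tensor, Tensor]:
    fwd = ifft2c if inverse else fft2c
    adj = fft2c if inverse else ifft2c  # adjoint of a unitary map is its inverse
    y = fwd(xr.data + 1j * xi.data)

    def bwd_r(g):
        gc = adj(g)  # contribution of the real output's cotangent
        if xr.requires_grad:
            xr._accumulate(gc.real)
        if xi.requires_grad:
            xi._accumulate(gc.imag)

    def bwd_i(g):
        gc = adj(1j * g)
        if xr.requires_grad:
            xr._accumulate(gc.real)
        if xi.requires_grad:
            xi._accumulate(gc.imag)

    yr = Tensor(y.real, parents=(xr, xi), backward=bwd_r)
    yi = Tensor(y.imag, parents=(xr, xi), backward=bwd_i)
    return yr, yi


def fft2c_pair(xr: Tensor, xi: Tensor) -> tuple[Tensor, Tensor]:
    """Differentiable centered orthonormal FFT of a (real, imag) pair."""
    return _fft_pair(xr, xi, inverse=False)


def ifft2c_pair(xr: Tensor, xi: Tensor) -> tuple[Tensor, Tensor]:
    """Differentiable centered orthonormal inverse FFT of a (real, imag) pair."""
    return _fft_pair(xr, xi, inverse=True)


class Adam:
    """Adam optimizer over a list of parameter tensors."""

    def __init__(
        self,
        params: list[Tensor],
        lr: float = 1e-4,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-9,
    ):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
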