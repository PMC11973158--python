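"""Complex-valued neural-network primitives.

A complex convolution with kernel ``w = w_r + i w_i`` applied to input
``x = x_r + i x_i`` expands, by bilinearity, into four real convolutions::

    C_r = w_r * x_r - w_i * x_i
    C_i = w_i * x_r + w_r * x_i

equivalently the 2x2 real block-matrix form [[w_r, -w_i], [w_i, w_r]] acting
on (x_r, x_i).  Working with the complex product directly — rather than
feeding real and imaginary parts as independent channels to a real network —
preserves the algebraic structure of complex MR data.

The default nonlinearity is the split rectifier (CReLU): ReLU applied
independently to real and imaginary parts.  The training loss is the
complex L1 / mean-absolute-error: mean over voxels of
``|y_r - yhat_r| + |y_i - yhat_i|``.

Two surfaces are provided: functional operations on complex numpy arrays
(for analysis and testing) and :class:`ComplexConv2d` layers on autodiff
tensor pairs (for the unrolled models).
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

__all__ = [
    "complex_conv2d",
    "complex_activation",
    "complex_l1_loss",
    "ComplexConv2d",
    "complex_l1_loss_t",
    "crelu_pair",
]


# ---------------------------------------------------------------------------
# Functional surface (complex numpy arrays)
# ---------------------------------------------------------------------------


def complex_conv2d(
    x: np.ndarray,
    w: np.ndarray,
    bias: np.ndarray | None = None,
    padding: int = 0,
) -> np.ndarray:
    """Complex-valued 2D cross-correlation.

    Parameters
    ----------
    x
        Complex input of shape (N, C_in, H, W).
    w
        Complex kernel of shape (C_out, C_in, kh, kw).
    bias
        Optional complex per-channel bias of shape (C_out,).
    padding
        Symmetric zero padding.

    Returns
    -------
    numpy.ndarray
        Complex feature map of shape (N, C_out, H', W').
    """
    x = np.asarray(x, dtype=np.complex128)
    w = np.asarray(w, dtype=np.complex128)
    if x.ndim != 4 or w.ndim != 4:
        raise ValueError("complex_conv2d expects x:(N,C,H,W) and w:(O,C,kh,kw)")
    if x.shape[1] != w.shape[1]:
        raise ValueError(f"channel mismatch: input {x.shape[1]} vs kernel {w.shape[1]}")
    xr, xi = Tensor(x.real), Tensor(x.imag)
    wr, wi = Tensor(w.real), Tensor(w.imag)
    cr = ad.sub(ad.conv2d(xr, wr, padding=padding), ad.conv2d(xi, wi, padding=padding))
    ci = ad.add(ad.conv2d(xr, wi, padding=padding), ad.conv2d(xi, wr, padding=padding))
    out = cr.data + 1j * ci.data
    if bias is not None:
        out = out + np.asarray(bias, dtype=np.complex128)[None, :, None, None]
    return out


def complex_activation(x: np.ndarray, kind: str = "crelu") -> np.ndarray:
    """Split activation applied independently to real and imaginary parts.

    ``kind="crelu"`` (default) rectifies each part; ``kind="identity"`` is a
    no-op switch for ablation.
    """
    x = np.asarray(x, dtype=np.complex128)
    if kind == "crelu":
        return np.maximum(x.real, 0.0) + 1j * np.maximum(x.imag, 0.0)
    if kind == "identity":
        return x
    raise ValueError(f"unknown activation kind {kind!r}")


def complex_l1_loss(y_hat: np.ndarray, y: np.ndarray) -> float:
    """Complex L1 / mean absolute error between prediction and ground truth.

    The mean runs over every voxel of every sample, so the loss scale is
    independent of image resolution and batch size.  Zero iff the arrays are
    identical; always nonnegative.
    """
    y_hat = np.asarray(y_hat, dtype=np.complex128)
    y = np.asarray(y, dtype=np.complex128)
    if y_hat.shape != y.shape:
        raise ValueError(f"shape mismatch: {y_hat.shape} vs {y.shape}")
    return float(
        np.mean(np.abs(y.real - y_hat.real) + np.abs(y.imag - y_hat.imag))
    )


# ---------------------------------------------------------------------------
# Layer surface (autodiff tensor pairs)
# ---------------------------------------------------------------------------


def crelu_pair(xr: Tensor, xi: Tensor) -> tuple[Tensor, Tensor]:
    """Split rectifier on a (real, imag) tensor pair."""
    return ad.relu(xr), ad.relu(xi)


def complex_l1_loss_t(
    yr: Tensor, yi: Tensor, tr: np.ndarray, ti: np.ndarray
) -> Tensor:
    """Differentiable complex L1 loss against a constant complex target."""
    n = yr.data.size
    dr = ad.sub(yr, Tensor(tr))
    di = ad.sub(yi, Tensor(ti))
    return ad.scale(ad.add(ad.abs_sum(dr), ad.abs_sum(di)), 1.0 / n)


class ComplexConv2d:
    """Complex 2D convolution layer with independent real/imag kernels.

    Kernels are initialized from a zero-mean normal whose variance is halved
    relative to the real-valued He fan-in rule, so the *complex* output
    variance matches the real-valued convention (each of w_r, w_i carries
    half the energy).  ``init_scale`` shrinks the init (used for the last
    layer of residual blocks so the untrained unrolled net starts near the
    identity).
    """

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        rng: np.random.Generator,
        bias: bool = True,
        init_scale: float = 1.0,
    ):
        k = kernel_size
        fan_in = in_channels * k * k
        std = init_scale * np.sqrt(1.0 / (2.0 * fan_in))
        self.w_r = Tensor(rng.normal(0.0, std, (out_channels, in_channels, k, k)), requires_grad=True)
        self.w_i = Tensor(rng.normal(0.0, std, (out_channels, in_channels, k, k)), requires_grad=True)
        if bias:
            self.b_r = Tensor(np.zeros(out_channels), requires_grad=True)
            self.b_i = Tensor(np.zeros(out_channels), requires_grad=True)
        else:
            self.b_r = self.b_i = None
        self.padding = k // 2

    def __call__(self, xr: Tensor, xi: Tensor) -> tuple[Tensor, Tensor]:
        p = self.padding
        cr = ad.sub(
            ad.conv2d(xr, self.w_r, self.b_r, padding=p),
            ad.conv2d(xi, self.w_i, padding=p),
        )
        ci = ad.add(
            ad.conv2d(xr, self.w_i, self.b_i, padding=p),
            ad.conv2d(xi, self.w_r, padding=p),
        )
        return cr, ci

    @property
    def parameters(self) -> list[Tensor]:
        ps = [self.w_r, self.w_i]
        if self.b_r is not None:
            ps += [self.b_r, self.b_i]
        return ps
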