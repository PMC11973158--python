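"""Unrolled complex-valued primal-dual reconstruction networks.

Both models unroll a primal-dual optimization scheme into ``n_iterations``
learned stages, replacing the proximal operators with complex-valued
convolutional blocks.  State is carried in two memories:

* the *primal* memory — ``n_primal`` complex images (image space);
* the *dual* memory — ``n_dual`` complex k-space grids (measurement space).

Each iteration first updates the dual memory from the concatenation of
(dual memory, FFT of the current primal estimate, measured undersampled
k-space) through a complex fully-convolutional block with a residual
connection — the dual block predicts missing k-space frequencies.  It then
updates the primal memory from (primal memory, inverse FFT of the first
dual channel) through the primal block — a complex fully-convolutional
block in Fourier-PDNet, a complex UNet in Fourier-PDUNet — which removes
image-space artefacts.  The reconstruction is the first primal channel.

The primal memory is initialized with the zero-filled reconstruction
replicated across channels and the dual memory with zeros, so a network
whose weights are all zero is exactly the identity on the zero-filled
reconstruction (every block output enters through a residual add).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .complexnn import ComplexConv2d, crelu_pair
from .kspace import SamplingMask, ifft2c

__all__ = ["ReconModelConfig", "FourierPD", "build_model"]


@dataclass(frozen=True)
class ReconModelConfig:
    """Hyperparameters of the unrolled networks.

    Defaults follow the learned primal-dual lineage (10 iterations, 5 primal
    and 5 dual memory channels, 32 filters, 3x3 kernels, 3 conv layers per
    block, UNet depth 3); desk-scale tests shrink to 3 iterations / 8
    filters.  ``unet_depth`` applies to the fourier_pdunet variant only.
    """

    variant: str = "fourier_pdnet"  # "fourier_pdnet" | "fourier_pdunet"
    n_iterations: int = 10
    n_primal: int = 5
    n_dual: int = 5
    n_filters: int = 32
    kernel_size: int = 3
    n_conv_layers: int = 3
    unet_depth: int = 3
    bias: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.variant not in ("fourier_pdnet", "fourier_pdunet"):
            raise ValueError(f"unknown variant {self.variant!r}")
        for name in ("n_iterations", "n_primal", "n_dual", "n_filters", "kernel_size", "n_conv_layers"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.variant == "fourier_pdunet" and self.unet_depth < 1:
            raise ValueError("unet_depth must be >= 1 for fourier_pdunet")

    def to_dict(self) -> dict:
        return {
            "variant": self.variant,
            "n_iterations": self.n_iterations,
            "n_primal": self.n_primal,
            "n_dual": self.n_dual,
            "n_filters": self.n_filters,
            "kernel_size": self.kernel_size,
            "n_conv_layers": self.n_conv_layers,
            "unet_depth": self.unet_depth,
            "bias": self.bias,
            "seed": self.seed,
        }


class _ComplexConvBlock:
    """Complex fully-convolutional block: (conv + CReLU) x (L-1), then conv.

    The final layer is initialized 10x smaller so the residual update starts
    near zero while gradients still reach every parameter.
    """

    def __init__(self, in_ch, out_ch, n_filters, n_layers, k, rng, bias):
        self.layers = []
        ch = in_ch
        for _ in range(max(n_layers - 1, 0)):
            self.layers.append(ComplexConv2d(ch, n_filters, k, rng, bias=bias))
            ch = n_filters
        self.head = ComplexConv2d(ch, out_ch, k, rng, bias=bias, init_scale=0.1)

    def __call__(self, xr, xi):
        for layer in self.layers:
            xr, xi = crelu_pair(*layer(xr, xi))
        return self.head(xr, xi)

    @property
    def parameters(self):
        ps = []
        for layer in self.layers:
            ps += layer.parameters
        return ps + self.head.parameters


class _ComplexUNet:
    """Small complex UNet: per-level conv + CReLU, 2x pooling, skip concats."""

    def __init__(self, in_ch, out_ch, n_filters, depth, k, rng, bias):
        self.depth = depth
        self.enc = []
        ch = in_ch
        for _ in range(depth):
            self.enc.append(ComplexConv2d(ch, n_filters, k, rng, bias=bias))
            ch = n_filters
        self.bottom = ComplexConv2d(n_filters, n_filters, k, rng, bias=bias)
        self.dec = [
            ComplexConv2d(2 * n_filters, n_filters, k, rng, bias=bias) for _ in range(depth)
        ]
        self.head = ComplexConv2d(n_filters, out_ch, k, rng, bias=bias, init_scale=0.1)

    def __call__(self, xr, xi):
        skips = []
        for conv in self.enc:
            xr, xi = crelu_pair(*conv(xr, xi))
            skips.append((xr, xi))
            xr, xi = ad.avg_pool2(xr), ad.avg_pool2(xi)
        xr, xi = crelu_pair(*self.bottom(xr, xi))
        for conv, (sr, si) in zip(self.dec, reversed(skips)):
            xr, xi = ad.upsample2(xr), ad.upsample2(xi)
            xr = ad.concat([xr, sr], axis=1)
            xi = ad.concat([xi, si], axis=1)
            xr, xi = crelu_pair(*conv(xr, xi))
        return self.head(xr, xi)

    @property
    def parameters(self):
        ps = []
        for conv in self.enc + [self.bottom] + self.dec + [self.head]:
            ps += conv.parameters
        return ps


class FourierPD:
    """Fourier-PDNet / Fourier-PDUNet backbone (variant set by the config).

    Weights are unshared across the unrolled iterations.  ``forward`` builds
    the autodiff graph (used in training); ``predict`` is the inference
    convenience returning a complex numpy image.
    """

    def __init__(self, config: ReconModelConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        c = config
        self.dual_blocks = [
            _ComplexConvBlock(
                c.n_dual + 2, c.n_dual, c.n_filters, c.n_conv_layers, c.kernel_size, rng, c.bias
            )
            for _ in range(c.n_iterations)
        ]
        if c.variant == "fourier_pdnet":
            self.primal_blocks = [
                _ComplexConvBlock(
                    c.n_primal + 1, c.n_primal, c.n_filters, c.n_conv_layers, c.kernel_size, rng, c.bias
                )
                for _ in range(c.n_iterations)
            ]
        else:
            self.primal_blocks = [
                _ComplexUNet(
                    c.n_primal + 1, c.n_primal, c.n_filters, c.unet_depth, c.kernel_size, rng, c.bias
                )
                for _ in range(c.n_iterations)
            ]

    # -- parameters -------------------------------------------------------

    @property
    def parameters(self) -> list[Tensor]:
        ps = []
        for b in self.dual_blocks + self.primal_blocks:
            ps += b.parameters
        return ps

    @property
    def parameter_count(self) -> int:
        return sum(p.data.size for p in self.parameters)

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters]

    def load_state_arrays(self, arrays: list[np.ndarray]) -> None:
        params = self.parameters
        if len(arrays) != len(params):
            raise ValueError(f"expected {len(params)} arrays, got {len(arrays)}")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError(f"shape mismatch {p.data.shape} vs {a.shape}")
            p.data = np.asarray(a, dtype=np.float64).copy()

    def zero_weights(self) -> None:
        for p in self.parameters:
            p.data[...] = 0.0

    # -- forward ----------------------------------------------------------

    @staticmethod
    def _as_batch(measured_k: np.ndarray) -> np.ndarray:
        measured_k = np.asarray(measured_k, dtype=np.complex128)
        if measured_k.ndim == 2:
            measured_k = measured_k[None]
        if measured_k.ndim != 3:
            raise ValueError("measured k-space must be (H, W) or (N, H, W)")
        return measured_k

    def forward(
        self, measured_k: np.ndarray, mask: SamplingMask | np.ndarray
    ) -> tuple[Tensor, Tensor]:
        """Unrolled forward pass; returns the (real, imag) output tensors.

        ``measured_k`` must be zero-filled (exactly zero off-mask).
        """
        grid = mask.grid if isinstance(mask, SamplingMask) else np.asarray(mask)
        measured_k = self._as_batch(measured_k)
        off_mask = measured_k * (1 - grid)
        if off_mask.size and np.abs(off_mask).max() > 0:
            raise ValueError("measured k-space carries energy off the sampling mask")

        c = self.config
        mk = measured_k[:, None]  # (N, 1, H, W)
        mr, mi = Tensor(mk.real), Tensor(mk.imag)
        zf = ifft2c(mk)
        primal_r = Tensor(np.repeat(zf.real, c.n_primal, axis=1))
        primal_i = Tensor(np.repeat(zf.imag, c.n_primal, axis=1))
        dual_r = Tensor(np.zeros_like(np.repeat(mk.real, c.n_dual, axis=1)))
        dual_i = Tensor(np.zeros_like(dual_r.data))

        est_ch = 1 if c.n_primal > 1 else 0  # second primal iterate feeds the dual
        for dual_block, primal_block in zip(self.dual_blocks, self.primal_blocks):
            pr = ad.channel_slice(primal_r, est_ch, est_ch + 1)
            pi = ad.channel_slice(primal_i, est_ch, est_ch + 1)
            fr, fi = ad.fft2c_pair(pr, pi)
            din_r = ad.concat([dual_r, fr, mr], axis=1)
            din_i = ad.concat([dual_i, fi, mi], axis=1)
            ur, ui = dual_block(din_r, din_i)
            dual_r, dual_i = ad.add(dual_r, ur), ad.add(dual_i, ui)

            dr = ad.channel_slice(dual_r, 0, 1)
            di = ad.channel_slice(dual_i, 0, 1)
            br, bi = ad.ifft2c_pair(dr, di)
            pin_r = ad.concat([primal_r, br], axis=1)
            pin_i = ad.concat([primal_i, bi], axis=1)
            vr, vi = primal_block(pin_r, pin_i)
            primal_r, primal_i = ad.add(primal_r, vr), ad.add(primal_i, vi)

        return (
            ad.channel_slice(primal_r, 0, 1),
            ad.channel_slice(primal_i, 0, 1),
        )

    def predict(self, measured_k: np.ndarray, mask: SamplingMask | np.ndarray) -> np.ndarray:
        """Backbone reconstruction as a complex array (no data consistency)."""
        squeeze = np.asarray(measured_k).ndim == 2
        yr, yi = self.forward(measured_k, mask)
        out = (yr.data + 1j * yi.data)[:, 0]
        return out[0] if squeeze else out


def build_model(config: ReconModelConfig) -> FourierPD:
    """Construct the backbone for a config (both variants)."""
    return FourierPD(config)
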