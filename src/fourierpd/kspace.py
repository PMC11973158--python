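"""Centered orthonormal Fourier transforms and variable-density Cartesian undersampling.

MRI data live in k-space, the 2D spatial-frequency domain.  Retrospective
undersampling multiplies fully sampled k-space by a binary mask that keeps a
fraction ``f`` of the points (theoretical acceleration factor ``1/f``).  Two
mask families are provided:

* ``varden1d`` — whole readout lines are kept along the phase-encoding
  direction; a contiguous block of centre lines is always acquired and the
  remaining lines are drawn with probability proportional to a 1D normal
  density centred on the k-space centre.
* ``varden2d`` — individual k-space points are kept; a fully sampled central
  disc covers a fixed fraction of k-space and the rest is drawn from a 2D
  normal density.

All transforms here are centered (DC component at ``(rows//2, cols//2)``,
0-based) and orthonormally scaled, so Parseval's identity holds exactly and
the adjoint of ``fft2c`` is ``ifft2c``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "fft2c",
    "ifft2c",
    "SamplingMask",
    "make_varden1d_mask",
    "make_varden2d_mask",
    "undersample",
    "theoretical_acceleration",
]


def fft2c(image: np.ndarray) -> np.ndarray:
    """Centered, orthonormal 2D FFT of the trailing two axes.

    Parameters
    ----------
    image
        Complex (or real) array; the last two axes are transformed.

    Returns
    -------
    numpy.ndarray
        Complex k-space grid with the DC component at the grid centre.
    """
    image = np.asarray(image)
    if image.ndim < 2:
        raise ValueError(f"fft2c needs at least a 2D array, got ndim={image.ndim}")
    axes = (-2, -1)
    return np.fft.fftshift(
        np.fft.fft2(np.fft.ifftshift(image, axes=axes), axes=axes, norm="ortho"),
        axes=axes,
    )


def ifft2c(kspace: np.ndarray) -> np.ndarray:
    """Inverse of :func:`fft2c` (centered, orthonormal)."""
    kspace = np.asarray(kspace)
    if kspace.ndim < 2:
        raise ValueError(f"ifft2c needs at least a 2D array, got ndim={kspace.ndim}")
    axes = (-2, -1)
    return np.fft.fftshift(
        np.fft.ifft2(np.fft.ifftshift(kspace, axes=axes), axes=axes, norm="ortho"),
        axes=axes,
    )


def _round_half_away(x: float) -> int:
    """Round half away from zero (3.5 -> 4, not banker's rounding)."""
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


@dataclass(frozen=True)
class SamplingMask:
    """Binary k-space acquisition pattern plus its generation metadata.

    Attributes
    ----------
    grid
        2D uint8 array, 1 where k-space is acquired.
    kind
        ``"varden1d"``, ``"varden2d"`` or ``"custom"``.
    fraction
        Sampled fraction of k-space; ``popcount(grid) == round(fraction * grid.size)``.
    seed
        RNG seed the mask was generated from (-1 for custom masks).
    params
        Extra generation parameters (centre_lines / centre_fraction / sigma).
    """

    grid: np.ndarray
    kind: str
    fraction: float
    seed: int = -1
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        grid = np.asarray(self.grid)
        if grid.ndim != 2:
            raise ValueError("mask grid must be 2D")
        object.__setattr__(self, "grid", grid.astype(np.uint8))

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape

    @property
    def n_sampled(self) -> int:
        return int(self.grid.sum())

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "shape": list(self.shape),
            "fraction": self.fraction,
            "seed": self.seed,
            "params": dict(self.params),
        }


def make_varden1d_mask(
    shape: tuple[int, int],
    fraction: float,
    centre_lines: int = 8,
    seed: int = 0,
    sigma: float | None = None,
) -> SamplingMask:
    """1D variable-density Cartesian mask (full readout lines).

    Exactly ``round(fraction * rows)`` phase-encoding lines are kept.  The
    ``centre_lines`` central lines are always acquired; the others are drawn
    without replacement with probability proportional to a 1D normal density
    centred on the k-space centre (default ``sigma = rows / 6``).

    Rows index the phase-encoding direction; a sampled line spans all columns.
    """
    rows, cols = shape
    if not 0.0 < fraction <= 1.0:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    n_lines = _round_half_away(fraction * rows)
    if centre_lines > n_lines:
        raise ValueError(
            f"centre_lines={centre_lines} exceeds the sampled-line budget {n_lines}"
        )
    if sigma is None:
        sigma = rows / 6.0

    centre = rows // 2
    start = centre - centre_lines // 2
    centre_idx = np.arange(start, start + centre_lines)

    rng = np.random.default_rng(seed)
    remaining = np.setdiff1d(np.arange(rows), centre_idx)
    n_extra = n_lines - centre_lines
    if n_extra > 0:
        w = np.exp(-0.5 * ((remaining - centre) / sigma) ** 2)
        w = w / w.sum()
        extra = rng.choice(remaining, size=n_extra, replace=False, p=w)
    else:
        extra = np.empty(0, dtype=int)

    grid = np.zeros((rows, cols), dtype=np.uint8)
    grid[np.concatenate([centre_idx, extra]), :] = 1
    return SamplingMask(
        grid=grid,
        kind="varden1d",
        fraction=fraction,
        seed=seed,
        params={"centre_lines": centre_lines, "sigma": sigma},
    )


def make_varden2d_mask(
    shape: tuple[int, int],
    fraction: float,
    centre_fraction: float = 0.025,
    seed: int = 0,
    sigma: float | None = None,
) -> SamplingMask:
    """2D variable-density Cartesian mask (pointwise sampling).

    A fully sampled central disc covers ``round(centre_fraction * total)``
    points; the remaining budget up to ``round(fraction * total)`` is drawn
    without replacement from a 2D normal density centred on the k-space centre
    (default ``sigma = max(shape) / 6``).
    """
    rows, cols = shape
    if not 0.0 < fraction <= 1.0:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    if not 0.0 <= centre_fraction <= fraction:
        raise ValueError(
            f"need 0 <= centre_fraction <= fraction, got {centre_fraction} vs {fraction}"
        )
    total = rows * cols
    n_total = _round_half_away(fraction * total)
    n_centre = _round_half_away(centre_fraction * total)
    if sigma is None:
        sigma = max(rows, cols) / 6.0

    r = np.arange(rows) - rows // 2
    c = np.arange(cols) - cols // 2
    rr, cc = np.meshgrid(r, c, indexing="ij")
    dist2 = (rr**2 + cc**2).ravel()

    # Central "disc": the n_centre points nearest the k-space centre.  Ties at
    # the boundary radius are broken by flat index so the count is exact.
    order = np.lexsort((np.arange(total), dist2))
    centre_flat = order[:n_centre]

    grid_flat = np.zeros(total, dtype=np.uint8)
    grid_flat[centre_flat] = 1

    n_extra = n_total - n_centre
    if n_extra > 0:
        rng = np.random.default_rng(seed)
        remaining = np.flatnonzero(grid_flat == 0)
        w = np.exp(-0.5 * dist2[remaining] / sigma**2)
        w = w / w.sum()
        extra = rng.choice(remaining, size=n_extra, replace=False, p=w)
        grid_flat[extra] = 1

    return SamplingMask(
        grid=grid_flat.reshape(rows, cols),
        kind="varden2d",
        fraction=fraction,
        seed=seed,
        params={"centre_fraction": centre_fraction, "sigma": sigma},
    )


def undersample(kspace: np.ndarray, mask: SamplingMask | np.ndarray) -> np.ndarray:
    """Zero out the k-space locations the mask does not acquire."""
    grid = mask.grid if isinstance(mask, SamplingMask) else np.asarray(mask)
    kspace = np.asarray(kspace)
    if kspace.shape[-2:] != grid.shape:
        raise ValueError(f"k-space {kspace.shape} does not match mask {grid.shape}")
    return kspace * grid


def theoretical_acceleration(mask: SamplingMask) -> float:
    """Theoretical acceleration factor ``1 / fraction`` (4 at 25%, 10 at 10%)."""
    if mask.fraction <= 0:
        raise ValueError("mask fraction must be positive")
    return 1.0 / mask.fraction
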