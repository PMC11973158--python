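"""Image-quality metrics: SSIM, NRMSE and the universal image quality index.

All three are computed on real-valued images; complex reconstructions are
evaluated channel-wise on their magnitude and phase images (magnitude
min-max scaled to dynamic range L = 1, phase mapped to [0, 2*pi) with
L = 2*pi).

SSIM here follows the windowed convention: the statistic

    SSIM = (2 mu_x mu_y + C1)(2 sigma_xy + C2)
           / ((mu_x^2 + mu_y^2 + C1)(sigma_x^2 + sigma_y^2 + C2)),

with C1 = (k1 L)^2, C2 = (k2 L)^2, k1 = 0.01, k2 = 0.03, is evaluated over
local uniform windows (default 7x7, sample-covariance normalized) and
averaged over the valid interior; a "global" mode evaluates the same
statistic once from whole-image moments.

UIQI is the product of a correlation term, a luminance-similarity term and a
contrast-similarity term.  One printed variant of its moment definitions uses
an idiosyncratic 1/(M+N-1) normalizer; because that normalizer is common to
sigma_xy, sigma_x * sigma_y and the contrast ratio, it cancels in Q, so the
"m_plus_n" and conventional "sample" (1/(MN-1)) normalizers return the same
index — both are exposed for transparency.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter

__all__ = ["SSIMParams", "ssim", "nrmse", "uiqi", "evaluate_pair", "magnitude_phase_channels"]


@dataclass(frozen=True)
class SSIMParams:
    """SSIM constants: C1 = (k1*L)^2, C2 = (k2*L)^2 over window ``win_size``."""

    k1: float = 0.01
    k2: float = 0.03
    L: float = 1.0
    win_size: int = 7
    mode: str = "windowed"  # "windowed" | "global"

    def __post_init__(self):
        if self.k1 <= 0 or self.k2 <= 0 or self.L <= 0:
            raise ValueError("k1, k2 and L must be positive")
        if self.mode not in ("windowed", "global"):
            raise ValueError(f"unknown SSIM mode {self.mode!r}")
        if self.mode == "windowed" and (self.win_size < 3 or self.win_size % 2 == 0):
            raise ValueError("win_size must be an odd integer >= 3")

    @property
    def C1(self) -> float:
        return (self.k1 * self.L) ** 2

    @property
    def C2(self) -> float:
        return (self.k2 * self.L) ** 2


def _check_pair(x, y):
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {y.shape}")
    return x, y


def ssim(x: np.ndarray, y: np.ndarray, params: SSIMParams | None = None) -> float:
    """Structural similarity index between two real images.

    Windowed mode matches the standard uniform-window, sample-covariance
    implementation (mean over the valid interior); global mode evaluates the
    SSIM statistic once from whole-image moments.
    """
    x, y = _check_pair(x, y)
    p = params or SSIMParams()
    C1, C2 = p.C1, p.C2

    if p.mode == "global":
        mx, my = x.mean(), y.mean()
        vx, vy = x.var(ddof=1), y.var(ddof=1)
        cxy = np.mean((x - mx) * (y - my)) * x.size / (x.size - 1)
        return float(
            (2 * mx * my + C1) * (2 * cxy + C2) / ((mx**2 + my**2 + C1) * (vx + vy + C2))
        )

    w = p.win_size
    if min(x.shape) < w:
        raise ValueError(f"image smaller than SSIM window {w}")
    # local moments over a uniform window, with the n/(n-1) sample-covariance
    # correction, evaluated on the valid interior only
    n_win = w**2
    cov_norm = n_win / (n_win - 1)
    ux = uniform_filter(x, size=w)
    uy = uniform_filter(y, size=w)
    uxx = uniform_filter(x * x, size=w)
    uyy = uniform_filter(y * y, size=w)
    uxy = uniform_filter(x * y, size=w)
    vx = cov_norm * (uxx - ux * ux)
    vy = cov_norm * (uyy - uy * uy)
    vxy = cov_norm * (uxy - ux * uy)
    s = (2 * ux * uy + C1) * (2 * vxy + C2) / ((ux**2 + uy**2 + C1) * (vx + vy + C2))
    pad = (w - 1) // 2
    return float(s[pad:-pad, pad:-pad].mean())


def nrmse(y: np.ndarray, y_hat: np.ndarray) -> float:
    """Normalized root-mean-square error: RMSE(y, y_hat) / RMS(y).

    ``y`` is the fully sampled ground truth (the normalizer); invariant under
    common rescaling of both images.
    """
    y, y_hat = _check_pair(y, y_hat)
    denom = np.sqrt(np.mean(y**2))
    if denom == 0:
        raise ZeroDivisionError("NRMSE undefined: reference image is identically zero")
    return float(np.sqrt(np.mean((y - y_hat) ** 2)) / denom)


def uiqi(x: np.ndarray, y: np.ndarray, normalizer: str = "m_plus_n") -> float:
    """Universal image quality index Q in [-1, 1].

    Product of (i) the correlation coefficient between x and y, (ii) a mean
    luminance similarity term 2*mx*my / (mx^2 + my^2), and (iii) a contrast
    similarity term 2*sx*sy / (sx^2 + sy^2).  ``normalizer`` selects the
    moment normalizer: "m_plus_n" (1/(M+N-1)) or the conventional "sample"
    (1/(MN-1)); Q itself is identical in both (the normalizer cancels).
    """
    x, y = _check_pair(x, y)
    if normalizer not in ("m_plus_n", "sample"):
        raise ValueError(f"unknown UIQI normalizer {normalizer!r}")
    M, N = (x.shape + (1, 1))[:2]
    norm = 1.0 / (M + N - 1) if normalizer == "m_plus_n" else 1.0 / (x.size - 1)
    mx, my = x.mean(), y.mean()
    dx, dy = x - mx, y - my
    sxy = norm * np.sum(dx * dy)
    sx2 = norm * np.sum(dx * dx)
    sy2 = norm * np.sum(dy * dy)
    if sx2 == 0 and sy2 == 0:
        raise ValueError("UIQI undefined: both images are constant")
    sx, sy = np.sqrt(sx2), np.sqrt(sy2)
    corr = sxy / (sx * sy) if sx > 0 and sy > 0 else 0.0
    # means that are zero up to floating cancellation make the luminance
    # ratio 0/0; its limit for matched (zero) luminance is 1
    scale = max(sx, sy, abs(mx), abs(my))
    if max(abs(mx), abs(my)) <= 1e-12 * scale:
        lum = 1.0
    else:
        lum = 2 * mx * my / (mx**2 + my**2)
    con = 2 * sx * sy / (sx2 + sy2)
    return float(corr * lum * con)


def magnitude_phase_channels(img: np.ndarray) -> dict[str, tuple[np.ndarray, float]]:
    """Split a complex image into metric channels with their dynamic ranges.

    Magnitude is min-max scaled to [0, 1] (L = 1; images with constant
    magnitude are returned as zeros); phase is mapped from (-pi, pi] to
    [0, 2*pi) with L = 2*pi.
    """
    img = np.asarray(img, dtype=np.complex128)
    mag = np.abs(img)
    rng = mag.max() - mag.min()
    mag = (mag - mag.min()) / rng if rng > 0 else np.zeros_like(mag)
    phase = np.mod(np.angle(img), 2 * np.pi)
    return {"magnitude": (mag, 1.0), "phase": (phase, 2 * np.pi)}


def evaluate_pair(truth: np.ndarray, pred: np.ndarray) -> dict[str, dict[str, float]]:
    """SSIM/NRMSE/UIQI of a reconstruction against ground truth.

    Returns ``{"magnitude": {...}, "phase": {...}}`` with the three metrics
    per channel, using the channel scalings of
    :func:`magnitude_phase_channels` (the truth's min-max scaling is applied
    to both magnitudes so the channels share one intensity mapping).
    """
    truth = np.asarray(truth, dtype=np.complex128)
    pred = np.asarray(pred, dtype=np.complex128)
    if truth.shape != pred.shape:
        raise ValueError(f"shape mismatch: {truth.shape} vs {pred.shape}")
    out: dict[str, dict[str, float]] = {}
    tmag = np.abs(truth)
    lo, hi = tmag.min(), tmag.max()
    span = hi - lo if hi > lo else 1.0
    channels = {
        "magnitude": ((tmag - lo) / span, (np.abs(pred) - lo) / span, 1.0),
        "phase": (
            np.mod(np.angle(truth), 2 * np.pi),
            np.mod(np.angle(pred), 2 * np.pi),
            2 * np.pi,
        ),
    }
    for name, (t, p, L) in channels.items():
        out[name] = {
            "ssim": ssim(t, p, SSIMParams(L=L)),
            "nrmse": nrmse(t, p),
            "uiqi": uiqi(t, p),
        }
    return out
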