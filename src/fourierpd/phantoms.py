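"""Synthetic complex gradient-echo phantoms with PRF-encoded heating.

The study data these phantoms emulate are single-channel 2D FLASH
gradient-echo acquisitions at 1.5 T (echo times 4.76 ms and 19.1 ms), with a
time series of 2-17 frames in which a localized hotspot raises tissue
temperature.  The generator produces:

* a piecewise-smooth magnitude in [0, 1] built from overlapping random
  ellipses (Shepp-Logan-like anatomy) inside a large background ellipse;
* a smooth low-order polynomial background phase emulating coil and
  susceptibility phase, so phase reconstruction is non-trivial;
* optional circular complex Gaussian noise added in image space (equivalent
  to k-space Gaussian noise under the orthonormal FFT);
* heated frames whose phase is incremented voxelwise by
  gamma * alpha * B0 * TE * dT(v, t) for a Gaussian hotspot dT, the exact
  inverse of the PRF temperature relation the thermometry module applies.

The reference frame's phase lies in (-pi, pi]; heated frames may exceed that
range and are deliberately NOT wrapped or unwrapped here — handling wraps is
the thermometry module's job.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .thermometry import ThermoConstants

__all__ = [
    "PhantomConfig",
    "HeatingScenario",
    "make_complex_phantom",
    "simulate_heating_series",
    "hotspot_map",
]


@dataclass(frozen=True)
class PhantomConfig:
    """Configuration of one synthetic complex phantom.

    Attributes
    ----------
    grid_size
        Pixels per side (square grid); at least 16.  256 mirrors the study's
        matrix size, 64 is the desk-scale test default.
    n_ellipses
        Number of random tissue ellipses overlaid on the background.
    magnitude_range
        (low, high) clip range of the magnitude, within [0, 1].
    background_phase_order
        Polynomial order of the smooth background phase field.
    noise_sd
        Standard deviation of circular complex Gaussian noise, as a fraction
        of the peak magnitude (0 disables noise).
    seed
        RNG seed; identical config + seed reproduces the phantom bit-for-bit.
    """

    grid_size: int = 256
    n_ellipses: int = 6
    magnitude_range: tuple[float, float] = (0.0, 1.0)
    background_phase_order: int = 2
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.grid_size < 16:
            raise ValueError(f"grid_size must be >= 16, got {self.grid_size}")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")
        lo, hi = self.magnitude_range
        if not (0.0 <= lo < hi <= 1.0):
            raise ValueError(f"magnitude_range must satisfy 0 <= lo < hi <= 1, got {self.magnitude_range}")


@dataclass(frozen=True)
class HeatingScenario:
    """A localized Gaussian hotspot heating over a short time series.

    ``delta_T_peak_per_tp`` lists the peak temperature rise (degC) of each
    *heated* frame, i.e. it has ``n_timepoints - 1`` entries (frame 0 is the
    unheated reference; two frames are the minimum for one temperature map).
    A list of length ``n_timepoints`` whose first entry is 0 is also
    accepted.  When empty, a linear ramp up to ``peak_delta_T`` is used.
    """

    hotspot_center: tuple[float, float] = (32.0, 32.0)
    hotspot_sigma: float = 6.0
    n_timepoints: int = 5
    delta_T_peak_per_tp: tuple[float, ...] = ()
    peak_delta_T: float = 5.0

    def __post_init__(self):
        if not 2 <= self.n_timepoints <= 17:
            raise ValueError(
                f"n_timepoints must be in [2, 17] (reference + heated frames), got {self.n_timepoints}"
            )
        if self.hotspot_sigma <= 0:
            raise ValueError("hotspot_sigma must be positive")
        peaks = tuple(self.delta_T_peak_per_tp)
        if peaks and len(peaks) == self.n_timepoints and peaks[0] == 0.0:
            peaks = peaks[1:]
        if peaks and len(peaks) != self.n_timepoints - 1:
            raise ValueError(
                f"delta_T_peak_per_tp must have {self.n_timepoints - 1} entries "
                f"(one per heated frame), got {len(peaks)}"
            )
        object.__setattr__(self, "delta_T_peak_per_tp", peaks)

    @property
    def peaks(self) -> np.ndarray:
        """Peak temperature rise of each heated frame (linear ramp default)."""
        if self.delta_T_peak_per_tp:
            return np.asarray(self.delta_T_peak_per_tp, dtype=np.float64)
        n = self.n_timepoints - 1
        return self.peak_delta_T * np.arange(1, n + 1) / n


def _random_ellipse_mask(
    grid_size: int, rng: np.random.Generator
) -> np.ndarray:
    """Boolean mask of one random (possibly rotated) ellipse."""
    yy, xx = np.mgrid[0:grid_size, 0:grid_size]
    cy, cx = rng.uniform(0.25 * grid_size, 0.75 * grid_size, size=2)
    a = rng.uniform(0.05, 0.25) * grid_size
    b = rng.uniform(0.05, 0.25) * grid_size
    theta = rng.uniform(0, np.pi)
    ct, st = np.cos(theta), np.sin(theta)
    u = (xx - cx) * ct + (yy - cy) * st
    v = -(xx - cx) * st + (yy - cy) * ct
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def make_complex_phantom(config: PhantomConfig) -> np.ndarray:
    """Generate one complex phantom image.

    Returns a (grid_size, grid_size) complex128 array whose magnitude is
    piecewise smooth in ``magnitude_range`` and whose phase is a smooth
    polynomial field in (-pi, pi] (plus noise if ``noise_sd > 0``).
    """
    n = config.grid_size
    rng = np.random.default_rng(config.seed)

    # Magnitude: large background ellipse + random tissue ellipses.
    yy, xx = np.mgrid[0:n, 0:n]
    cy = cx = (n - 1) / 2.0
    body = ((xx - cx) / (0.45 * n)) ** 2 + ((yy - cy) / (0.45 * n)) ** 2 <= 1.0
    mag = np.where(body, 0.35, 0.0)
    for _ in range(config.n_ellipses):
        ell = _random_ellipse_mask(n, rng) & body
        mag[ell] += rng.uniform(-0.25, 0.45)
    lo, hi = config.magnitude_range
    mag = np.clip(mag, lo, hi)

    # Smooth background phase: low-order polynomial in normalized coords,
    # scaled into a sub-interval of (-pi, pi) so the reference never wraps.
    u = (xx - cx) / n
    v = (yy - cy) / n
    phase = np.zeros((n, n))
    for p in range(config.background_phase_order + 1):
        for q in range(config.background_phase_order + 1 - p):
            phase += rng.uniform(-1.0, 1.0) * (u**p) * (v**q)
    span = np.max(np.abs(phase))
    if span > 0:
        phase *= 0.9 * np.pi / span

    img = mag * np.exp(1j * phase)
    if config.noise_sd > 0:
        s = config.noise_sd * mag.max()
        img = img + s * (rng.standard_normal((n, n)) + 1j * rng.standard_normal((n, n)))
    return img


def hotspot_map(
    shape: tuple[int, int], scenario: HeatingScenario, peak: float
) -> np.ndarray:
    """Gaussian temperature-rise map with the given peak (degC)."""
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    r0, c0 = scenario.hotspot_center
    d2 = (yy - r0) ** 2 + (xx - c0) ** 2
    return peak * np.exp(-0.5 * d2 / scenario.hotspot_sigma**2)


def simulate_heating_series(
    phantom: np.ndarray,
    scenario: HeatingScenario,
    constants: ThermoConstants,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> np.ndarray:
    """Apply PRF-encoded heating to a phantom across a time series.

    Frame 0 is the unmodified reference; frame t multiplies the phantom by
    ``exp(i * gamma * alpha * B0 * TE * dT(v, t))`` where dT is the Gaussian
    hotspot with the scenario's per-frame peak.  Magnitude is unchanged in
    the noiseless case; optional circular complex Gaussian noise (sd as a
    fraction of peak magnitude, fresh draw per frame) is added afterwards.

    Returns a (n_timepoints, rows, cols) complex128 stack.
    """
    phantom = np.asarray(phantom, dtype=np.complex128)
    if phantom.ndim != 2:
        raise ValueError("phantom must be a 2D complex image")
    if not np.all(np.isfinite(phantom.real)) or not np.all(np.isfinite(phantom.imag)):
        raise ValueError("phantom must be finite")

    frames = [phantom.copy()]
    rad_per_degC = constants.rad_per_degC
    for peak in scenario.peaks:
        dT = hotspot_map(phantom.shape, scenario, float(peak))
        frames.append(phantom * np.exp(1j * rad_per_degC * dT))
    series = np.stack(frames)

    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        s = noise_sd * np.abs(phantom).max()
        series = series + s * (
            rng.standard_normal(series.shape) + 1j * rng.standard_normal(series.shape)
        )
    return series
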