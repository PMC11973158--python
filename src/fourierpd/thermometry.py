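"""PRF-shift MR thermometry: phase differences, temperature maps, error statistics.

The proton resonance frequency (PRF) of water shifts linearly with
temperature, so in a gradient-echo acquisition the image phase accrued at
echo time TE changes by

    d(phase) = gamma * alpha * B0 * TE  per degree Celsius,

with gamma the proton gyromagnetic ratio (rad/s/T), alpha the PRF
temperature-sensitivity coefficient (about -0.01 ppm/degC, tissue
independent), and B0 the main field strength.  A temperature-change map
relative to a reference frame is therefore

    dT = d(phase) / (gamma * alpha * B0 * TE).

The phase difference between a heated image I_H and the reference I_ref is
computed from the complex product conj(I_ref) * I_H via the four-quadrant
arctangent, which yields the principal value in (-pi, pi] without explicit
phase unwrapping of the individual images.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ThermoConstants",
    "TemperatureMap",
    "phase_difference",
    "temperature_map",
    "temperature_series",
    "temperature_error",
    "rms_temperature_error",
]

GAMMA_PROTON = 2 * np.pi * 42.577e6
"""Proton gyromagnetic ratio in rad/s/T."""


@dataclass(frozen=True)
class ThermoConstants:
    """Physical constants of the PRF temperature relation.

    Attributes
    ----------
    gamma
        Gyromagnetic ratio in rad/s/T (default: proton, 2*pi*42.577e6).
    alpha
        PRF temperature sensitivity in ppm per degree Celsius (default -0.01;
        converted internally by 1e-6).
    B0
        Main magnetic field strength in tesla.
    TE
        Echo time in seconds.
    """

    gamma: float = GAMMA_PROTON
    alpha: float = -0.01
    B0: float = 1.5
    TE: float = 19.1e-3

    def __post_init__(self):
        if self.gamma <= 0 or self.B0 <= 0 or self.TE <= 0:
            raise ValueError("gamma, B0 and TE must all be positive")
        if self.alpha == 0:
            raise ValueError("alpha must be nonzero")

    @property
    def rad_per_degC(self) -> float:
        """Phase shift per degree Celsius: gamma * alpha * 1e-6 * B0 * TE (rad)."""
        return self.gamma * self.alpha * 1e-6 * self.B0 * self.TE


@dataclass
class TemperatureMap:
    """Relative temperature-change map in degrees Celsius.

    ``delta_T`` is relative to the series' reference frame; ``valid`` flags
    voxels where the phase difference was defined (nonzero magnitude in both
    frames); ``roi`` optionally marks the tumour / hotspot region.
    """

    delta_T: np.ndarray
    valid: np.ndarray | None = None
    roi: np.ndarray | None = None


def phase_difference(
    I_ref: np.ndarray, I_H: np.ndarray, return_valid: bool = False
) -> np.ndarray | tuple[np.ndarray, np.ndarray]:
    """Principal-value phase difference between a heated and a reference image.

    Computed as atan2(Im(conj(I_ref) * I_H), Re(conj(I_ref) * I_H)), i.e. the
    numerator Re(I_ref) Im(I_H) - Im(I_ref) Re(I_H) over the denominator
    Re(I_ref) Re(I_H) + Im(I_ref) Im(I_H); range (-pi, pi].  An injected shift
    beyond pi wraps to its principal value (e.g. 3.5 rad -> 3.5 - 2*pi).

    Voxels where both numerator and denominator vanish (zero magnitude) get
    a phase difference of 0 and are flagged False in the validity mask.
    """
    I_ref = np.asarray(I_ref, dtype=np.complex128)
    I_H = np.asarray(I_H, dtype=np.complex128)
    if I_ref.shape != I_H.shape:
        raise ValueError(f"shape mismatch: {I_ref.shape} vs {I_H.shape}")
    num = I_ref.real * I_H.imag - I_ref.imag * I_H.real
    den = I_ref.real * I_H.real + I_ref.imag * I_H.imag
    valid = (num != 0) | (den != 0)
    dphi = np.arctan2(num, den)
    dphi = np.where(valid, dphi, 0.0)
    if return_valid:
        return dphi, valid
    return dphi


def temperature_map(
    delta_phi: np.ndarray, constants: ThermoConstants
) -> np.ndarray:
    """Convert a phase-difference map (rad) to a temperature change map (degC)."""
    denom = constants.rad_per_degC
    if denom == 0:
        raise ValueError("gamma * alpha * B0 * TE must be nonzero")
    return np.asarray(delta_phi, dtype=np.float64) / denom


def temperature_series(
    frames: np.ndarray | list[np.ndarray], constants: ThermoConstants
) -> np.ndarray:
    """Temperature maps of frames 1..T-1 of a complex series against frame 0.

    Frame 0 is the unheated reference (the first acquisition); the result has
    shape (T-1, rows, cols).
    """
    frames = np.asarray(frames, dtype=np.complex128)
    if frames.ndim != 3 or frames.shape[0] < 2:
        raise ValueError("need a (T, rows, cols) series with T >= 2")
    ref = frames[0]
    return np.stack(
        [temperature_map(phase_difference(ref, f), constants) for f in frames[1:]]
    )


def _roi_select(series: np.ndarray, roi: np.ndarray | None) -> np.ndarray:
    if roi is None:
        return series.reshape(series.shape[0], -1)
    roi = np.asarray(roi, dtype=bool)
    if roi.shape != series.shape[1:]:
        raise ValueError(f"ROI shape {roi.shape} does not match maps {series.shape[1:]}")
    if not roi.any():
        raise ValueError("ROI selects no voxels")
    return series[:, roi]


def temperature_error(
    x_series: np.ndarray, y_series: np.ndarray, roi: np.ndarray | None = None
) -> float:
    """Scaled mean squared temperature difference between two map series.

    E_T(x, y) = 100 / (V * tau) * sum_t sum_v (dT_x(v,t) - dT_y(v,t))^2,
    with tau time points and V voxels (restricted to the ROI when given).
    Symmetric, nonnegative, zero iff the series agree on the evaluated voxels.
    """
    x = np.asarray(x_series, dtype=np.float64)
    y = np.asarray(y_series, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError(f"series shapes differ: {x.shape} vs {y.shape}")
    if x.ndim < 2:
        x = x.reshape(1, -1)
        y = y.reshape(1, -1)
    diff = _roi_select(x, roi) - _roi_select(y, roi)
    return float(100.0 * np.mean(diff**2))


def rms_temperature_error(
    x_series: np.ndarray, y_series: np.ndarray, roi: np.ndarray | None = None
) -> float:
    """Root-mean-square temperature difference in degrees Celsius.

    Companion statistic to :func:`temperature_error`: same squared
    differences, but reported as sqrt(mean) so the value carries degC units
    and is directly comparable to a temperature accuracy requirement.
    """
    x = np.asarray(x_series, dtype=np.float64)
    y = np.asarray(y_series, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError(f"series shapes differ: {x.shape} vs {y.shape}")
    if x.ndim < 2:
        x = x.reshape(1, -1)
        y = y.reshape(1, -1)
    diff = _roi_select(x, roi) - _roi_select(y, roi)
    return float(np.sqrt(np.mean(diff**2)))
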