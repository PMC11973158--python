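"""Readers and writers for the formats the pipeline touches.

Complex images travel as magnitude/phase pairs.  Phase storage differs by
format ("dialect") and is never auto-guessed:

* ``nifti``  — float radians stored natively in NIfTI files;
* ``dicom``  — scaled integers; the stored integer range is mapped linearly
  onto (-pi, pi], with the extreme stored values hitting the interval
  endpoints.

Time series are written as one magnitude/phase NIfTI pair per time point
plus a YAML sidecar recording the thermometry constants and the scenario /
provenance metadata.  Sampling masks go to PNG (binary) plus a JSON sidecar
with their generation parameters; measured k-space goes to an HDF5
container holding the complex grid, the mask and metadata.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np
import yaml
from PIL import Image

from .kspace import SamplingMask
from .thermometry import ThermoConstants

__all__ = [
    "ComplexSeries",
    "read_complex",
    "read_complex_dicom",
    "write_complex_nifti",
    "write_series",
    "read_series",
    "write_mask",
    "read_mask",
    "write_kspace_h5",
    "read_kspace_h5",
]


@dataclass
class ComplexSeries:
    """An ordered complex time series with acquisition metadata."""

    frames: np.ndarray  # (T, rows, cols) complex
    voxel_size: tuple[float, float, float] = (1.95, 1.95, 5.0)
    TE: float | None = None
    B0: float | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=np.complex128)
        if self.frames.ndim != 3:
            raise ValueError("frames must be (T, rows, cols)")

    def constants(self, alpha: float = -0.01) -> ThermoConstants:
        if self.TE is None or self.B0 is None:
            raise ValueError("TE and B0 must be set before thermometry")
        return ThermoConstants(alpha=alpha, B0=self.B0, TE=self.TE)


def _nifti_array(path: str | Path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).get_fdata(), dtype=np.float64)


def read_complex(magnitude_path: str | Path, phase_path: str | Path) -> np.ndarray:
    """Combine a NIfTI magnitude/phase pair into a complex image.

    Phase is taken as float radians (the NIfTI dialect).
    """
    mag = _nifti_array(magnitude_path)
    phase = _nifti_array(phase_path)
    if mag.shape != phase.shape:
        raise ValueError(f"magnitude {mag.shape} and phase {phase.shape} differ in shape")
    return mag * np.exp(1j * phase)


def read_complex_dicom(magnitude_path: str | Path, phase_path: str | Path) -> np.ndarray:
    """Combine a DICOM magnitude/phase pair into a complex image.

    The stored phase integers are mapped linearly onto (-pi, pi]: the lowest
    representable stored value maps just above -pi and the highest to +pi,
    using RescaleSlope/Intercept when present and the full stored-integer
    range implied by BitsStored / PixelRepresentation otherwise.
    """
    import pydicom

    mds = pydicom.dcmread(str(magnitude_path))
    pds = pydicom.dcmread(str(phase_path))
    mag = mds.pixel_array.astype(np.float64)
    raw = pds.pixel_array.astype(np.float64)
    if mag.shape != raw.shape:
        raise ValueError(f"magnitude {mag.shape} and phase {raw.shape} differ in shape")

    slope = float(getattr(pds, "RescaleSlope", 1.0))
    intercept = float(getattr(pds, "RescaleIntercept", 0.0))
    stored = raw * slope + intercept

    bits = int(getattr(pds, "BitsStored", 12))
    signed = int(getattr(pds, "PixelRepresentation", 0)) == 1
    if signed:
        lo = (-(2 ** (bits - 1))) * slope + intercept
        hi = (2 ** (bits - 1) - 1) * slope + intercept
    else:
        lo = intercept
        hi = (2**bits - 1) * slope + intercept
    # linear map: hi -> +pi, and the step below lo -> -pi (half-open interval)
    span = hi - lo
    if span <= 0:
        raise ValueError("cannot determine the stored phase range from the DICOM header")
    phase = -np.pi + (stored - lo + (span / (2**bits - 1))) / (span + span / (2**bits - 1)) * 2 * np.pi
    return mag * np.exp(1j * phase)


def write_complex_nifti(
    img: np.ndarray, magnitude_path: str | Path, phase_path: str | Path
) -> None:
    """Write one complex image as a float NIfTI magnitude/phase pair."""
    img = np.asarray(img, dtype=np.complex128)
    affine = np.eye(4)
    nib.save(nib.Nifti1Image(np.abs(img), affine), str(magnitude_path))
    nib.save(nib.Nifti1Image(np.angle(img), affine), str(phase_path))


def write_series(series: ComplexSeries, out_dir: str | Path) -> Path:
    """Write a complex series as per-frame NIfTI pairs plus a YAML sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for t, frame in enumerate(series.frames):
        write_complex_nifti(frame, out / f"tp{t:03d}_mag.nii.gz", out / f"tp{t:03d}_phase.nii.gz")
    sidecar = {
        "n_timepoints": int(series.frames.shape[0]),
        "shape": list(series.frames.shape[1:]),
        "voxel_size_mm": list(series.voxel_size),
        "TE_s": series.TE,
        "B0_T": series.B0,
        "provenance": series.provenance,
    }
    with open(out / "series.yaml", "w") as fh:
        yaml.safe_dump(sidecar, fh)
    return out


def read_series(in_dir: str | Path) -> ComplexSeries:
    """Inverse of :func:`write_series`."""
    src = Path(in_dir)
    with open(src / "series.yaml") as fh:
        meta = yaml.safe_load(fh)
    frames = []
    for t in range(meta["n_timepoints"]):
        frames.append(read_complex(src / f"tp{t:03d}_mag.nii.gz", src / f"tp{t:03d}_phase.nii.gz"))
    series = ComplexSeries(
        frames=np.stack(frames),
        voxel_size=tuple(meta.get("voxel_size_mm", (1.95, 1.95, 5.0))),
        TE=meta.get("TE_s"),
        B0=meta.get("B0_T"),
        provenance=meta.get("provenance", {}),
    )
    return series


def write_mask(mask: SamplingMask, png_path: str | Path) -> None:
    """Binary PNG + JSON sidecar with the generation parameters."""
    png_path = Path(png_path)
    Image.fromarray((mask.grid * 255).astype(np.uint8)).save(png_path)
    with open(png_path.with_suffix(".json"), "w") as fh:
        json.dump(mask.to_dict(), fh, indent=2)


def read_mask(png_path: str | Path) -> SamplingMask:
    png_path = Path(png_path)
    grid = (np.asarray(Image.open(png_path)) > 127).astype(np.uint8)
    with open(png_path.with_suffix(".json")) as fh:
        meta = json.load(fh)
    return SamplingMask(
        grid=grid,
        kind=meta["kind"],
        fraction=meta["fraction"],
        seed=meta.get("seed", -1),
        params=meta.get("params", {}),
    )


def write_kspace_h5(
    path: str | Path, measured_k: np.ndarray, mask: SamplingMask, meta: dict | None = None
) -> None:
    """Measured (zero-filled) k-space + mask + metadata in one HDF5 file."""
    with h5py.File(str(path), "w") as fh:
        fh.create_dataset("kspace", data=np.asarray(measured_k, dtype=np.complex128))
        fh.create_dataset("mask", data=mask.grid)
        fh.attrs["mask_meta"] = json.dumps(mask.to_dict())
        fh.attrs["meta"] = json.dumps(meta or {})


def read_kspace_h5(path: str | Path) -> tuple[np.ndarray, SamplingMask, dict]:
    with h5py.File(str(path), "r") as fh:
        k = fh["kspace"][...]
        grid = fh["mask"][...]
        mask_meta = json.loads(fh.attrs["mask_meta"])
        meta = json.loads(fh.attrs["meta"])
    mask = SamplingMask(
        grid=grid,
        kind=mask_meta["kind"],
        fraction=mask_meta["fraction"],
        seed=mask_meta.get("seed", -1),
        params=mask_meta.get("params", {}),
    )
    return k, mask, meta
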