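"""Core containers and conventions shared across the pipeline.

Conventions used everywhere in this package:

* Volumes are cubic ``numpy`` arrays indexed ``[z, y, x]``; images ``[y, x]``.
* The real-space origin sits at voxel index ``N // 2`` on each axis
  (0-based), so coordinate of voxel ``i`` is ``(i - N // 2) * voxel_size``
  in Angstrom.  This matches the centring assumed by the FFT-based code.
* Euler angles are ZYZ intrinsic ``(rot, tilt, psi)`` in degrees; the
  rotation matrix is ``Rz(rot) @ Ry(tilt) @ Rz(psi)`` and a projection
  samples the volume at rotated coordinates, integrating along z.
* Spatial frequency is in 1/Angstrom; Nyquist is ``1 / (2 * pixel_size)``.
* Defocus is positive for underfocus, in micrometre.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "VolumeMap",
    "AcquisitionParams",
    "CTFParams",
    "PicoemError",
    "ValidationError",
    "SizingError",
    "electron_wavelength",
    "freq_grid_2d",
    "freq_grid_3d",
]


class PicoemError(Exception):
    """Base class for pipeline errors."""


class ValidationError(PicoemError):
    """Invalid parameter combination or malformed input."""


class SizingError(PicoemError):
    """Array or box too small/large for the requested operation."""


@dataclass
class VolumeMap:
    """3D density grid with voxel size (Angstrom) and centre-origin convention."""

    data: np.ndarray
    voxel_size: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValidationError(f"VolumeMap needs a 3D array, got ndim={self.data.ndim}")
        if self.voxel_size <= 0:
            raise ValidationError("voxel_size must be positive")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def is_cubic(self) -> bool:
        n = self.data.shape[0]
        return self.data.shape == (n, n, n)

    @property
    def nyquist(self) -> float:
        """Nyquist frequency in 1/Angstrom."""
        return 1.0 / (2.0 * self.voxel_size)

    def copy(self) -> "VolumeMap":
        return VolumeMap(self.data.copy(), self.voxel_size)


@dataclass(frozen=True)
class AcquisitionParams:
    """Microscope and exposure parameters.

    Defaults correspond to a 300 keV instrument with a direct detector
    recording 17 frames of 2.8 e/A^2 each at 0.056 s per frame during a
    1 s exposure, sampled at 1.04 A/px.
    """

    voltage_kv: float = 300.0
    cs_mm: float = 2.7
    amplitude_contrast: float = 0.07
    pixel_size: float = 1.04
    n_frames: int = 17
    dose_per_frame: float = 2.8
    frame_interval_s: float = 0.056
    exposure_time_s: float = 1.0

    def __post_init__(self) -> None:
        if self.voltage_kv <= 0:
            raise ValidationError("voltage must be positive")
        if self.pixel_size <= 0:
            raise ValidationError("pixel size must be positive")
        if self.n_frames < 1:
            raise ValidationError("need at least one frame")
        if self.dose_per_frame < 0:
            raise ValidationError("per-frame dose must be non-negative")
        if not (0.0 <= self.amplitude_contrast <= 1.0):
            raise ValidationError("amplitude contrast fraction must lie in [0, 1]")
        if self.n_frames * self.frame_interval_s > self.exposure_time_s + self.frame_interval_s:
            raise ValidationError("frames x interval exceeds exposure time by more than one interval")

    @property
    def wavelength(self) -> float:
        """Relativistic electron wavelength in Angstrom."""
        return electron_wavelength(self.voltage_kv)

    @property
    def total_dose(self) -> float:
        return self.n_frames * self.dose_per_frame


@dataclass(frozen=True)
class CTFParams:
    """Astigmatic defocus pair (um, underfocus positive) plus flip state.

    ``defocus_u >= defocus_v`` by convention; ``astig_angle_deg`` is the
    azimuth of the defocus_u direction, canonical range [0, 180).
    """

    defocus_u_um: float
    defocus_v_um: float
    astig_angle_deg: float = 0.0
    phase_flipped: bool = False

    def __post_init__(self) -> None:
        if self.defocus_u_um < self.defocus_v_um:
            raise ValidationError("defocus_u must be >= defocus_v (ordering convention)")
        if self.defocus_u_um <= 0 or self.defocus_v_um <= 0:
            raise ValidationError("defocus must be positive (underfocus convention)")
        if not (0.0 <= self.astig_angle_deg < 180.0):
            raise ValidationError("astigmatism angle must lie in [0, 180)")

    @property
    def mean_defocus_um(self) -> float:
        return 0.5 * (self.defocus_u_um + self.defocus_v_um)

    @property
    def astigmatism_um(self) -> float:
        return self.defocus_u_um - self.defocus_v_um

    def flipped(self) -> "CTFParams":
        return replace(self, phase_flipped=True)


def electron_wavelength(voltage_kv: float) -> float:
    """Relativistic electron wavelength in Angstrom for voltage in kV.

    lambda = h / sqrt(2 m0 e V (1 + eV / (2 m0 c^2)))
    """
    v = voltage_kv * 1e3
    return 12.2639 / np.sqrt(v * (1.0 + 0.97845e-6 * v))


def freq_grid_2d(shape: tuple[int, int], pixel_size: float):
    """FFT-layout spatial frequency grids (ky, kx) in 1/Angstrom."""
    ky = np.fft.fftfreq(shape[0], d=pixel_size)[:, None]
    kx = np.fft.fftfreq(shape[1], d=pixel_size)[None, :]
    return ky, kx


def freq_grid_3d(shape: tuple[int, int, int], voxel_size: float):
    """FFT-layout spatial frequency grids (kz, ky, kx) in 1/Angstrom."""
    kz = np.fft.fftfreq(shape[0], d=voxel_size)[:, None, None]
    ky = np.fft.fftfreq(shape[1], d=voxel_size)[None, :, None]
    kx = np.fft.fftfreq(shape[2], d=voxel_size)[None, None, :]
    return kz, ky, kx
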