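"""Acquisition geometry of a Fourier-domain OCT B-scan stack.

The geometry object carries the handful of instrument constants that every
other module needs: the centre wavelength of the source, the group
refractive index of the medium, the frame rate of repeated B-scan
acquisition and the pixel pitches of the reconstructed image.  Axial pixel
pitch is quoted *in air*; geometric distances inside the sample are obtained
by dividing optical (air-equivalent) distance by the group index ``n_g``.

Conventions shared by the whole package:

* row 0 is the shallowest depth and depth increases with row index;
* axial velocities are signed, positive toward larger depth;
* velocities are reported in nm/s, depths in micrometres.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["AcquisitionGeometry", "nyquist_velocity"]


@dataclass(frozen=True)
class AcquisitionGeometry:
    """Instrument constants for one complex B-scan stack.

    Parameters
    ----------
    centre_wavelength_nm
        Centre wavelength of the OCT source, nm.
    group_index
        Group refractive index ``n_g`` of the sample medium used to convert
        optical to geometric path (1.37 for corneal stroma).
    frame_rate_hz
        B-scan repetition rate, Hz.  Frame ``k`` is acquired at
        ``k / frame_rate_hz`` seconds.
    axial_pixel_pitch_um
        Axial pixel size *in air*, micrometres per pixel.
    lateral_pixel_pitch_um
        Lateral pixel size, micrometres per pixel.
    n_frames
        Number of frames in the stack.
    """

    centre_wavelength_nm: float = 800.0
    group_index: float = 1.37
    frame_rate_hz: float = 2.0
    axial_pixel_pitch_um: float = 5.0
    lateral_pixel_pitch_um: float = 10.0
    n_frames: int = 10

    def __post_init__(self) -> None:
        for name in (
            "centre_wavelength_nm",
            "group_index",
            "frame_rate_hz",
            "axial_pixel_pitch_um",
            "lateral_pixel_pitch_um",
        ):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")

    @property
    def frame_interval_s(self) -> float:
        """Time between consecutive frames, seconds."""
        return 1.0 / self.frame_rate_hz

    def timestamps(self, n_frames: int | None = None) -> np.ndarray:
        """Strictly increasing frame timestamps ``k / frame_rate``, seconds."""
        n = self.n_frames if n_frames is None else n_frames
        return np.arange(n, dtype=float) * self.frame_interval_s

    @property
    def axial_pitch_medium_um(self) -> float:
        """Geometric axial pixel size inside the medium, micrometres."""
        return self.axial_pixel_pitch_um / self.group_index

    def depth_um(self, row) -> np.ndarray:
        """Geometric depth (in the medium) of a pixel row, micrometres."""
        return np.asarray(row, dtype=float) * self.axial_pitch_medium_um

    @property
    def phase_per_displacement(self) -> float:
        """Fourier-phase change per nm of axial displacement, rad/nm.

        A scatterer moving by ``dz`` (geometric, in the medium) changes the
        round-trip optical path by ``2 n_g dz`` and therefore the Fourier
        phase by ``4 pi n_g dz / lambda``.
        """
        return 4.0 * np.pi * self.group_index / self.centre_wavelength_nm

    def measurement_window_s(self, n_frames: int | None = None) -> float:
        """Total time spanned by ``n_frames`` consecutive frames, seconds."""
        n = self.n_frames if n_frames is None else n_frames
        return n / self.frame_rate_hz

    def as_attrs(self) -> dict:
        """Flat dict of the geometry fields, for HDF5 attributes."""
        return {
            "centre_wavelength_nm": self.centre_wavelength_nm,
            "group_index": self.group_index,
            "frame_rate_hz": self.frame_rate_hz,
            "axial_pixel_pitch_um": self.axial_pixel_pitch_um,
            "lateral_pixel_pitch_um": self.lateral_pixel_pitch_um,
            "n_frames": self.n_frames,
        }

    @classmethod
    def from_attrs(cls, attrs) -> "AcquisitionGeometry":
        return cls(
            centre_wavelength_nm=float(attrs["centre_wavelength_nm"]),
            group_index=float(attrs["group_index"]),
            frame_rate_hz=float(attrs["frame_rate_hz"]),
            axial_pixel_pitch_um=float(attrs["axial_pixel_pitch_um"]),
            lateral_pixel_pitch_um=float(attrs["lateral_pixel_pitch_um"]),
            n_frames=int(attrs["n_frames"]),
        )


def nyquist_velocity(geometry: AcquisitionGeometry) -> float:
    """Largest axial velocity measurable without phase aliasing, nm/s.

    A phase step of pi per inter-frame interval is the aliasing limit, so

        v_max = lambda * frame_rate / (4 n_g).

    For the 800 nm / 2 Hz / n_g = 1.37 configuration this is ~292 nm/s.
    """
    return (
        geometry.centre_wavelength_nm
        * geometry.frame_rate_hz
        / (4.0 * geometry.group_index)
    )
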