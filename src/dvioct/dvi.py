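"""Deformation velocity imaging from complex OCT frame stacks.

The Fourier phase of a Fourier-domain OCT pixel advances by
``4 pi n dz / lambda`` when the scatterers in it move axially by ``dz``,
giving nanometre displacement sensitivity.  DVI turns this into a
tomographic map of relative axial velocity inside a deforming sample:

1. per A-scan, a reference pixel is chosen (the strongest signal within a
   small window of a set point inside the cornea) and its phase subtracted
   from the whole A-scan, cancelling bulk motion;
2. the first frame's phase is subtracted per pixel, leaving the change;
3. the phase change is temporally unwrapped over the stack;
4. the phase rate is estimated by ordinary least squares against the frame
   timestamps and converted to velocity by ``v = (dphi/dtau) lambda / (4 pi n)``.

The result is the relative axial velocity of every pixel with respect to the
reference depth, in nm/s, valid up to the Nyquist cap
``lambda f / (4 n)`` (a pi phase step per frame interval).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .geometry import AcquisitionGeometry, nyquist_velocity
from .segmentation import CornealInterfaces
from .stack import ComplexFrameStack

__all__ = [
    "DVIConfig",
    "DeformationVelocityImage",
    "AxialVelocityProfile",
    "select_reference_pixel",
    "temporal_unwrap",
    "phase_rate",
    "velocity_from_phase_rate",
    "nyquist_velocity",
    "compute_dvi",
    "axial_profile",
    "noise_floor",
]


@dataclass(frozen=True)
class DVIConfig:
    """Parameters of the DVI computation.

    ``group_index`` is the refractive index used in the phase-to-velocity
    conversion (1.37 for corneal stroma).  ``reference_halfwidth`` is the
    half-size, in pixels, of the window around the set point searched for
    the strongest-signal reference pixel.  ``boxcar_size`` is the spatial
    smoothing applied to the masked velocity image (never before axial
    averaging).
    """

    scene_variant: str = "with_epithelium"
    group_index: float = 1.37
    reference_halfwidth: int = 10
    boxcar_size: int = 5
    smooth: bool = True


@dataclass
class DeformationVelocityImage:
    """Per-pixel relative axial velocity (nm/s) over a segmented cornea.

    ``velocity_raw`` is the unsmoothed estimate (NaN outside the mask);
    ``velocity_smoothed`` is the boxcar-smoothed version (shrinking the
    window at mask edges), or None when smoothing was disabled.
    """

    velocity_raw: np.ndarray
    velocity_smoothed: np.ndarray | None
    mask: np.ndarray
    reference_rows: np.ndarray
    set_rows: np.ndarray
    geometry: AcquisitionGeometry
    config: DVIConfig

    @property
    def velocity(self) -> np.ndarray:
        if self.velocity_smoothed is not None:
            return self.velocity_smoothed
        return self.velocity_raw

    @property
    def axial_pitch_medium_um(self) -> float:
        return self.geometry.axial_pixel_pitch_um / self.config.group_index


@dataclass
class AxialVelocityProfile:
    """Column-averaged velocity versus distance from a named interface."""

    distance_um: np.ndarray
    velocity_nm_s: np.ndarray
    n_columns: np.ndarray
    from_interface: str

    def __len__(self) -> int:
        return len(self.distance_um)


def select_reference_pixel(
    amplitude_column: np.ndarray, set_row: int, halfwidth: int = 10
) -> int:
    """Row of the strongest signal within ``halfwidth`` pixels of a set point.

    Ties resolve to the smallest row.
    """
    amplitude_column = np.asarray(amplitude_column)
    lo = max(set_row - halfwidth, 0)
    hi = min(set_row + halfwidth, len(amplitude_column) - 1)
    if lo > hi:
        raise ValueError("reference search window does not intersect the column")
    return lo + int(np.argmax(amplitude_column[lo : hi + 1]))


def temporal_unwrap(series: np.ndarray, axis: int = 0) -> np.ndarray:
    """Unwrap a wrapped phase series over time.

    Consecutive differences are shifted by multiples of 2 pi so each lies in
    (-pi, pi]; the first element is unchanged.
    """
    series = np.asarray(series, dtype=float)
    if series.shape[axis] < 2:
        return series.copy()
    return np.unwrap(series, axis=axis)


def phase_rate(unwrapped: np.ndarray, timestamps: np.ndarray, axis: int = 0) -> np.ndarray:
    """Ordinary-least-squares slope of unwrapped phase against time, rad/s."""
    unwrapped = np.asarray(unwrapped, dtype=float)
    t = np.asarray(timestamps, dtype=float)
    if t.ndim != 1 or t.shape[0] != unwrapped.shape[axis]:
        raise ValueError("timestamps must match the time axis length")
    tc = t - t.mean()
    denom = np.dot(tc, tc)
    if denom == 0:
        raise ValueError("timestamps must not be all equal")
    moved = np.moveaxis(unwrapped, axis, 0)
    return np.tensordot(tc, moved - moved.mean(axis=0), axes=(0, 0)) / denom


def velocity_from_phase_rate(rate, wavelength_nm: float, group_index: float):
    """Convert a temporal phase rate (rad/s) to axial velocity (nm/s)."""
    if wavelength_nm <= 0 or group_index <= 0:
        raise ValueError("wavelength and index must be positive")
    return np.asarray(rate) * wavelength_nm / (4.0 * np.pi * group_index)


def _masked_boxcar(values: np.ndarray, mask: np.ndarray, size: int) -> np.ndarray:
    """Boxcar mean over valid pixels only; the window shrinks at mask edges."""
    filled = np.where(mask, values, 0.0)
    num = ndimage.uniform_filter(filled, size=size, mode="constant")
    den = ndimage.uniform_filter(mask.astype(float), size=size, mode="constant")
    out = np.full(values.shape, np.nan)
    good = mask & (den > 0)
    out[good] = num[good] / den[good]
    return out


def compute_dvi(
    stack: ComplexFrameStack,
    interfaces: CornealInterfaces,
    config: DVIConfig | None = None,
) -> DeformationVelocityImage:
    """Compute a deformation-velocity image from a complex frame stack.

    The per-column set point is the epithelial interface for scenes with an
    epithelium, otherwise the depth equidistant between the anterior and
    posterior surfaces (which keeps both interfaces within the aliasing-free
    range).  The reference phase is that of the single strongest pixel near
    the set point; subtracting it per frame removes bulk motion and anchors
    zero velocity at the reference depth.
    """
    config = config or DVIConfig()
    if stack.n_frames < 2:
        raise ValueError("need at least two frames")
    H, W = stack.shape
    if interfaces.n_cols != W:
        raise ValueError("interfaces were segmented on a different image width")

    amp0 = stack.amplitude(0)
    if config.scene_variant == "with_epithelium" and "epithelial" in interfaces.auxiliary:
        set_rows = interfaces.auxiliary["epithelial"].rows
    elif config.scene_variant == "with_epithelium":
        set_rows = interfaces.anterior.rows
    else:
        set_rows = (interfaces.anterior.rows + interfaces.posterior.rows) // 2

    cols = np.arange(W)
    ref_rows = np.array(
        [
            select_reference_pixel(amp0[:, c], int(set_rows[c]), config.reference_halfwidth)
            for c in cols
        ]
    )

    # referenced phase change from the first frame, computed in the complex
    # domain (equivalent to wrapped phase subtraction)
    ref_vals = stack.frames[:, ref_rows, cols]  # (n_frames, W)
    rel = stack.frames * np.conj(ref_vals)[:, None, :]
    rel = rel * np.conj(rel[0])[None, :, :]
    phase = temporal_unwrap(np.angle(rel), axis=0)

    rate = phase_rate(phase, stack.timestamps, axis=0)
    velocity = velocity_from_phase_rate(
        rate, stack.geometry.centre_wavelength_nm, config.group_index
    )

    mask = interfaces.mask((H, W))
    v_raw = np.where(mask, velocity, np.nan)
    v_max = nyquist_velocity(stack.geometry)
    finite = v_raw[np.isfinite(v_raw)]
    if finite.size and np.max(np.abs(finite)) > 0.95 * v_max:
        warnings.warn(
            "velocities approach the Nyquist cap; aliasing likely", RuntimeWarning
        )
    v_smooth = (
        _masked_boxcar(velocity, mask, config.boxcar_size) if config.smooth else None
    )
    return DeformationVelocityImage(
        velocity_raw=v_raw,
        velocity_smoothed=v_smooth,
        mask=mask,
        reference_rows=ref_rows,
        set_rows=np.asarray(set_rows),
        geometry=stack.geometry,
        config=config,
    )


def axial_profile(
    dvi: DeformationVelocityImage,
    interfaces: CornealInterfaces,
    from_interface: str = "posterior",
) -> AxialVelocityProfile:
    """Mean velocity at each pixel distance from a corneal interface.

    Averages the *unsmoothed* velocity over all columns that have a valid
    pixel at the given distance, then converts pixel distance to geometric
    micrometres in the medium.  Distance increases into the cornea.
    """
    if from_interface not in ("posterior", "anterior"):
        raise ValueError("from_interface must be 'posterior' or 'anterior'")
    v = dvi.velocity_raw
    H, W = v.shape
    thickness = interfaces.posterior.rows - interfaces.anterior.rows
    max_d = int(thickness.max())
    cols = np.arange(W)
    means = np.full(max_d + 1, np.nan)
    counts = np.zeros(max_d + 1, dtype=int)
    for d in range(max_d + 1):
        if from_interface == "posterior":
            rows = interfaces.posterior.rows - d
        else:
            rows = interfaces.anterior.rows + d
        ok = (rows >= 0) & (rows < H) & (d <= thickness)
        vals = v[rows[ok], cols[ok]]
        vals = vals[np.isfinite(vals)]
        counts[d] = vals.size
        if vals.size:
            means[d] = vals.mean()
    if counts.sum() == 0:
        raise ValueError("empty mask: no valid pixels to average")
    distance_um = np.arange(max_d + 1) * dvi.axial_pitch_medium_um
    return AxialVelocityProfile(
        distance_um=distance_um,
        velocity_nm_s=means,
        n_columns=counts,
        from_interface=from_interface,
    )


def noise_floor(
    dvi: DeformationVelocityImage,
    mode: str = "raw",
    interfaces: CornealInterfaces | None = None,
    region: np.ndarray | None = None,
    min_pixels: int = 100,
) -> float:
    """Velocity noise as a spatial standard deviation, nm/s.

    ``raw`` and ``smoothed`` use the per-pixel images over the region
    (default: the whole mask); ``axial_averaged`` uses the column-averaged
    axial profile, whose noise is further suppressed by the averaging.
    """
    if mode in ("raw", "smoothed"):
        values = dvi.velocity_raw if mode == "raw" else dvi.velocity_smoothed
        if values is None:
            raise ValueError("smoothed image not available (smoothing disabled)")
        sel = dvi.mask if region is None else (dvi.mask & region)
        vals = values[sel]
        vals = vals[np.isfinite(vals)]
        if vals.size < min_pixels:
            raise ValueError(f"region too small ({vals.size} < {min_pixels} pixels)")
        return float(np.std(vals, ddof=1))
    if mode == "axial_averaged":
        if interfaces is None:
            raise ValueError("axial_averaged mode requires the interfaces")
        if int(dvi.mask.sum()) < min_pixels:
            raise ValueError("region too small for a noise estimate")
        profile = axial_profile(dvi, interfaces)
        vals = profile.velocity_nm_s[np.isfinite(profile.velocity_nm_s)]
        return float(np.std(vals, ddof=1))
    raise ValueError(f"unknown noise-floor mode {mode!r}")
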