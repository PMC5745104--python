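"""Synthetic corneal OCT phantoms with known deformation ground truth.

The simulator emulates the scene of a de-swelling cornea suspended in a
glass vial as seen by a Fourier-domain OCT system: two bright container-wall
lines, a speckled scattering stroma bounded by smooth anterior/posterior
interfaces, and (optionally) a bright scattering epithelial layer on the
anterior surface.  Frames are generated directly at the complex-B-scan
level: each pixel is a complex number whose magnitude follows the scene
amplitude and whose Fourier phase advances by ``4 pi n_g dz / lambda`` for a
sub-pixel axial displacement ``dz``.

Scatterer displacement over a ten-frame stack is kept far below one axial
pixel (hundreds of nm against a ~12 um pixel), so the amplitude pattern is
held fixed while only the phase evolves; amplitude decorrelation is
negligible in this regime.

Speckle inside the stroma is drawn as a circular complex Gaussian, giving
the Rayleigh amplitude statistics of fully developed OCT speckle.  Additive
complex Gaussian noise models the detection noise floor; the scene SNR is
the ratio of the per-quadrature stromal speckle sigma to the noise sigma.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .geometry import AcquisitionGeometry
from .stack import ComplexFrameStack

__all__ = [
    "SceneLayout",
    "ScenePhantom",
    "DeformationFieldTruth",
    "InvalidLayoutError",
    "make_corneal_scene",
    "make_deformation_field",
    "render_frame_stack",
    "true_velocity_image",
]

FIELD_KINDS = (
    "static",
    "rigid",
    "uniform_strain",
    "exponential_front",
    "model_trajectory",
)


class InvalidLayoutError(ValueError):
    """Interface layout does not fit inside the image or overlaps."""


@dataclass(frozen=True)
class SceneLayout:
    """Geometric description of the vial-plus-cornea scene, in pixels.

    Interface rows are the row of each truth path at the central column;
    anterior and posterior paths bow downward by ``curvature_px`` at the
    lateral edges relative to the centre (a convex cornea seen from above).
    """

    n_rows: int = 360
    n_cols: int = 160
    wall_top_row: float = 40.0
    wall_bottom_row: float = 330.0
    anterior_row: float = 110.0
    posterior_row: float = 260.0
    curvature_px: float = 6.0
    tilt_px: float = 0.0
    with_epithelium: bool = True
    line_thickness: int = 3
    wall_amplitude: float = 12.0
    epithelium_amplitude: float = 6.0
    endothelium_amplitude: float = 4.0
    # specular reflection of the bare anterior surface, painted only when
    # the scattering epithelium is absent
    anterior_reflection_amplitude: float = 3.0


@dataclass
class ScenePhantom:
    """A realized scene: truth paths, mean amplitude and speckle field."""

    layout: SceneLayout
    snr: float
    seed: int
    anterior_rows: np.ndarray
    posterior_rows: np.ndarray
    epithelial_rows: np.ndarray | None
    wall_rows: list
    mean_amplitude: np.ndarray
    base_field: np.ndarray  # complex speckle realization, frame-0 field
    noise_sigma: float

    @property
    def shape(self) -> tuple[int, int]:
        return self.mean_amplitude.shape

    @property
    def with_epithelium(self) -> bool:
        return self.epithelial_rows is not None

    def stroma_mask(self, margin: int = 0) -> np.ndarray:
        """Boolean mask of pixels strictly inside the stroma."""
        rows = np.arange(self.shape[0])[:, None]
        return (rows > self.anterior_rows[None, :] + margin) & (
            rows < self.posterior_rows[None, :] - margin
        )


def _curved_path(layout: SceneLayout, centre_row: float, curvature: float) -> np.ndarray:
    c = np.arange(layout.n_cols, dtype=float)
    u = (c - (layout.n_cols - 1) / 2.0) / ((layout.n_cols - 1) / 2.0)
    return centre_row + curvature * u**2 + layout.tilt_px * u


def make_corneal_scene(
    geometry: AcquisitionGeometry,
    layout: SceneLayout,
    snr: float,
    seed: int,
) -> ScenePhantom:
    """Build a layered corneal-in-vial phantom scene.

    The scene has bright thin container-wall lines, a speckled stroma
    between the anterior and posterior truth paths, an optional bright
    epithelial line on the anterior path, and near-zero amplitude elsewhere.
    Deterministic for a fixed seed.
    """
    if not snr > 0:
        raise ValueError("snr must be strictly positive")
    H, W = layout.n_rows, layout.n_cols
    anterior = _curved_path(layout, layout.anterior_row, layout.curvature_px)
    posterior = _curved_path(layout, layout.posterior_row, layout.curvature_px)
    wall_top = np.full(W, float(layout.wall_top_row))
    wall_bottom = np.full(W, float(layout.wall_bottom_row))

    half = layout.line_thickness // 2 + 1
    if np.any(anterior >= posterior):
        raise InvalidLayoutError("anterior path must lie above posterior path")
    for path in (anterior, posterior):
        if np.any(path < half) or np.any(path > H - 1 - half):
            raise InvalidLayoutError("corneal interface leaves the image")
    if np.any(wall_top + half >= anterior - half) or np.any(
        posterior + half >= wall_bottom - half
    ):
        raise InvalidLayoutError("container walls overlap the cornea")
    if layout.wall_top_row < half or layout.wall_bottom_row > H - 1 - half:
        raise InvalidLayoutError("container wall leaves the image")

    rng = np.random.default_rng(seed)
    rows = np.arange(H)[:, None]

    # stroma: circular complex Gaussian speckle, per-quadrature sigma = 1
    # (inclusive of both interface rows so the amplitude steps sit on the paths)
    stroma = (rows >= np.ceil(anterior)[None, :]) & (rows <= posterior[None, :])
    base = np.zeros((H, W), dtype=np.complex128)
    speckle = rng.normal(size=(H, W)) + 1j * rng.normal(size=(H, W))
    base[stroma] = speckle[stroma]

    def paint_line(path: np.ndarray, amplitude: float, offset: int = 0) -> None:
        centre = np.rint(path).astype(int) + offset
        phases = rng.uniform(-np.pi, np.pi, size=(layout.line_thickness, W))
        for k in range(layout.line_thickness):
            r = centre + k - layout.line_thickness // 2
            ok = (r >= 0) & (r < H)
            base[r[ok], np.arange(W)[ok]] = amplitude * np.exp(
                1j * phases[k, ok]
            )

    paint_line(wall_top, layout.wall_amplitude)
    paint_line(wall_bottom, layout.wall_amplitude)
    if layout.endothelium_amplitude > 0:
        # specular endothelial reflection centred on the posterior truth path
        paint_line(posterior, layout.endothelium_amplitude)
    epithelial = None
    if layout.with_epithelium:
        epithelial = anterior.copy()
        paint_line(epithelial, layout.epithelium_amplitude)
    elif layout.anterior_reflection_amplitude > 0:
        paint_line(anterior, layout.anterior_reflection_amplitude)

    noise_sigma = 0.0 if np.isinf(snr) else 1.0 / snr
    return ScenePhantom(
        layout=layout,
        snr=snr,
        seed=seed,
        anterior_rows=anterior,
        posterior_rows=posterior,
        epithelial_rows=epithelial,
        wall_rows=[wall_top, wall_bottom],
        mean_amplitude=np.abs(base),
        base_field=base,
        noise_sigma=noise_sigma,
    )


@dataclass
class DeformationFieldTruth:
    """Ground-truth axial deformation-velocity field.

    ``velocity_of(depth_um, lateral_um, t_s)`` returns the signed axial
    velocity in nm/s (positive toward larger depth) of the material point at
    geometric depth ``depth_um`` (in the medium); ``bulk_velocity_of(t_s)``
    is a rigid axial velocity applied to the whole scene on top of it.
    """

    kind: str
    velocity_of: Callable[[np.ndarray, np.ndarray, float], np.ndarray]
    bulk_velocity_of: Callable[[float], float]
    params: dict = field(default_factory=dict)


def make_deformation_field(kind: str, **params) -> DeformationFieldTruth:
    """Construct a ground-truth field of the requested kind.

    Kinds
    -----
    static
        No motion at all.
    rigid
        Zero deformation; uniform bulk velocity ``bulk_velocity_nm_s``.
    uniform_strain
        ``v(z) = 1000 * strain_rate * (z - z_ref_um)`` nm/s for
        ``strain_rate`` in 1/s and depths in um.
    exponential_front
        A de-swelling front at the posterior boundary:
        ``v(z) = boundary_velocity_nm_s * exp(-(boundary_depth_um - z)
        / decay_length_um)`` for ``z <= boundary_depth_um``.
    model_trajectory
        Velocities interpolated from a de-swelling model trajectory; the
        model's anterior face is placed at ``anterior_depth_um``.

    Every kind accepts ``bulk_velocity_nm_s`` (constant rigid motion).
    """
    if kind not in FIELD_KINDS:
        raise ValueError(f"unknown deformation field kind {kind!r}")
    bulk = float(params.pop("bulk_velocity_nm_s", 0.0))

    def bulk_of(t: float) -> float:
        return bulk

    if kind in ("static", "rigid"):

        def velocity_of(z, x, t):
            return np.zeros_like(np.asarray(z, dtype=float))

    elif kind == "uniform_strain":
        s = float(params["strain_rate"])  # 1/s
        z_ref = float(params.get("z_ref_um", 0.0))

        def velocity_of(z, x, t):
            return 1000.0 * s * (np.asarray(z, dtype=float) - z_ref)

    elif kind == "exponential_front":
        v0 = float(params["boundary_velocity_nm_s"])
        ell = float(params["decay_length_um"])
        zb = float(params["boundary_depth_um"])

        def velocity_of(z, x, t):
            z = np.asarray(z, dtype=float)
            return v0 * np.exp(-np.maximum(zb - z, 0.0) / ell)

    elif kind == "model_trajectory":
        trajectory = params["trajectory"]
        z0 = float(params["anterior_depth_um"])

        def velocity_of(z, x, t):
            z = np.asarray(z, dtype=float)
            return trajectory.velocity_at(z - z0, t)

    return DeformationFieldTruth(
        kind=kind, velocity_of=velocity_of, bulk_velocity_of=bulk_of, params=params
    )


def _displacement_samples(
    phantom_shape: tuple[int, int],
    fieldtruth: DeformationFieldTruth,
    geometry: AcquisitionGeometry,
    timestamps: np.ndarray,
) -> np.ndarray:
    """Cumulative axial displacement (nm) of every pixel at every frame time.

    Trapezoidal integration of the velocity field; exact for fields that are
    constant in time over the stack.
    """
    H, W = phantom_shape
    Z = geometry.depth_um(np.arange(H))[:, None] * np.ones((1, W))
    X = np.arange(W)[None, :] * geometry.lateral_pixel_pitch_um * np.ones((H, 1))
    d = np.zeros((len(timestamps), H, W))
    v_prev = fieldtruth.velocity_of(Z, X, timestamps[0]) + fieldtruth.bulk_velocity_of(
        timestamps[0]
    )
    for k in range(1, len(timestamps)):
        v_k = fieldtruth.velocity_of(Z, X, timestamps[k]) + fieldtruth.bulk_velocity_of(
            timestamps[k]
        )
        dt = timestamps[k] - timestamps[k - 1]
        d[k] = d[k - 1] + 0.5 * (v_prev + v_k) * dt
        v_prev = v_k
    return d


def render_frame_stack(
    phantom: ScenePhantom,
    fieldtruth: DeformationFieldTruth,
    geometry: AcquisitionGeometry,
    seed: int,
    n_frames: int | None = None,
    t_start: float = 0.0,
) -> ComplexFrameStack:
    """Render a complex B-scan stack of the phantom under a velocity field.

    Each pixel's phase advances by ``4 pi n_g / lambda`` times its cumulative
    axial displacement (deformation plus bulk motion); the amplitude pattern
    is the fixed phantom speckle.  Independent complex Gaussian noise is
    added per pixel per frame at the phantom noise level.  Deterministic for
    a fixed seed.
    """
    n = geometry.n_frames if n_frames is None else n_frames
    if n < 1:
        raise ValueError("need at least one frame")
    timestamps = t_start + geometry.timestamps(n)
    disp = _displacement_samples(phantom.shape, fieldtruth, geometry, timestamps)
    axial_range_nm = phantom.shape[0] * geometry.axial_pitch_medium_um * 1000.0
    if np.max(np.abs(disp)) > axial_range_nm:
        raise ValueError("displacement exceeds the axial range; scene wraps out of frame")

    kappa = geometry.phase_per_displacement  # rad per nm
    frames = phantom.base_field[None, :, :] * np.exp(1j * kappa * disp)
    if phantom.noise_sigma > 0:
        rng = np.random.default_rng(seed)
        noise = rng.normal(scale=phantom.noise_sigma, size=frames.shape) + 1j * rng.normal(
            scale=phantom.noise_sigma, size=frames.shape
        )
        frames = frames + noise
    return ComplexFrameStack(frames=frames, timestamps=timestamps, geometry=geometry)


def true_velocity_image(
    phantom: ScenePhantom,
    fieldtruth: DeformationFieldTruth,
    geometry: AcquisitionGeometry,
    n_frames: int | None = None,
    t_start: float = 0.0,
) -> np.ndarray:
    """Ground-truth per-pixel velocity over a stack's measurement window, nm/s.

    Defined as the least-squares slope of the true displacement samples
    against the frame timestamps — i.e. exactly the quantity a phase-rate
    estimator observes, computed from the deformation field itself (no
    phases involved).  Bulk motion is excluded.
    """
    n = geometry.n_frames if n_frames is None else n_frames
    timestamps = t_start + geometry.timestamps(n)
    no_bulk = DeformationFieldTruth(
        kind=fieldtruth.kind,
        velocity_of=fieldtruth.velocity_of,
        bulk_velocity_of=lambda t: 0.0,
        params=fieldtruth.params,
    )
    disp = _displacement_samples(phantom.shape, no_bulk, geometry, timestamps)
    t = timestamps - timestamps.mean()
    return np.tensordot(t, disp, axes=(0, 0)) / np.dot(t, t)
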