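"""Iterative graph-search segmentation of corneal and container interfaces.

Interfaces in a structural B-scan appear as bright lines (container walls,
scattering epithelium) or sharp vertical steps in amplitude (anterior and
posterior corneal surfaces).  Both are recovered as left-to-right paths of
minimum summed energy through a per-pixel cost map — the inverted amplitude
for bright lines, the inverted vertical-gradient magnitude for steps — with
a per-column vertical step bound enforcing continuity.  Multiple interfaces
are found by iterating the search with pixels near previously found paths
blocked.

The minimum-energy path is computed by dynamic programming over columns; on
ties the lexicographically smallest path (smallest rows, from the leftmost
column) is returned so results are fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "EnergyMap",
    "InterfacePath",
    "CornealInterfaces",
    "SegmentationConfig",
    "FlattenedImage",
    "NoPathError",
    "SegmentationError",
    "build_energy",
    "min_energy_path",
    "iterate_paths",
    "flatten_to_profile",
    "segment_cornea",
]


class NoPathError(RuntimeError):
    """No unblocked left-to-right path exists under the step bound."""

    def __init__(self, message: str, paths_found: list | None = None):
        super().__init__(message)
        self.paths_found = paths_found or []


class SegmentationError(RuntimeError):
    """The segmentation pipeline could not produce valid corneal interfaces."""


@dataclass
class EnergyMap:
    """Non-negative per-pixel path cost with its provenance."""

    values: np.ndarray
    kind: str  # inverted_amplitude | inverted_vertical_gradient
    median_size: int
    boxcar_size: int

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class InterfacePath:
    """Row index per column of one left-to-right interface path."""

    rows: np.ndarray
    label: str = "unlabeled"
    step_bound: int = 1

    def __post_init__(self) -> None:
        self.rows = np.asarray(self.rows, dtype=int)

    def __len__(self) -> int:
        return len(self.rows)

    def shifted(self, offset: int, label: str | None = None) -> "InterfacePath":
        return InterfacePath(
            self.rows + offset, label or self.label, self.step_bound
        )


@dataclass
class CornealInterfaces:
    """Anterior/posterior corneal paths plus auxiliary interfaces."""

    anterior: InterfacePath
    posterior: InterfacePath
    auxiliary: dict = field(default_factory=dict)
    source: str = ""

    def __post_init__(self) -> None:
        if np.any(self.anterior.rows >= self.posterior.rows):
            raise SegmentationError(
                "anterior path must lie strictly above posterior path"
            )

    @property
    def n_cols(self) -> int:
        return len(self.anterior.rows)

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        """Boolean mask of the segmented cornea (inclusive of both paths)."""
        rows = np.arange(shape[0])[:, None]
        return (rows >= self.anterior.rows[None, :]) & (
            rows <= self.posterior.rows[None, :]
        )


def build_energy(
    image: np.ndarray,
    kind: str,
    median_size: int = 3,
    boxcar_size: int = 5,
) -> EnergyMap:
    """Build a path-search energy map from an amplitude image.

    The image is median-filtered, converted to a cost (``max - amplitude``
    for bright-line search, ``max - |vertical gradient|`` for edge search)
    and boxcar-smoothed.  The result is finite and non-negative.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("image must be 2-D")
    if not np.all(np.isfinite(image)):
        raise ValueError("image contains non-finite pixels")
    if np.any(image < 0):
        raise ValueError("amplitude image must be non-negative")
    for name, size in (("median_size", median_size), ("boxcar_size", boxcar_size)):
        if size < 1 or size % 2 == 0:
            raise ValueError(f"{name} must be odd and >= 1")

    smoothed = ndimage.median_filter(image, size=median_size, mode="nearest")
    if kind == "inverted_amplitude":
        energy = smoothed.max() - smoothed
    elif kind == "inverted_vertical_gradient":
        grad = np.abs(np.gradient(smoothed, axis=0))
        energy = grad.max() - grad
    else:
        raise ValueError(f"unknown energy kind {kind!r}")
    energy = ndimage.uniform_filter(energy, size=boxcar_size, mode="nearest")
    return EnergyMap(
        values=np.maximum(energy, 0.0),
        kind=kind,
        median_size=median_size,
        boxcar_size=boxcar_size,
    )


def _suffix_costs(cost: np.ndarray, step_bound: int) -> np.ndarray:
    """D[r, c] = minimum total cost of a path from (r, c) to the right edge."""
    H, W = cost.shape
    D = np.empty_like(cost)
    D[:, -1] = cost[:, -1]
    size = 2 * step_bound + 1
    for c in range(W - 2, -1, -1):
        best_next = ndimage.minimum_filter1d(D[:, c + 1], size=size, mode="nearest")
        D[:, c] = cost[:, c] + best_next
    return D


def min_energy_path(
    energy: EnergyMap | np.ndarray,
    blocked: np.ndarray | None = None,
    step_bound: int = 1,
    label: str = "unlabeled",
) -> InterfacePath:
    """Minimum-total-energy left-to-right path under a vertical step bound.

    Among all paths with ``|row[c+1] - row[c]| <= step_bound`` that avoid
    blocked pixels, returns the one of smallest summed pixel energy; ties
    are broken toward the lexicographically smallest row sequence starting
    from the leftmost column.
    """
    values = energy.values if isinstance(energy, EnergyMap) else np.asarray(energy, float)
    H, W = values.shape
    if step_bound < 0:
        raise ValueError("step_bound must be >= 0")
    cost = values.astype(float).copy()
    if blocked is not None:
        blocked = np.asarray(blocked, dtype=bool)
        if blocked.shape != cost.shape:
            raise ValueError("blocked mask shape mismatch")
        cost[blocked] = np.inf

    D = _suffix_costs(cost, step_bound)
    if not np.any(np.isfinite(D[:, 0])):
        raise NoPathError("no unblocked path exists under the step bound")

    rows = np.empty(W, dtype=int)
    rows[0] = int(np.argmin(D[:, 0]))  # argmin takes the smallest row on ties
    for c in range(1, W):
        lo = max(rows[c - 1] - step_bound, 0)
        hi = min(rows[c - 1] + step_bound, H - 1)
        window = D[lo : hi + 1, c]
        rows[c] = lo + int(np.argmin(window))
    if not np.isfinite(D[rows[0], 0]):
        raise NoPathError("no unblocked path exists under the step bound")
    return InterfacePath(rows=rows, label=label, step_bound=step_bound)


def _block_around(blocked: np.ndarray, path: InterfacePath, halfwidth: int) -> None:
    H = blocked.shape[0]
    for c, r in enumerate(path.rows):
        lo = max(r - halfwidth, 0)
        hi = min(r + halfwidth, H - 1)
        blocked[lo : hi + 1, c] = True


def iterate_paths(
    energy: EnergyMap | np.ndarray,
    n_paths: int,
    block_halfwidth: int = 10,
    step_bound: int = 1,
    blocked: np.ndarray | None = None,
    label: str = "unlabeled",
) -> list[InterfacePath]:
    """Find ``n_paths`` successive minimum-energy paths.

    After each path is found, all pixels within ``block_halfwidth`` rows of
    it are blocked before the next search; paths are returned in discovery
    order.  Raises :class:`NoPathError` (carrying the paths found so far) if
    blocking exhausts a column first.
    """
    if n_paths < 1:
        raise ValueError("n_paths must be >= 1")
    values = energy.values if isinstance(energy, EnergyMap) else np.asarray(energy, float)
    work_blocked = (
        np.zeros(values.shape, dtype=bool) if blocked is None else np.asarray(blocked, bool).copy()
    )
    paths: list[InterfacePath] = []
    for k in range(n_paths):
        try:
            path = min_energy_path(
                energy, blocked=work_blocked, step_bound=step_bound, label=f"{label}_{k}"
            )
        except NoPathError as exc:
            raise NoPathError(
                f"found only {len(paths)} of {n_paths} paths before blocking "
                "exhausted a column",
                paths_found=paths,
            ) from exc
        paths.append(path)
        _block_around(work_blocked, path, block_halfwidth)
    return paths


@dataclass
class FlattenedImage:
    """An image with each column circularly shifted to flatten a path."""

    values: np.ndarray
    shifts: np.ndarray  # shift applied per column: flat_row = (row + shift) mod H
    target_row: int

    def to_original_rows(self, flat_rows: np.ndarray) -> np.ndarray:
        H = self.values.shape[0]
        return (np.asarray(flat_rows, dtype=int) - self.shifts) % H

    def to_flat_rows(self, rows: np.ndarray) -> np.ndarray:
        H = self.values.shape[0]
        return (np.asarray(rows, dtype=int) + self.shifts) % H

    def unflatten(self) -> np.ndarray:
        """Invert the per-column shifts, restoring the original image."""
        out = np.empty_like(self.values)
        for c in range(self.values.shape[1]):
            out[:, c] = np.roll(self.values[:, c], -self.shifts[c])
        return out


def flatten_to_profile(
    image: np.ndarray,
    path: InterfacePath,
    target_row: int | None = None,
) -> FlattenedImage:
    """Circularly shift each column so the path lands on one constant row.

    The per-column shifts are recorded so found paths (or the image) can be
    mapped back to original coordinates exactly.
    """
    image = np.asarray(image)
    if image.ndim != 2 or image.shape[1] != len(path.rows):
        raise ValueError("path length must equal image width")
    if target_row is None:
        target_row = int(np.round(np.median(path.rows)))
    shifts = (target_row - path.rows).astype(int)
    out = np.empty_like(image)
    for c in range(image.shape[1]):
        out[:, c] = np.roll(image[:, c], shifts[c])
    return FlattenedImage(values=out, shifts=shifts, target_row=target_row)


@dataclass
class SegmentationConfig:
    """Tunable parameters of the corneal segmentation pipeline.

    Filter sizes and the blocking halfwidth default to small robust values;
    all are deliberately overridable per scene.  ``blocked_rows`` is an
    optional user-supplied boolean mask (image shape) of pixels the search
    must avoid — the configuration-level replacement for interactive review
    of false paths.
    """

    scene_variant: str = "with_epithelium"  # or "without_epithelium"
    row_range: tuple[int, int] | None = None
    median_size: int = 3
    boxcar_size: int = 5
    block_halfwidth: int = 10
    step_bound: int = 1
    n_wall_paths: int = 2
    flatten_margin_up: int = 180
    flatten_margin_down: int = 360
    min_thickness_px: int = 10
    contrast_min: float = 2.0
    blocked_rows: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.scene_variant not in ("with_epithelium", "without_epithelium"):
            raise ValueError(f"unknown scene_variant {self.scene_variant!r}")


def segment_cornea(image: np.ndarray, config: SegmentationConfig) -> CornealInterfaces:
    """Full iterative graph-search segmentation of a corneal B-scan.

    Pipeline: restrict to the configured vertical range; find and block the
    bright container-wall lines with the inverted-amplitude energy; find an
    approximate anterior profile (amplitude search hits the scattering
    epithelium when present, otherwise a vertical-gradient search recovers
    the interface); flatten the image to that profile and discard rows
    outside the configured margins; run a final vertical-gradient search for
    the anterior and posterior surfaces in the flattened image; map all
    paths back to original coordinates.

    Raises :class:`SegmentationError` when no plausible cornea is found
    (interfaces out of order, implausibly thin, or without amplitude
    contrast against the background).
    """
    image = np.asarray(image, dtype=float)
    H, W = image.shape
    row_lo, row_hi = config.row_range if config.row_range is not None else (0, H)
    sub = image[row_lo:row_hi]
    base_blocked = np.zeros(sub.shape, dtype=bool)
    if config.blocked_rows is not None:
        base_blocked |= np.asarray(config.blocked_rows, bool)[row_lo:row_hi]

    # container walls: bright lines, inverted-amplitude search
    amp_energy = build_energy(
        sub, "inverted_amplitude", config.median_size, config.boxcar_size
    )
    blocked = base_blocked.copy()
    walls = iterate_paths(
        amp_energy,
        config.n_wall_paths,
        block_halfwidth=config.block_halfwidth,
        step_bound=config.step_bound,
        blocked=blocked,
        label="vial_wall",
    )
    for wall in walls:
        _block_around(blocked, wall, config.block_halfwidth)

    # approximate anterior profile
    if config.scene_variant == "with_epithelium":
        approx = min_energy_path(
            amp_energy, blocked=blocked, step_bound=config.step_bound, label="epithelial"
        )
    else:
        grad_energy = build_energy(
            sub, "inverted_vertical_gradient", config.median_size, config.boxcar_size
        )
        approx = min_energy_path(
            grad_energy, blocked=blocked, step_bound=config.step_bound, label="anterior_approx"
        )

    # flatten to the approximate profile and crop to the margins around it
    flat = flatten_to_profile(sub, approx)
    crop_lo = max(flat.target_row - config.flatten_margin_up, 0)
    crop_hi = min(flat.target_row + config.flatten_margin_down, sub.shape[0])
    flat_crop = flat.values[crop_lo:crop_hi]
    flat_blocked = np.zeros_like(flat_crop, dtype=bool)
    wall_block = base_blocked.copy()
    for wall in walls:  # keep the bright wall edges out of the final search
        _block_around(wall_block, wall, config.block_halfwidth)
    for c in range(W):
        col_blocked = np.roll(wall_block[:, c], flat.shifts[c])
        flat_blocked[:, c] = col_blocked[crop_lo:crop_hi]

    # final vertical-gradient search for the two corneal surfaces
    grad_energy = build_energy(
        flat_crop, "inverted_vertical_gradient", config.median_size, config.boxcar_size
    )
    try:
        final = iterate_paths(
            grad_energy,
            2,
            block_halfwidth=config.block_halfwidth,
            step_bound=config.step_bound,
            blocked=flat_blocked,
            label="corneal",
        )
    except NoPathError as exc:
        raise SegmentationError("could not find two corneal interfaces") from exc

    mapped = []
    for path in final:
        orig = flat.to_original_rows(path.rows + crop_lo) + row_lo
        mapped.append(InterfacePath(orig, path.label, config.step_bound))
    mapped.sort(key=lambda p: float(np.mean(p.rows)))
    anterior, posterior = mapped
    anterior.label, posterior.label = "anterior", "posterior"

    if np.any(posterior.rows - anterior.rows < config.min_thickness_px):
        raise SegmentationError("segmented cornea is implausibly thin")

    # plausibility: the stroma must be brighter than the background above it
    rows = np.arange(H)[:, None]
    inside = (rows > anterior.rows[None, :]) & (rows < posterior.rows[None, :])
    above = (rows < anterior.rows[None, :] - config.block_halfwidth) & (
        rows > anterior.rows[None, :] - 3 * config.block_halfwidth
    )
    if inside.sum() == 0 or above.sum() == 0:
        raise SegmentationError("degenerate segmentation geometry")
    contrast = image[inside].mean() / max(image[above].mean(), 1e-30)
    if contrast < config.contrast_min:
        raise SegmentationError(
            f"no corneal amplitude contrast (ratio {contrast:.2f} < "
            f"{config.contrast_min})"
        )

    auxiliary = {f"vial_wall_{k}": w.shifted(row_lo) for k, w in enumerate(walls)}
    if config.scene_variant == "with_epithelium":
        auxiliary["epithelial"] = approx.shifted(row_lo, "epithelial")
    try:
        return CornealInterfaces(
            anterior=anterior, posterior=posterior, auxiliary=auxiliary
        )
    except SegmentationError:
        raise
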