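"""Structured run configuration for the end-to-end pipeline.

A run configuration is a nested mapping (usually loaded from YAML) with one
section per pipeline stage.  Validation is strict: an unknown key anywhere
raises a :class:`ConfigError` naming it, so typos never silently fall back
to defaults.  All randomness in a run flows from the single root ``seed``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .deswell import DeswellModelParams
from .dvi import DVIConfig
from .geometry import AcquisitionGeometry
from .phantom import SceneLayout
from .segmentation import SegmentationConfig

__all__ = ["ConfigError", "RunConfig", "load_config"]


class ConfigError(ValueError):
    """A configuration mapping failed validation."""


def _build(cls, section: dict, name: str, skip: tuple = ()):
    allowed = {f.name for f in dataclasses.fields(cls)} - set(skip)
    unknown = set(section) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) in '{name}': {sorted(unknown)}")
    return cls(**section)


@dataclass
class RunConfig:
    """Fully resolved configuration of one pipeline run."""

    seed: int = 0
    out_dir: str = "dvi_run"
    stages: list = field(
        default_factory=lambda: ["simulate", "segment", "dvi", "thickness", "model_fit"]
    )
    sample_times_s: list = field(default_factory=lambda: [300.0, 1200.0, 3600.0])
    snr: float = 20.0
    geometry: AcquisitionGeometry = field(default_factory=AcquisitionGeometry)
    # tall enough for a fully swollen (~1 mm) cornea at the default pitch
    scene: SceneLayout = field(
        default_factory=lambda: SceneLayout(
            n_rows=480, wall_bottom_row=455.0, anterior_row=100.0
        )
    )
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    dvi: DVIConfig = field(default_factory=DVIConfig)
    # default run: a moderately leaky endothelium whose velocities stay
    # below the Nyquist cap of the default geometry, and an element count
    # small enough for an interactive fit
    model: DeswellModelParams = field(
        default_factory=lambda: DeswellModelParams(L_endo=40e-12, n_elements=12)
    )
    fit_bounds: dict = field(default_factory=dict)
    fit_grid_points: int = 3
    fit_maxiter: int = 2000

    def resolved(self) -> dict:
        """Plain-dict view of the full configuration, for manifests."""

        def plain(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {
                    k: plain(v) for k, v in dataclasses.asdict(obj).items()
                }
            if isinstance(obj, np.ndarray):
                return obj.tolist()
            if isinstance(obj, (list, tuple)):
                return [plain(v) for v in obj]
            if isinstance(obj, dict):
                return {k: plain(v) for k, v in obj.items()}
            if isinstance(obj, (np.floating, np.integer)):
                return obj.item()
            return obj

        return {
            "seed": self.seed,
            "out_dir": self.out_dir,
            "stages": list(self.stages),
            "sample_times_s": list(self.sample_times_s),
            "snr": self.snr,
            "geometry": plain(self.geometry),
            "scene": plain(self.scene),
            "segmentation": plain(self.segmentation),
            "dvi": plain(self.dvi),
            "model": plain(self.model),
            "fit_bounds": plain(self.fit_bounds),
            "fit_grid_points": self.fit_grid_points,
            "fit_maxiter": self.fit_maxiter,
        }


_SECTION_TYPES = {
    "geometry": AcquisitionGeometry,
    "scene": SceneLayout,
    "segmentation": SegmentationConfig,
    "dvi": DVIConfig,
    "model": DeswellModelParams,
}
_SCALAR_KEYS = {
    "seed",
    "out_dir",
    "stages",
    "sample_times_s",
    "snr",
    "fit_bounds",
    "fit_grid_points",
    "fit_maxiter",
}


def load_config(source) -> RunConfig:
    """Build a validated :class:`RunConfig` from a mapping or a YAML path."""
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            mapping = yaml.safe_load(fh) or {}
    else:
        mapping = dict(source)
    unknown = set(mapping) - _SCALAR_KEYS - set(_SECTION_TYPES)
    if unknown:
        raise ConfigError(f"unknown top-level key(s): {sorted(unknown)}")
    kwargs = {k: mapping[k] for k in _SCALAR_KEYS if k in mapping}
    for name, cls in _SECTION_TYPES.items():
        if name in mapping:
            section = dict(mapping[name] or {})
            skip = ("blocked_rows", "pressure_law") if name in ("segmentation", "model") else ()
            kwargs[name] = _build(cls, section, name, skip=skip)
    return RunConfig(**kwargs)
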