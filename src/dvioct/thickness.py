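"""Automated corneal thickness time series from segmented B-scan stacks.

Thickness is reported geometrically: the anterior-to-posterior optical
(air-equivalent) separation divided by a constant group refractive index
(1.37 assumed for the cornea; hydration-driven variation of the index is
deliberately ignored).  Stacks acquired at irregular intervals — e.g. once
a minute during rapid de-swelling, every ten minutes later — are supported;
segmentation failures at individual time points are recorded as gaps rather
than aborting the series.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import AcquisitionGeometry
from .segmentation import (
    CornealInterfaces,
    SegmentationConfig,
    SegmentationError,
    NoPathError,
    segment_cornea,
)
from .stack import ComplexFrameStack

__all__ = ["ThicknessSeries", "thickness_per_column", "thickness_series"]


@dataclass
class ThicknessSeries:
    """Mean geometric corneal thickness versus time.

    ``time_min`` is minutes since transfer to the de-swelling solution;
    ``sd_um`` is the per-column spread at each time point.  ``failures``
    lists (time_min, reason) for time points where segmentation failed.
    """

    time_min: np.ndarray
    mean_thickness_um: np.ndarray
    sd_um: np.ndarray
    n_columns: np.ndarray
    group_index: float
    failures: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.time_min = np.asarray(self.time_min, dtype=float)
        self.mean_thickness_um = np.asarray(self.mean_thickness_um, dtype=float)
        if len(self.time_min) > 1 and not np.all(np.diff(self.time_min) > 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.mean_thickness_um <= 0):
            raise ValueError("thickness must be positive")

    def __len__(self) -> int:
        return len(self.time_min)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_min": self.time_min,
                "mean_thickness_um": self.mean_thickness_um,
                "sd_um": self.sd_um,
                "n_columns": self.n_columns,
            }
        )


def thickness_per_column(
    interfaces: CornealInterfaces, geometry: AcquisitionGeometry
) -> np.ndarray:
    """Geometric thickness of each column, micrometres.

    ``(posterior_row - anterior_row) * axial_pixel_pitch_air / n_G``.
    """
    sep = interfaces.posterior.rows - interfaces.anterior.rows
    if np.any(sep <= 0):
        raise ValueError("anterior/posterior ordering violated (zero thickness)")
    return sep * geometry.axial_pixel_pitch_um / geometry.group_index


def _central_columns(n_cols: int, fraction: float) -> slice:
    drop = int(round(n_cols * (1.0 - fraction) / 2.0))
    return slice(drop, n_cols - drop)


def thickness_series(
    stacks: list[ComplexFrameStack],
    config: SegmentationConfig | None = None,
    central_fraction: float = 0.8,
) -> ThicknessSeries:
    """Mean thickness at each stack's acquisition time, sorted by time.

    Each stack's frame-0 amplitude is segmented; the mean is taken over a
    central fraction of columns (default 80%) to avoid edge artefacts.  A
    stack whose segmentation fails contributes a gap (recorded in
    ``failures``) instead of aborting the series.
    """
    if not stacks:
        raise ValueError("need at least one stack")
    config = config or SegmentationConfig()
    records = []
    failures = []
    for stack in sorted(stacks, key=lambda s: s.timestamps[0]):
        t_min = stack.timestamps[0] / 60.0
        try:
            interfaces = segment_cornea(stack.amplitude(0), config)
            per_col = thickness_per_column(interfaces, stack.geometry)
        except (SegmentationError, NoPathError, ValueError) as exc:
            failures.append((t_min, str(exc)))
            continue
        sel = _central_columns(len(per_col), central_fraction)
        central = per_col[sel]
        records.append(
            (t_min, central.mean(), central.std(ddof=1), central.size, stack.geometry.group_index)
        )
    if not records:
        raise RuntimeError("segmentation failed at every time point")
    records.sort(key=lambda r: r[0])
    t, mean, sd, n, _ = zip(*records)
    return ThicknessSeries(
        time_min=np.array(t),
        mean_thickness_um=np.array(mean),
        sd_um=np.array(sd),
        n_columns=np.array(n),
        group_index=records[0][4],
        failures=failures,
    )
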