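"""Time-ordered stacks of complex-valued OCT B-scans."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import AcquisitionGeometry

__all__ = ["ComplexFrameStack"]


@dataclass
class ComplexFrameStack:
    """A stack of complex B-scans with acquisition metadata.

    Attributes
    ----------
    frames
        Complex array of shape ``(n_frames, n_rows, n_cols)``.  The complex
        argument of each pixel is the Fourier phase; the magnitude is the
        structural OCT amplitude.
    timestamps
        Acquisition time of each frame, seconds; strictly increasing.
    geometry
        Instrument constants.
    """

    frames: np.ndarray
    timestamps: np.ndarray
    geometry: AcquisitionGeometry

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be (n_frames, n_rows, n_cols)")
        if not np.iscomplexobj(self.frames):
            raise ValueError("frames must be complex-valued")
        if self.timestamps.shape != (self.frames.shape[0],):
            raise ValueError("one timestamp per frame required")
        if self.frames.shape[0] > 1 and not np.all(np.diff(self.timestamps) > 0):
            raise ValueError("timestamps must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        """(n_rows, n_cols) of a single B-scan."""
        return self.frames.shape[1:]

    def amplitude(self, frame: int = 0) -> np.ndarray:
        """Structural amplitude image of one frame."""
        return np.abs(self.frames[frame])

    def phase(self) -> np.ndarray:
        """Wrapped Fourier phase of every pixel in every frame, rad in (-pi, pi]."""
        return np.angle(self.frames)
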