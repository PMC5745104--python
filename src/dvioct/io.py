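"""File I/O for complex frame stacks, images and tables.

Complex B-scan stacks are stored in HDF5 (no community-standard container
exists for complex OCT stacks): datasets ``/real``, ``/imag`` and
``/timestamps`` at full float precision, with the acquisition-geometry
fields as root attributes.  An optional ``/truth`` group carries phantom
ground truth (interface paths, velocity-field samples) alongside synthetic
stacks.  Amplitude previews go to multi-page TIFF; velocity images to
floating-point TIFF; tables to CSV.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile

from .geometry import AcquisitionGeometry
from .stack import ComplexFrameStack

__all__ = [
    "FormatError",
    "write_stack",
    "read_stack",
    "write_image",
    "read_image",
    "write_table",
    "read_table",
    "write_amplitude_preview",
]


class FormatError(RuntimeError):
    """A container file is malformed or missing a required dataset."""


def write_stack(
    path, stack: ComplexFrameStack, truth: dict | None = None
) -> None:
    """Write a complex stack (and optional ground-truth arrays) to HDF5."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        # track_times=False keeps files byte-identical across reruns
        f.create_dataset("real", data=stack.frames.real, track_times=False)
        f.create_dataset("imag", data=stack.frames.imag, track_times=False)
        f.create_dataset("timestamps", data=stack.timestamps, track_times=False)
        for key, value in stack.geometry.as_attrs().items():
            f.attrs[key] = value
        if truth:
            grp = f.create_group("truth")
            for key, value in truth.items():
                grp.create_dataset(key, data=np.asarray(value), track_times=False)


def read_stack(path) -> tuple[ComplexFrameStack, dict]:
    """Read a complex stack from HDF5; returns (stack, truth-dict)."""
    path = Path(path)
    try:
        with h5py.File(path, "r") as f:
            for name in ("real", "imag", "timestamps"):
                if name not in f:
                    raise FormatError(f"{path}: missing dataset /{name}")
            frames = f["real"][...] + 1j * f["imag"][...]
            timestamps = f["timestamps"][...]
            geometry = AcquisitionGeometry.from_attrs(f.attrs)
            truth = {}
            if "truth" in f:
                truth = {k: f["truth"][k][...] for k in f["truth"]}
    except OSError as exc:
        raise FormatError(f"{path}: not a readable HDF5 container ({exc})") from exc
    except KeyError as exc:
        raise FormatError(f"{path}: missing geometry attribute {exc}") from exc
    return ComplexFrameStack(frames=frames, timestamps=timestamps, geometry=geometry), truth


def write_image(path, image: np.ndarray) -> None:
    """Write a 2-D image: float TIFF for .tif/.tiff, 8-bit PNG otherwise."""
    path = Path(path)
    image = np.asarray(image)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, image.astype(np.float32))
    else:
        from matplotlib import pyplot as plt

        finite = image[np.isfinite(image)]
        lo, hi = (finite.min(), finite.max()) if finite.size else (0.0, 1.0)
        plt.imsave(path, np.nan_to_num(image, nan=lo), vmin=lo, vmax=hi, cmap="viridis")


def read_image(path) -> np.ndarray:
    path = Path(path)
    try:
        return tifffile.imread(path)
    except (tifffile.TiffFileError, ValueError, OSError) as exc:
        raise FormatError(f"{path}: not a readable TIFF ({exc})") from exc


def write_amplitude_preview(path, stack: ComplexFrameStack) -> None:
    """Multi-page float TIFF of per-frame amplitudes."""
    tifffile.imwrite(Path(path), np.abs(stack.frames).astype(np.float32))


def write_table(path, frame: pd.DataFrame) -> None:
    frame.to_csv(Path(path), index=False, float_format="%.6g")


def read_table(path) -> pd.DataFrame:
    try:
        return pd.read_csv(Path(path))
    except (pd.errors.ParserError, OSError) as exc:
        raise FormatError(f"{path}: not a readable CSV ({exc})") from exc
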