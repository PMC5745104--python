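"""End-to-end orchestration: simulate -> segment -> DVI/thickness -> model fit.

A pipeline run drives the whole method on synthetic data in closed loop:
a de-swelling model trajectory defines the ground-truth motion, complex
frame stacks are rendered from it at the configured sampling times, each is
segmented, thickness and DVI profiles are measured, and the model constants
are re-fitted from the measured profiles.  Every artefact is written under
the configured output directory and listed, with its SHA-256 checksum, in a
JSON manifest.  A failing stage is recorded in the manifest and later
independent stages are still attempted.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig
from .deswell import fit_to_dvi, model_velocity_profile, simulate
from .dvi import axial_profile, compute_dvi
from .io import write_amplitude_preview, write_image, write_stack, write_table
from .phantom import make_corneal_scene, make_deformation_field, render_frame_stack
from .segmentation import segment_cornea
from .thickness import thickness_per_column, thickness_series

__all__ = ["run_pipeline"]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages and return the run manifest.

    Idempotent for identical configuration and seed: every artefact is a
    deterministic function of both.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": config.resolved(),
        "stages": {},
        "artifacts": [],
    }
    rng_root = np.random.default_rng(config.seed)
    seeds = rng_root.integers(0, 2**31 - 1, size=16)

    def record(stage: str, paths: list[Path], error: str | None = None) -> None:
        manifest["stages"][stage] = {
            "artifacts": [str(p.relative_to(out)) for p in paths],
            "error": error,
        }
        for p in paths:
            manifest["artifacts"].append(
                {"path": str(p.relative_to(out)), "sha256": _sha256(p)}
            )

    geometry = config.geometry
    layout = config.scene
    sample_times = sorted(float(t) for t in config.sample_times_s)
    pitch_med = geometry.axial_pixel_pitch_um / geometry.group_index

    # --- model trajectory defining the ground-truth deformation -----------
    trajectory = None
    try:
        t_end = sample_times[-1] + geometry.measurement_window_s() + 1.0
        dense = np.union1d(
            np.linspace(0.0, t_end, 41),
            np.concatenate([[t, t + geometry.measurement_window_s()] for t in sample_times]),
        )
        trajectory = simulate(config.model, t_end, sample_times=dense)
        traj_path = out / "model_trajectory.csv"
        write_table(
            traj_path,
            pd.DataFrame(
                {
                    "time_s": trajectory.times,
                    "thickness_um": trajectory.thickness_um,
                }
            ),
        )
        record("model_simulate", [traj_path])
    except Exception as exc:  # noqa: BLE001 - failures go to the manifest
        record("model_simulate", [], error=f"{type(exc).__name__}: {exc}")

    # --- render phantom stacks at the sampling times ----------------------
    stacks, scenes = [], []
    if "simulate" in config.stages and trajectory is not None:
        try:
            paths = []
            anterior_depth_um = layout.anterior_row * pitch_med
            fieldtruth = make_deformation_field(
                "model_trajectory",
                trajectory=trajectory,
                anterior_depth_um=anterior_depth_um,
            )
            for k, t in enumerate(sample_times):
                thick_px = trajectory.thickness_at(t) * 1e4 / pitch_med
                layout_t = dataclasses.replace(
                    layout, posterior_row=layout.anterior_row + thick_px
                )
                scene = make_corneal_scene(
                    geometry, layout_t, snr=config.snr, seed=int(seeds[k])
                )
                stack = render_frame_stack(
                    scene, fieldtruth, geometry, seed=int(seeds[k + 8]), t_start=t
                )
                scenes.append(scene)
                stacks.append(stack)
                stack_path = out / f"stack_{k:02d}.h5"
                write_stack(
                    stack_path,
                    stack,
                    truth={
                        "anterior_rows": scene.anterior_rows,
                        "posterior_rows": scene.posterior_rows,
                    },
                )
                preview = out / f"stack_{k:02d}_amplitude.tif"
                write_amplitude_preview(preview, stack)
                paths += [stack_path, preview]
            record("simulate", paths)
        except Exception as exc:  # noqa: BLE001
            record("simulate", [], error=f"{type(exc).__name__}: {exc}")
            stacks = []

    # --- segmentation ------------------------------------------------------
    interfaces_by_time = {}
    if "segment" in config.stages and stacks:
        try:
            paths = []
            for k, stack in enumerate(stacks):
                interfaces = segment_cornea(stack.amplitude(0), config.segmentation)
                interfaces_by_time[sample_times[k]] = interfaces
                frame = pd.DataFrame(
                    {
                        "column": np.arange(interfaces.n_cols),
                        "anterior_row": interfaces.anterior.rows,
                        "posterior_row": interfaces.posterior.rows,
                    }
                )
                p = out / f"interfaces_{k:02d}.csv"
                write_table(p, frame)
                paths.append(p)
            record("segment", paths)
        except Exception as exc:  # noqa: BLE001
            record("segment", [], error=f"{type(exc).__name__}: {exc}")

    # --- thickness series ---------------------------------------------------
    if "thickness" in config.stages and stacks:
        try:
            series = thickness_series(stacks, config.segmentation)
            p = out / "thickness_series.csv"
            write_table(p, series.to_frame())
            record("thickness", [p])
        except Exception as exc:  # noqa: BLE001
            record("thickness", [], error=f"{type(exc).__name__}: {exc}")

    # --- DVI and axial profiles --------------------------------------------
    measured_profiles, measured_thickness = [], []
    if "dvi" in config.stages and interfaces_by_time:
        try:
            paths = []
            for k, stack in enumerate(stacks):
                t = sample_times[k]
                if t not in interfaces_by_time:
                    continue
                interfaces = interfaces_by_time[t]
                dvi_img = compute_dvi(stack, interfaces, config.dvi)
                profile = axial_profile(dvi_img, interfaces, "posterior")
                measured_profiles.append((t, profile))
                measured_thickness.append(
                    float(np.mean(thickness_per_column(interfaces, geometry)))
                )
                img_path = out / f"dvi_{k:02d}.tif"
                write_image(img_path, dvi_img.velocity)
                png_path = out / f"dvi_{k:02d}.png"
                write_image(png_path, dvi_img.velocity)
                prof_path = out / f"profile_{k:02d}.csv"
                write_table(
                    prof_path,
                    pd.DataFrame(
                        {
                            "distance_um": profile.distance_um,
                            "mean_velocity_nm_s": profile.velocity_nm_s,
                            "n_columns": profile.n_columns,
                        }
                    ),
                )
                paths += [img_path, png_path, prof_path]
            record("dvi", paths)
        except Exception as exc:  # noqa: BLE001
            record("dvi", [], error=f"{type(exc).__name__}: {exc}")

    # --- model fit to the measured profiles ---------------------------------
    if "model_fit" in config.stages and len(measured_profiles) >= 3:
        try:
            fit = fit_to_dvi(
                measured_profiles,
                measured_thickness,
                template=config.model,
                bounds=config.fit_bounds or None,
                grid_points=config.fit_grid_points,
                maxiter=config.fit_maxiter,
            )
            frame = pd.DataFrame(
                {
                    "parameter": ["k_over_mu", "L_endo", "H0", "H_eq", "objective"],
                    "value": [
                        fit.params.k_over_mu,
                        fit.params.L_endo,
                        fit.params.H0,
                        fit.params.H_eq,
                        fit.objective,
                    ],
                }
            )
            p = out / "model_fit.csv"
            write_table(p, frame)
            record("model_fit", [p])
        except Exception as exc:  # noqa: BLE001
            record("model_fit", [], error=f"{type(exc).__name__}: {exc}")
    elif "model_fit" in config.stages:
        record("model_fit", [], error="fewer than three measured profiles available")

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
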