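"""DVI core: unwrapping, phase-rate regression, recovery and noise floors."""

import numpy as np
import pytest

import dvioct as dv
from dvioct.dvi import (
    noise_floor,
    phase_rate,
    select_reference_pixel,
    temporal_unwrap,
    velocity_from_phase_rate,
)
from dvioct.segmentation import CornealInterfaces, InterfacePath

from conftest import relative_truth


def brute_force_unwrap(series):
    """Oracle: pick the 2-pi shift minimising each consecutive jump."""
    out = [series[0]]
    for x in series[1:]:
        candidates = x + 2 * np.pi * np.arange(-5, 6)
        out.append(candidates[np.argmin(np.abs(candidates - out[-1]))])
    return np.array(out)


class TestPrimitives:
    def test_reference_pixel_in_window_max(self):
        col = np.zeros(100)
        col[52] = 5.0
        assert select_reference_pixel(col, set_row=50) == 52

    def test_reference_pixel_tie_takes_smaller_row(self):
        col = np.zeros(100)
        col[48] = col[53] = 5.0
        assert select_reference_pixel(col, set_row=50) == 48

    def test_reference_pixel_ignores_out_of_window_max(self):
        col = np.zeros(100)
        col[55] = 3.0
        col[80] = 9.0  # global max, outside the +-10 window of row 50
        assert select_reference_pixel(col, set_row=50) == 55

    def test_reference_pixel_empty_window_rejected(self):
        with pytest.raises(ValueError):
            select_reference_pixel(np.zeros(5), set_row=40, halfwidth=2)

    @pytest.mark.parametrize(
        "series",
        [
            [0.0, 2.5, -1.3],
            [1.0, 1.0, 1.0],
            list(np.angle(np.exp(1j * 0.4 * np.arange(12)))),
        ],
    )
    def test_temporal_unwrap_matches_oracle(self, series):
        got = temporal_unwrap(np.asarray(series))
        want = brute_force_unwrap(series)
        assert np.allclose(got, want, atol=1e-12)
        # each consecutive jump lies in (-pi, pi]
        assert np.all(np.abs(np.diff(got)) <= np.pi + 1e-12)

    def test_unwrap_recovers_ramp(self):
        t = np.arange(10)
        truth = 0.4 * t
        wrapped = np.angle(np.exp(1j * truth))
        assert np.allclose(temporal_unwrap(wrapped), truth, atol=1e-12)

    def test_phase_rate_exact_line(self):
        t = np.array([0.0, 0.5, 1.0, 1.5])
        assert phase_rate(t.copy(), t) == pytest.approx(1.0)

    def test_phase_rate_symmetric_noise_invariant(self):
        t = np.arange(8.0)
        line = 0.7 * t + 2.0
        eps = np.array([1, -2, 3, 4, 4, 3, -2, 1]) * 0.3
        # noise symmetric about the window midpoint is orthogonal to the
        # centred time axis, so the OLS slope is unchanged
        assert phase_rate(line + eps, t) == pytest.approx(
            phase_rate(line, t), abs=1e-12
        )

    def test_phase_rate_matches_closed_form(self):
        rng = np.random.default_rng(0)
        t = np.sort(rng.random(12)) * 5
        y = rng.random(12)
        want = np.sum((t - t.mean()) * (y - y.mean())) / np.sum((t - t.mean()) ** 2)
        assert phase_rate(y, t) == pytest.approx(want, abs=1e-12)

    def test_phase_rate_rejects_constant_time(self):
        with pytest.raises(ValueError):
            phase_rate(np.zeros(3), np.zeros(3))

    def test_velocity_conversion(self):
        assert velocity_from_phase_rate(0.0, 800.0, 1.37) == 0.0
        want = 800.0 / (4 * 1.37)  # pi rad/s
        assert velocity_from_phase_rate(np.pi, 800.0, 1.37) == pytest.approx(
            want
        ) and want == pytest.approx(145.985, abs=1e-3)
        v1 = velocity_from_phase_rate(2.0, 800.0, 1.0)
        v2 = velocity_from_phase_rate(2.0, 800.0, 2.0)
        assert v1 == pytest.approx(2 * v2)

    @pytest.mark.parametrize(
        "wavelength,n,rate,want",
        [(800.0, 1.37, 2.0, 291.97), (800.0, 1.0, 2.0, 400.0), (1300.0, 1.37, 10.0, 2372.26)],
    )
    def test_nyquist_velocity(self, wavelength, n, rate, want):
        g = dv.AcquisitionGeometry(
            centre_wavelength_nm=wavelength, group_index=n, frame_rate_hz=rate
        )
        assert dv.nyquist_velocity(g) == pytest.approx(want, abs=0.1)


def _compute(scene, fieldtruth, geometry, seed=0, variant="with_epithelium", smooth=True):
    stack = dv.render_frame_stack(scene, fieldtruth, geometry, seed=seed)
    interfaces = dv.segment_cornea(
        stack.amplitude(0), dv.SegmentationConfig(scene_variant=variant)
    )
    image = dv.compute_dvi(
        stack, interfaces, dv.DVIConfig(scene_variant=variant, smooth=smooth)
    )
    return stack, interfaces, image


class TestComputeDVI:
    def test_rigid_bulk_removed(self, geometry, noiseless_scene):
        field = dv.make_deformation_field("rigid", bulk_velocity_nm_s=100.0)
        _, _, image = _compute(noiseless_scene, field, geometry)
        assert np.nanmax(np.abs(image.velocity_raw)) < 1e-6

    def test_uniform_strain_slope_recovered(self, geometry, noiseless_scene, pitch_med):
        s = -2e-4
        field = dv.make_deformation_field("uniform_strain", strain_rate=s, z_ref_um=0.0)
        _, interfaces, image = _compute(noiseless_scene, field, geometry)
        # axial regression of v_r against geometric depth recovers the strain rate
        rows, cols = np.nonzero(image.mask & noiseless_scene.stroma_mask(1))
        v = image.velocity_raw[rows, cols] * 1e-3  # um/s
        z = rows * pitch_med
        slope = np.polyfit(z, v, 1)[0]
        assert slope == pytest.approx(s, rel=0.01)
        # zero velocity at each reference pixel
        ref_v = image.velocity_raw[image.reference_rows, np.arange(image.mask.shape[1])]
        assert np.nanmax(np.abs(ref_v)) < 1e-9

    def test_bulk_motion_immunity(self, geometry, noiseless_scene):
        base = dv.make_deformation_field(
            "uniform_strain", strain_rate=-2e-4, z_ref_um=0.0
        )
        with_bulk = dv.make_deformation_field(
            "uniform_strain", strain_rate=-2e-4, z_ref_um=0.0, bulk_velocity_nm_s=200.0
        )
        _, _, a = _compute(noiseless_scene, base, geometry)
        _, _, b = _compute(noiseless_scene, with_bulk, geometry)
        diff = np.abs(a.velocity_raw - b.velocity_raw)
        assert np.nanmax(diff) < 1e-6

    def test_smoothing_reduces_error_at_noise(self, geometry, pitch_med):
        scene = dv.make_corneal_scene(geometry, dv.SceneLayout(), snr=20.0, seed=8)
        field = dv.make_deformation_field(
            "exponential_front",
            boundary_velocity_nm_s=-200.0,
            decay_length_um=120.0,
            boundary_depth_um=float(np.median(scene.posterior_rows)) * pitch_med,
        )
        _, _, image = _compute(scene, field, geometry, seed=9)
        rel = relative_truth(scene, field, geometry, image)
        sel = image.mask & scene.stroma_mask(2)
        rms_raw = np.sqrt(np.nanmean((image.velocity_raw - rel)[sel] ** 2))
        rms_smooth = np.sqrt(np.nanmean((image.velocity_smoothed - rel)[sel] ** 2))
        assert rms_smooth < rms_raw

    def test_aliased_phase_steps_indistinguishable(self, geometry):
        """A per-frame step of dphi and dphi + 2 pi give identical output."""
        H, W, n = 40, 8, 10
        t = geometry.timestamps(n)
        rng = np.random.default_rng(2)
        base = rng.normal(size=(H, W)) + 1j * rng.normal(size=(H, W))
        base[20] = 10.0  # bright reference line
        interfaces = CornealInterfaces(
            anterior=InterfacePath(np.full(W, 5)),
            posterior=InterfacePath(np.full(W, 35)),
            auxiliary={"epithelial": InterfacePath(np.full(W, 20))},
        )
        images = []
        for dphi in (0.8, 0.8 + 2 * np.pi):
            ramp = np.zeros((n, H, W))
            ramp[:, 30, :] = dphi * np.arange(n)[:, None]
            stack = dv.ComplexFrameStack(
                base[None] * np.exp(1j * ramp), t, geometry
            )
            images.append(dv.compute_dvi(stack, interfaces, dv.DVIConfig()))
        assert np.allclose(
            images[0].velocity_raw, images[1].velocity_raw, atol=1e-9, equal_nan=True
        )


class TestAxialProfile:
    def test_constant_image_constant_profile(self, geometry, noiseless_scene):
        field = dv.make_deformation_field("static")
        _, interfaces, image = _compute(noiseless_scene, field, geometry)
        image.velocity_raw[image.mask] = 3.14
        profile = dv.axial_profile(image, interfaces, "posterior")
        valid = np.isfinite(profile.velocity_nm_s)
        assert np.allclose(profile.velocity_nm_s[valid], 3.14)
        # length covers the thickest column, one bin per pixel distance
        max_thick = int(
            (interfaces.posterior.rows - interfaces.anterior.rows).max()
        )
        assert len(profile) == max_thick + 1

    def test_uniform_strain_profile_slope(self, geometry, noiseless_scene, pitch_med):
        s = -2e-4
        field = dv.make_deformation_field("uniform_strain", strain_rate=s, z_ref_um=0.0)
        _, interfaces, image = _compute(noiseless_scene, field, geometry)
        profile = dv.axial_profile(image, interfaces, "posterior")
        ok = np.isfinite(profile.velocity_nm_s) & (profile.n_columns > 100)
        # moving away from the posterior face means decreasing depth, so the
        # profile slope is -s (in um/s per um)
        slope = np.polyfit(
            profile.distance_um[ok], profile.velocity_nm_s[ok] * 1e-3, 1
        )[0]
        assert slope == pytest.approx(-s, rel=0.01)


class TestNoiseFloor:
    def test_noiseless_floor_is_negligible(self, geometry, noiseless_scene):
        field = dv.make_deformation_field("static")
        _, interfaces, image = _compute(noiseless_scene, field, geometry)
        assert noise_floor(image, "raw") < 1e-9
        assert noise_floor(image, "smoothed") < 1e-9
        assert noise_floor(image, "axial_averaged", interfaces=interfaces) < 1e-9

    def test_floor_hierarchy_and_scaling(self, geometry):
        """Raw > smoothed > axially averaged, and ~1/sqrt(N) with averaging."""
        scene = dv.make_corneal_scene(geometry, dv.SceneLayout(), snr=10.0, seed=21)
        field = dv.make_deformation_field("static")
        _, interfaces, image = _compute(scene, field, geometry, seed=22)
        raw = noise_floor(image, "raw")
        smoothed = noise_floor(image, "smoothed")
        averaged = noise_floor(image, "axial_averaged", interfaces=interfaces)
        assert raw > smoothed > averaged
        # averaging N pixels from distinct columns scales the floor as N^-0.5
        rng = np.random.default_rng(5)
        rows = interfaces.anterior.rows + 40
        vals = image.velocity_raw[rows, np.arange(image.mask.shape[1])]
        sds = []
        sizes = [2, 8, 32]
        for N in sizes:
            means = [
                vals[rng.choice(len(vals), size=N, replace=False)].mean()
                for _ in range(400)
            ]
            sds.append(np.std(means))
        slope = np.polyfit(np.log(sizes), np.log(sds), 1)[0]
        assert slope == pytest.approx(-0.5, abs=0.12)

    def test_small_region_rejected(self, geometry, default_scene):
        field = dv.make_deformation_field("static")
        _, interfaces, image = _compute(default_scene, field, geometry)
        region = np.zeros_like(image.mask)
        region[:, :1] = True
        with pytest.raises(ValueError, match="region too small"):
            noise_floor(image, "raw", region=region & image.mask, min_pixels=10**6)
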