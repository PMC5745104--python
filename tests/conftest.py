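"""Shared fixtures: geometry, phantom scenes and rendered stacks.

Heavy artefacts are session-scoped so the suite renders each scene once.
"""

from __future__ import annotations

import numpy as np
import pytest

import dvioct as dv


@pytest.fixture(scope="session")
def geometry() -> dv.AcquisitionGeometry:
    """The default instrument: 800 nm, n_g = 1.37, 2 Hz, 10 frames."""
    return dv.AcquisitionGeometry()


@pytest.fixture(scope="session")
def pitch_med(geometry) -> float:
    return geometry.axial_pitch_medium_um


@pytest.fixture(scope="session")
def default_scene(geometry) -> dv.ScenePhantom:
    return dv.make_corneal_scene(geometry, dv.SceneLayout(), snr=20.0, seed=11)


@pytest.fixture(scope="session")
def noiseless_scene(geometry) -> dv.ScenePhantom:
    return dv.make_corneal_scene(geometry, dv.SceneLayout(), snr=np.inf, seed=11)


def segment_scene(scene, variant="with_epithelium"):
    """Segment a phantom scene's mean amplitude image."""
    return dv.segment_cornea(
        scene.mean_amplitude, dv.SegmentationConfig(scene_variant=variant)
    )


def relative_truth(scene, fieldtruth, geometry, dvi_image, t_start=0.0):
    """Ground-truth velocity image relative to the DVI reference rows."""
    truth = dv.true_velocity_image(scene, fieldtruth, geometry, t_start=t_start)
    cols = np.arange(truth.shape[1])
    return truth - truth[dvi_image.reference_rows, cols][None, :]
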