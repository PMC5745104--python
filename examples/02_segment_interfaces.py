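"""Graph-search segmentation of the corneal interfaces in a phantom B-scan.

Renders a noisy scene, runs the iterative minimum-energy path search and
compares the recovered anterior/posterior paths with the scene truth.
"""

import numpy as np

import dvioct as dv

geometry = dv.AcquisitionGeometry()
scene = dv.make_corneal_scene(
    geometry, dv.SceneLayout(curvature_px=7.0), snr=10.0, seed=4
)
stack = dv.render_frame_stack(
    scene, dv.make_deformation_field("static"), geometry, seed=5, n_frames=2
)

interfaces = dv.segment_cornea(stack.amplitude(0), dv.SegmentationConfig())

for name, path, truth in [
    ("anterior", interfaces.anterior.rows, scene.anterior_rows),
    ("posterior", interfaces.posterior.rows, scene.posterior_rows),
]:
    err = np.abs(path - truth)
    print(f"{name:9s}: mean |error| {err.mean():.2f} px, max {err.max():.2f} px")
print("Sub-pixel mean error means the thickness measurement inherits less")
print("than one axial pixel (~3.6 um in tissue) of segmentation bias.")
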