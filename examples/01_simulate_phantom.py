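"""Render a synthetic corneal B-scan stack with known deformation truth.

Builds the vial-plus-cornea scene, applies an exponential de-swelling front
at the endothelial (posterior) interface and renders ten complex frames at
2 Hz, then prints the phase step the motion imprints on the Fourier phase.
"""

import numpy as np

import dvioct as dv

geometry = dv.AcquisitionGeometry()  # 800 nm, n_g 1.37, 2 Hz, 10 frames
layout = dv.SceneLayout()
scene = dv.make_corneal_scene(geometry, layout, snr=20.0, seed=1)

pm = geometry.axial_pitch_medium_um
field = dv.make_deformation_field(
    "exponential_front",
    boundary_velocity_nm_s=-250.0,  # posterior face moves up at 250 nm/s
    decay_length_um=120.0,
    boundary_depth_um=layout.posterior_row * pm,
)
stack = dv.render_frame_stack(scene, field, geometry, seed=2)

step = np.angle(stack.frames[1] * np.conj(stack.frames[0]))
post = int(layout.posterior_row)
print(f"stack: {stack.n_frames} frames of {stack.shape} over "
      f"{geometry.measurement_window_s():.0f} s")
print(f"phase step near the endothelium: {np.median(step[post, :]):+.3f} rad/frame")
print(f"phase step near the epithelium:  {np.median(step[int(layout.anterior_row)+6, :]):+.3f} rad/frame")
print("The de-swelling front advances the Fourier phase fastest at the")
print("posterior face; 250 nm/s at 2 Hz corresponds to about -2.7 rad/frame.")
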