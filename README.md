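# dvioct — deformation velocity imaging for Fourier-domain OCT

`dvioct` images nanometre-per-second relative axial velocities inside a
deforming semi-solid sample from the Fourier phase of repeated complex OCT
B-scans. Its target application is the osmotic de-swelling of donor human
corneas stored for transplantation: a cornea suspended in a vial of
hypertonic (dextran) solution thins over hours, and the motion of every
point inside the stroma — not just the resulting thickness — reveals where
the water leaves and how well the cellular barrier layers (epithelium,
endothelium) function. The package is written for researchers in OCT
methods development, corneal biophysics and eye banking who want a fully
testable, synthetic-data-driven implementation of the method.

## What it computes

**Deformation velocity imaging (DVI).** In Fourier-domain OCT each pixel is
complex, `I'_P = A_P (a_P + b_P i)`, and its phase `φ_P = tan⁻¹(b_P/a_P)`
advances by `4π n Δz / λ` when the scatterers in it move axially by `Δz`.
The relative axial velocity of pixel *P* against a per-A-scan reference
pixel *RP* is

```
v_r = d(φ_P − φ_RP)/dτ · λ / (4π n)
```

with the phase rate estimated by least squares over ten frames (5 s at
2 Hz) after temporal unwrapping. Subtracting the reference phase cancels
bulk motion of the suspended sample; the reference (the strongest signal
within ±10 px of a set point — the epithelial interface, or mid-depth for
epithelium-free corneas) anchors zero velocity. Velocities are valid up to
the Nyquist cap `v_max = λ f / (4n)` ≈ 292 nm/s for 800 nm / 1.37 / 2 Hz.

**Graph-search segmentation.** Corneal and container interfaces are
minimum-energy left-to-right paths through an inverted-amplitude or
inverted-vertical-gradient cost map (median + boxcar smoothed), found by
dynamic programming with a per-column step bound and iterated with
previously found paths blocked. Thickness is the anterior-posterior
separation divided by a constant group index of 1.37.

**1-D osmotic de-swelling model.** The stroma is `N` elements of equal dry
thickness carrying hydration `H = M_W/M_D`; water moves between elements by
Darcy flow (`k/μ`, driven by the swelling-pressure gradient, default law
`Π = C·H⁻²` with `C = 2.41×10⁶ dyne/cm²`) and exits across the endothelial
membrane with conductivity `L` into a bath at osmotic pressure `Π(H_eq)`.
The model predicts thickness-vs-time and velocity-vs-depth profiles, and
its constants can be fitted to measured DVI profiles at three or more
times (coarse grid search + simplex refinement).

**Synthetic phantoms.** No raw recordings of this kind are publicly
deposited, so a phantom generator renders complex B-scan stacks of the
vial-plus-cornea scene — Rayleigh speckle stroma, specular interface
lines, additive complex Gaussian noise — whose per-pixel phase evolves
exactly as `4π n z(t)/λ` under a prescribed deformation field (rigid,
uniform strain, exponential de-swelling front, or a model trajectory).
Every stage of the pipeline is validated against this exact ground truth.

## Worked example

```bash
python examples/03_deformation_velocity_image.py
```

prints

```
velocity at the endothelial face:   -109.4 nm/s
velocity near the epithelium:          0.1 nm/s
axial slope of the profile:       -2.00e-04 1/s  (truth -2.0e-04)
Nyquist cap of this instrument:      292.0 nm/s
```

A phantom shrinking at a uniform strain rate of −2×10⁻⁴ s⁻¹ was rendered
at SNR 20, segmented, and processed by DVI. The endothelial face, ~750 µm
from the anterior reference, moves at ~109 nm/s toward it; the axial slope
of the column-averaged velocity profile recovers the strain rate to three
significant figures; all velocities sit safely below the 292 nm/s aliasing
cap. The other examples cover phantom rendering (`01`), segmentation
accuracy (`02`), the automated thickness series (`04`) and model-constant
recovery from velocity profiles (`05`).

A thin CLI wraps the same library calls:

```bash
dvi-oct simulate --kind exponential_front --snr 20 --seed 1 --out stack.h5
dvi-oct segment stack.h5 --out interfaces.csv
dvi-oct dvi stack.h5 --out dvi_result
dvi-oct run --seed 1 --out run_dir          # full closed-loop pipeline
```

Stacks are HDF5 (`/real`, `/imag`, `/timestamps` + geometry attributes),
images float TIFF/PNG, tables CSV; `dvi-oct run` writes a manifest with
SHA-256 checksums and is byte-reproducible for a fixed seed.

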