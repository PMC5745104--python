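# Methods

## Phase model and the DVI estimator

A Fourier-domain OCT pixel is a complex number whose argument (the Fourier
phase) shifts by `4π n_g Δz / λ` when the scatterers inside it move
axially by a geometric distance `Δz` in a medium of group index `n_g`. The
pixels of a corneal stroma contain many scatterers, but during slow
osmotic deformation they move approximately in unison, so each pixel
behaves as a single phase source. The DVI estimator proceeds per A-scan:

1. choose a reference pixel — the strongest amplitude within ±10 px of a
   set point (the epithelial interface when present, otherwise the depth
   midway between anterior and posterior surfaces, which keeps both faces
   within the aliasing-free range) — and subtract its phase from the whole
   A-scan in every frame, removing rigid bulk motion of the suspended
   sample;
2. subtract each pixel's first-frame phase;
3. unwrap the resulting phase change over the frames (consecutive
   differences forced into (−π, π]);
4. fit an ordinary-least-squares slope against the frame timestamps and
   convert with `v_r = (dφ/dτ)·λ/(4πn)`.

Steps 1–2 are computed in the complex domain (`I_P · conj(I_RP)`, then
`· conj(first frame)`), which is identical to wrapped phase subtraction
but avoids intermediate wrapping artefacts. The estimator is exact, to
floating precision, for any motion whose velocity is constant over the
measurement window, and unbiased for slowly varying motion (the OLS slope
is then the window-average velocity).

Assumptions and limits: per-interval phase steps of `Δφ` and `Δφ + 2π`
are indistinguishable, so velocities alias beyond
`v_max = λf/(4n)` (≈292 nm/s at 800 nm, n = 1.37, 2 Hz); a warning is
issued when estimates approach the cap. Spatial unwrapping from the
reference pixel, a conceivable anti-aliasing extension, is out of scope.
Only axial motion is modelled or measured.

## Graph-search segmentation

Interfaces are extracted as left-to-right paths of minimum summed energy.
Two energy maps are used: inverted amplitude (`max − A`, for bright
specular lines) and inverted vertical-gradient magnitude
(`max − |∂A/∂row|`, for amplitude steps), each computed on a
median-filtered image and then boxcar-smoothed. The minimum-energy path
under a per-column step bound is found by dynamic programming over suffix
costs; on cost ties the lexicographically smallest row sequence from the
leftmost column is returned, making results fully deterministic. Further
interfaces are found by blocking all pixels within a vertical halfwidth of
prior paths and re-running the search.

The corneal pipeline: restrict to a configured row range; find and block
the two container-wall lines with the amplitude energy; take the next
amplitude path (scattering epithelium) or a gradient path (bare anterior
surface) as an approximate corneal profile; circularly shift each column
to flatten that profile and crop to configured margins; run the final
gradient-energy search twice (with blocking) for the anterior and
posterior surfaces; map back through the recorded shifts. A result is
rejected — with a segmentation error rather than a wrong answer — when the
surfaces are out of order, implausibly close, or the enclosed region shows
no amplitude contrast against the background above it (the guard that
catches scenes with no cornea at all).

Defaults (all overridable per scene): median 3×3, boxcar 5×5, blocking
halfwidth 10 px, step bound 1 px/column, final-search margins 180 px above
/ 360 px below the approximate profile. The step bound of 1 suits smooth
corneal curvature at these pixel pitches; steeper scenes need a larger
bound. Interactive review of false paths is replaced by an optional
user-supplied blocked-pixel mask in the configuration.

## Thickness

Per column, geometric thickness is the anterior–posterior row separation
times the axial pixel pitch in air divided by a constant group index of
1.37; hydration dependence of the index is deliberately ignored. A series
over many stacks averages a central fraction of columns (default 80%, to
avoid edge artefacts), supports irregular sampling intervals, sorts by
acquisition time, and records per-time-point segmentation failures as gaps
instead of aborting.

## Synthetic phantoms

The generator emulates the experimental scene at the complex-B-scan level;
spectral-interferogram formation is upstream of everything the method uses
and is not modelled. A scene comprises: two bright container-wall lines;
a stroma of circular-complex-Gaussian speckle (Rayleigh amplitude)
between smooth curved anterior/posterior truth paths; a bright epithelial
line on the anterior path, or, for epithelium-free scenes, a weaker
specular anterior-surface reflection; and a specular endothelial line
centred on the posterior path. The two specular corneal lines reflect what
real corneal B-scans show at these interfaces and give the
gradient-energy search a symmetric, unbiased edge; without them a pure
speckle-to-background step localises with a systematic ~1.5 px offset
under any median/boxcar combination.

Frames evolve only in phase: per-pixel displacement is the trapezoidal
time-integral of the prescribed velocity field (exact for fields constant
over the window) plus bulk motion, converted at `4π n_g/λ` rad per nm.
Amplitude is held fixed — over ten frames the displacement is hundreds of
nm against a ~12 µm pixel, so speckle decorrelation is negligible.
Independent complex Gaussian noise is added per pixel per frame; the scene
SNR is the ratio of per-quadrature speckle sigma to noise sigma. The
instrument SNR of the original experiments is not known, so noise-floor
behaviour is characterised as a function of SNR (the hierarchy raw >
smoothed > axially averaged and the ~N^−1/2 averaging law) rather than at
one calibrated value; at SNR ≈ 5 the three floors are ≈9 / 1.8 / 0.7 nm/s.

What the phantoms do not emulate: lateral motion, amplitude decorrelation,
dispersion artefacts from the vial wall, polarization effects, and folded
interface overlays. Passing tests therefore demonstrate correctness of
the phase math, segmentation and bookkeeping under realistic speckle and
noise, not robustness to those instrument artefacts.

Deformation-field kinds: `rigid` (bulk only), `uniform_strain`
(`v = s·(z − z_ref)`), `exponential_front` (a de-swelling front decaying
from the posterior boundary), `model_trajectory` (velocities interpolated
from a de-swelling simulation), `static`. Ground truth for comparisons is
the OLS slope of the true displacement samples over the same window — the
exact quantity a phase-rate estimator observes — computed directly from
the field, never through the phase pipeline.

## De-swelling model

One-dimensional, CGS units internally. `N` elements (default 50) of equal
dry thickness `D_dry/N` (default `D_dry` = 0.0116 cm, giving a ~1 mm
swollen cornea at H₀ = 7.6) carry hydration `H`; wet thickness is
`(D_dry/N)(1+H)` with unit densities. Element fluid pressure is `−Π(H)`;
internal Darcy flux between neighbours is `(k/μ)·ΔP/Δx` with Δx the
centre-to-centre distance; the posterior boundary flux is
`L·(π_ext − Π(H_N))` outward across the endothelial membrane, with
`π_ext = Π(H_eq)`. The anterior face is sealed by default (osmotic flow
through an intact epithelium is negligible); `membrane` and `open`
variants are provided. Solute transport and hydration-dependent
permeability are deliberately excluded, so only the rapid initial osmotic
phase is in scope — the late re-swelling seen in long experiments is not.

The swelling-pressure law is not uniquely fixed by the available
literature constants, so it is pluggable: the default is
`Π = C·H^(−γ)` with `C = 2.41×10⁶ dyne/cm²` and γ = 2, chosen as the
simplest strictly decreasing positive law through the classical empirical
constant. All conservation, convergence and recovery behaviour is
law-agnostic, and every output records the law used.

Integration is explicit Euler at a fixed step below an estimated
stability bound (`0.4·min(δ·Δx_min/((k/μ)·max|Π'|), δ/(L·max|Π'|))`,
with `max|Π'|` over the run's hydration range); steps shorten to land
exactly on sample times. Fluxes are applied antisymmetrically, so water is
conserved to machine precision per step; the simulation additionally
reports the global balance against the time-integrated boundary fluxes
(≤1e−10 relative in practice). Halving dt or doubling N changes the final
thickness by <1e−9 relative at the defaults. The power-law hot loop is
compiled with numba; a plain-Python path handles custom pressure laws and
is tested for exact agreement with the compiled path. Negative hydration
after a step raises a stability error advising a smaller dt.

Velocity profiles use the anterior face as the zero-velocity reference
(matching the DVI reference for with-epithelium corneas): face positions
are cumulative wet thicknesses and face velocities their central finite
differences between samples. Model-to-measurement comparison interpolates
the model profile linearly onto the measured distance-from-endothelium
grid.

## Fitting model constants to DVI profiles

`fit_to_dvi` recovers `(k/μ, L, H₀, H_eq)` from velocity profiles at ≥3
times plus the mean thickness at those times. The objective is the summed
squared profile misfit (scaled by the measured RMS velocity) plus the
squared thickness misfit (scaled by 1% of the mean thickness). A
deterministic coarse grid inside the bounds (conductivities gridded in
log space, default 3 points per axis) seeds Nelder-Mead refinements from
the three best grid points — the misfit surface has long curved valleys in
which a single simplex start can stall. The model's start-time offset
before the first measurement can optionally be fitted as a nuisance
parameter (default off; the synthetic studies define t = 0 exactly).
Sample times for each candidate simulation bracket every measurement time
by ±2.5 s so the model's central-difference velocity matches the 5 s DVI
window average.

Identifiability: profiles during early de-swelling are dominated by the
membrane flux, so `L`, `H₀` and `H_eq` are well constrained while the
stromal `k/μ` is weaker; at 5% profile noise single-replicate `k/μ`
errors of ~20% occur even at the exact optimum of the noisy objective,
while the replicate median stays well inside 15%. Monte-Carlo statements
about noisy recovery therefore use the replicate median.

## Problem sizes and defaults used in the shipped studies

Phantom scenes are 360×160 px (480 rows for fully swollen corneas) at
5 µm/px axial pitch in air, SNR 5–50, ten frames at 2 Hz; model runs use
N = 50 (N = 10–16 inside fitting loops and closed-loop studies, where the
same discretisation is used on both sides of the comparison); fits use a
3⁴ grid plus ≤2000 simplex iterations. These sizes make the full test
suite and the acceptance script run on a single CPU in a few minutes
while leaving every headline quantity far from its tolerance.
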