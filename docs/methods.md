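# Methods

`slotsim` simulates and quantifies time-resolved live/dead monitoring of a
cell-colonized cylindrical implant imaged by rotational optical projection
tomography (SLOT-style). This note records the models, the parameter
choices, the numerical decisions, and what the synthetic data can and
cannot say about real measurements.

## Phantom model

The implant is a solid cylinder (default Ø 3 mm × 30 mm, titanium in the
physical system) standing on the central vertical axis of the voxel grid,
embedded in an optically clear hydrogel inside a wider sample tube.
Cells adhere only to the lateral cylinder surface; their number is Poisson
with mean `density · 2πrL` and their positions are uniform in axial
position `z` (0 at the implant top, increasing downward) and azimuth.
Cell morphology, migration and proliferation are not modeled: a cell is a
point emitter fixed for the whole experiment.

Two fluorescence channels are rendered on the voxel grid (voxel centers at
`(i + 0.5)·pitch`):

* **live** — every cell deposits `I_live` into its voxel; imaged once at
  the start of the experiment.
* **dead** — a membrane-compromised cell deposits
  `I_dead · b^(number of dead-channel exposures since compromise)`.
  `b ∈ (0, 1]` is the per-exposure photobleaching retention factor;
  exposure counters increment *after* each rendering, so a newly
  compromised cell appears at full intensity and fades on subsequent
  exposures. This reproduces the characteristic drop in dead-stain signal
  above the advancing front: older signal has been excited more often.

### Toxicant and death kinetics

A cytotoxic bolus (chlorhexidine in the physical system, source
concentration `C0 = 400 µM`) is applied at the implant top at `t = 0`.
Three front modes are available:

* `constant_velocity` (default): concentration is `C0` behind a sharp
  front at depth `v·t` and zero below it. This is the default because the
  measured front in this kind of experiment is linear in time, which pure
  constant-source diffusion does not produce; the mode is a kinematic
  description of the observed behavior, not a transport model.
* `diffusion`: one-dimensional diffusion into a semi-infinite medium with
  a constant source at `z = 0`, `C(z,t) = C0·erfc(z / (2√(Dt)))`. The
  threshold crossing of an erfc profile advances as `√t` (decelerating),
  so this mode is provided for exploration of the transport-limited
  regime. How a diffusing antiseptic produces a constant-velocity death
  front physically (advection, reaction kinetics, threshold sharpening)
  is an open question the package does not resolve.
* `homogeneous_control`: no toxicant; every live cell dies with
  probability `p_control` per imaging interval, uniformly over the
  implant — the toxicant-free control in which death accrues without
  spatial structure.

Death is a sharp threshold: a live cell is compromised at the first
imaging time at which its local concentration reaches `θ` (default
72 µM, a concentration at which most fibroblasts die within hours in 2D
dose-response experiments). The transition is absorbing. A staining lag
between membrane compromise and dead-stain visibility is not modeled
(none is reported for the dyes in question).

### Parameter defaults

| parameter | default | unit | rationale |
|---|---|---|---|
| implant radius / length | 1.5 / 30 | mm | the physical implant model |
| tube radius | 7.5 | mm | glass sample tube |
| voxel pitch | 0.078 | mm | desk-scale grid (below) |
| grid | 96×96×384 | voxels | desk-scale grid (below) |
| cell surface density | 150 | cells/mm² | sub-confluent fibroblast monolayer (~4×10⁴ cells on the implant) |
| time points | 0, 7, …, 63 | h | the imaging cadence of the experiment emulated |
| front velocity | 0.2 | mm/h | the measured front speed in the emulated experiment |
| C0 | 400 | µM | applied chlorhexidine concentration |
| D | 0.36 | mm²/h | ≈10⁻⁶ cm²/s, a small molecule in a hydrogel |
| θ | 72 | µM | lowest 2D dose with high short-term kill |
| bleach factor b | 0.9 | per exposure | visible but not dominating fade over 10 exposures (0.9⁹ ≈ 0.39) |
| p_control | 0.03 | per interval | slow background death without medium exchange |

Randomness derives from a single scenario seed through a fixed
stream-splitting rule: `SeedSequence(seed)` is spawned into three
children used for (0) cell seeding, (1) control-mode death draws,
(2) acquisition noise. Fixed seed ⇒ bit-identical volumes.

### Grid scale

The full-scale instrument geometry (8.5 µm/pixel, 1000×3079 detector,
1200 projections) is available in the configuration but is not the
default. The working default is a desk-scale grid of 96×96×384 voxels at
78 µm pitch with 120 projection angles, which preserves every geometric
ratio of the experiment (implant radius ≈ 19 voxels, axial extent ≈ 384
voxels) while keeping a complete ten-time-point tomographic run in about
a minute. At this pitch the 30 mm implant is 0.048 mm (a sub-voxel
fraction) longer than the grid; cell deposits past the last axial voxel
are folded into the bottom voxel row rather than dropped, so channel
totals are exact.

## Image formation and reconstruction

Projection is parallel-beam emission tomography: for rotation angle φ
(degrees, counter-clockwise, 0° along +x of the transverse slice) a point
at transverse offset (x, y) from the rotation axis maps to detector
coordinate `s = x·cosφ + y·sinφ`, and each detector pixel records the
line integral of emission along its ray (unit sampling step, bilinear
interpolation). There is no attenuation, scattering, refraction at the
tube wall, or depth-dependent point-spread function — the same idealized
geometry that filtered back projection itself presumes. Detector row `h`
sees transverse slice `h`. The projection of a whole volume is evaluated
as one sparse matrix product; the operator is cached per (width, angle
set) and reused across channels and time points. Optional noise: Poisson
shot noise per pixel, optionally plus zero-mean Gaussian readout noise,
clamped at zero. The default is noise-free.

Reconstruction is standard filtered back projection. Each sinogram row is
convolved, via FFT with zero-padding to the next power of two ≥ 2W, with
the classical band-limited ramp kernel (central tap 1/4, odd taps
−1/(πn)², even taps 0; Shepp-Logan variant multiplies the frequency
response by a sinc; "none" is the identity). Backprojection samples each
filtered projection at `s = x·cosφ + y·sinφ` with linear interpolation
and scales the angular sum by `π/(2·n_angles)`; it is implemented as the
cached-sparse-operator adjoint of the forward convention. Values outside
the inscribed reconstruction circle are zeroed, and negative values are
clamped to zero by default (emission is non-negative); clamping is
switchable. On a 128² disc phantom with 180 angles the round trip
FBP(Radon(f)) reconstructs the disc with ≈3.8 % RMSE of its amplitude —
the module's oracle, cross-checked against scikit-image's `iradon`.

## Quantification

For each reconstructed (or ground-truth) volume a side-view maximum
intensity projection is taken along one transverse horizontal axis
(one view; averaging over views is not done). The axial profile is the
mean over the implant-width columns, taken from the known geometry:
center column `floor(W/2)`, half-width `round(radius/pitch)` columns,
half-open interval. An Otsu-threshold fallback ROI is provided for
externally produced volumes where the geometry is unknown. Row `h` maps
to axial position `h·pitch`.

Each channel's profile series is normalized by a **single global maximum
across the whole time series**, not per time point. This matters: the
dead-stain profiles then grow toward the live-stain distribution over
time; per-time-point normalization would erase exactly the trend the
analysis measures.

## Front tracking

The difference spectrum of two succeeding dead-channel profiles
(computed on the normalized series by default; switchable to raw) is the
newly gained intensity per position; negative values are retained because
the photobleaching-driven fade above the front is part of the signature.
Consecutive spectra telescope exactly to (last − first) profile.

Peak localization smooths the spectrum with an 11-sample moving average,
excludes 5 % of positions at each end, and takes the position of the
maximum strictly-positive value, ties breaking toward the smaller (upper)
position. The window and margin suppress single-voxel noise without
displacing a millimetre-scale front (11 samples ≈ 0.86 mm at desk
pitch); both are configuration. If no positive interior value exists the
interval reports "no front" and is dropped from the track (the first
interval of a run can legitimately contain no deaths).

Each retained peak is timestamped with the later time of its interval,
and ordinary least squares of position on time gives the front velocity;
`R² = 1 − SS_res/SS_tot`, defined as 1 for an exact degenerate fit
(all positions equal). A run is classified `directed` when `R² ≥ 0.9`
and slope ≥ 0.02 mm/h, else `non_systematic`. On the default desk-scale
scenario the recovered slope is within ~6 % of the configured 0.2 mm/h
with R² ≈ 0.993; the residual is dominated by band quantization (each
7 h interval paints a 1.4 mm band of new death whose smoothed plateau
the argmax localizes to within a few voxels) and by the edge margin
clipping the first interval's peak, which lies within 5 % of the top.

The toxicant-free control ensemble (classification stability over many
seeds) is evaluated on profiles quantified directly from the ground-truth
emission volumes. The quantification stage accepts externally produced
volumes by design, and the control question — whether randomly placed
gain peaks are ever classified as a directed front — concerns the
profile → difference-spectrum → fit chain, not the imaging model.

## Plate assays

Two standalone normalizations for 2D cytocompatibility screens:
MTT metabolic activity `100·(sample − blank)/(control − blank)` and LDH
cytotoxicity `100·(experimental − low)/(high − low)`, where the low
control is spontaneous release and the high control the fully lysed
culture. Values outside [0, 100] are returned as computed — spontaneous
release below the low control is informative, so nothing is clipped.

## What passing tests do and do not show

The generator produces point-emitter cells on an ideal cylinder in a
noise-free, attenuation-free optical system with perfect rotation
geometry. Passing the pipeline's checks demonstrates that the analysis
chain (projection → FBP → MIP → width-averaged profile → difference
spectrum → peak track → linear fit) is self-consistent and recovers a
known front velocity under those conditions. It does not validate the
optical model against a real instrument (alignment errors, scattering,
depth-dependent blur, autofluorescent background), the biology
(cell-shape signal, detachment, staining kinetics), or transport in a
real hydrogel. The diffusion mode's decelerating front is a reminder
that the constant-velocity default is an empirical, not mechanistic,
description.
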