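# slotsim

Synthetic live/dead monitoring of cell-colonized cylindrical implants by
rotational optical projection tomography (SLOT-style), end to end: phantom
simulation, projection, filtered back projection, and quantification of a
toxicant-driven cell-death front.

## The problem

Dental-implant materials are usually screened on flat 2D samples with
terminal assays, which cannot follow *where* along a cylindrical implant
tissue cells die, or *when*. A 3D alternative embeds a fibroblast-colonized
titanium cylinder (Ø 3 mm × 30 mm) in a clear hydrogel, stains all cells
with a long-term tracer (live channel) and membrane-compromised cells with
an impermeant DNA dye (dead channel), applies an antiseptic (chlorhexidine,
400 µM) at the top, and images the whole implant tomographically every 7 h
for 63 h. The readout is the speed of the cell-death front moving down the
implant.

`slotsim` is a tested, fully synthetic implementation of that measurement
chain for people developing or validating such analyses: it generates
ground-truth phantoms with known front kinetics, simulates the imaging,
and quantifies the result, so every analysis step can be checked against
the known truth. The quantification half also accepts externally produced
reconstructed volumes (multi-page TIFF stacks).

## The model and the readout

* **Phantom** — cells are point emitters placed uniformly at random
  (Poisson count, mean `ρ·2πrL`) on the lateral cylinder surface. A
  toxicant front moves down from the top: behind it, cells pass the
  concentration threshold θ and switch (irreversibly) to the dead channel.
  Modes: sharp front at `z = v·t` (default), constant-source diffusion
  `C(z,t) = C0·erfc(z/(2√(Dt)))`, or a spatially homogeneous control.
  Dead-stain emission photobleaches by a factor `b` per imaging exposure.
* **Imaging** — parallel-beam emission tomography: for each of `n` angles
  over 360°, detector pixel `(h, s)` records the line integral of slice `h`
  along the ray `x·cosφ + y·sinφ = s`. Reconstruction is filtered back
  projection (band-limited ramp or Shepp-Logan kernel, backprojection
  scaled by `π/2n`).
* **Quantification** — side-view maximum intensity projection, axial
  profile averaged over the implant-width columns, and a single max-to-1
  normalization per channel across the whole time series. The difference
  spectrum of succeeding dead profiles `ΔI_t(z) = I_t(z) − I_{t−1}(z)`
  shows a positive peak at the front; ordinary least squares of peak
  position on time gives the front velocity `v` and `R²`, and the run is
  classified `directed` (`R² ≥ 0.9`, slope ≥ 0.02 mm/h) or
  `non_systematic`.

See `docs/methods.md` for assumptions, parameter defaults and numerical
choices.

## Worked example

```python
from slotsim import ScenarioConfig, run_study

config = ScenarioConfig(rng_seed=1)   # Ø 3 mm × 30 mm implant, v = 0.2 mm/h,
                                      # 96×96×384 voxels, 120 angles, t = 0..63 h
result, manifest = run_study(config)  # simulate → project → FBP → quantify → track
fit = result.fit
print(f"front velocity {fit.slope:.3f} mm/h, R^2 = {fit.r_squared:.3f}, "
      f"{fit.n_points} points -> {result.label}")
```

prints

```
front velocity 0.188 mm/h, R^2 = 0.993, 9 points -> directed
```

i.e. the pipeline recovered the configured 0.2 mm/h front velocity to
within ~6 % (the residual is band quantization: each 7 h interval paints a
1.4 mm band of new death), with a fit quality well above the `directed`
threshold. The homogeneous control comes out the other way:

```python
control = ScenarioConfig(front_mode="homogeneous_control", rng_seed=1)
result, _ = run_study(control, profile_source="emission")
print(result.label)        # non_systematic
```

The same chain is available from the shell, stage by stage or in one shot:

```bash
slotsim pipeline --config scenario.yaml --outdir run/   # writes TIFFs, CSVs,
                                                        # fit record, manifest
slotsim assay --in plate.csv --out plate_out.csv        # MTT / LDH percentages
```

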