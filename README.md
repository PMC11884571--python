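# stretchfield

Quantitative analysis of pneumatic cell-stretching videomicroscopy.

Pneumatic stretching devices deform an elastomeric culture membrane under
cyclic vacuum while cells growing on it are imaged live. Quantifying such
experiments requires a chain of measurements: the membrane strain actually
delivered to the cells, its stability over many hours of cycling, the
kinematics and shape changes of the cells themselves, and the dynamics of
the pneumatic actuation. `stretchfield` implements that whole chain as a
tested, reusable Python library, driven by a synthetic-data generator with
analytically known ground truth so every estimator can be validated
end-to-end.

## What it computes

**Displacement by digital image correlation (DIC).** Relaxed/stretched image
pairs of a tracer-particle speckle pattern (or of the cells themselves) are
correlated with a multi-pass, window-deformation scheme: normalized FFT
cross-correlation per interrogation window, 3-point Gaussian subpixel peak
fit, normalized-median outlier rejection, and between passes a warp of the
deformed image by the current field. The default pass schedule is 320 px
windows / 160 px step, then 160/80, then 80/40, with CLAHE (64 px tiles)
preprocessing. Pairs follow the per-period referencing convention: every
stretched frame is compared against the relaxed frame of its own period.

**Green–Lagrange strain.** From the displacement field U on the DIC grid,

    E = ½ (∇U + ∇Uᵀ + ∇Uᵀ∇U) = ½ (FᵀF − I),   F = I + ∇U,

with gradients by central differences on the calibrated grid. Strain fields
are cropped at the borders (DIC boundary artifacts), spatially averaged over
a region of interest, normalized to t = 0, and summarised by stability
metrics (maximum relative fluctuation per component, maximum absolute
change). The closed-form Poisson membrane deflection dz_P = ½ ν ε h is also
provided.

**Cell readouts.** Mean cell speed by single-pass windowed correlation of
consecutive unstretched frames (32 px windows, 16 px step); junctional
fluorescence as the whole-FOV integral after rolling-ball background
subtraction (100 px disk), normalized to the first frame; and per-cell
morphometrics from label masks — registration to a landmark, segment
cropping, centroid tracking, area, perimeter (Crofton estimator),
circularity 4πA/P² and shape factor P/√A — normalized per cell to t = 0
with population mean ± SEM.

**Pneumatics.** Set-point vacuum waveforms (rectangular / trapezoidal /
sinusoidal, finite slew rate, sampled), a linear time-invariant lag model of
the valve response (underdamped second order by default, reproducing the
measured ≈300 ms evacuation with overshoot and ≈1.5 s settling),
pressure-change rates by central differences, per-period rate peaks with
mean ± SEM, vacuum-percent ↔ absolute-pressure conversion, implied strain
rates from the linear strain–vacuum relation, and acquisition schedules.

**Synthetic data.** Speckle images of Gaussian tracer particles warped by
prescribed affine or radial deformations (with an exact analytic
displacement query), monolayer time-lapses (Voronoi label masks,
phase-contrast-like texture, junction fluorescence with a controllable
amplitude ramp, controllable drift speed), and actuation schedules.
Everything is bit-reproducible under a fixed seed.

## Worked example

```python
import numpy as np
from stretchfield import synthgen
from stretchfield.dic import ImagePair, PassSchedule, clahe, estimate_displacement
from stretchfield.strainfield import green_lagrange, crop_and_average, poisson_deflection
from stretchfield.pneumatics import implied_strain_rate, cycles_in_duration

img = synthgen.generate_speckle(synthgen.SpeckleSpec(image_size=(512, 512), seed=7))
warped, _ = synthgen.apply_deformation(
    img, synthgen.DeformationSpec(kind="radial", radial_strain=0.05))
pair = ImagePair(clahe(img), clahe(warped), calibration=0.5675)
field = estimate_displacement(pair, PassSchedule(((128, 64), (64, 32))))
exx, eyy, exy = crop_and_average(green_lagrange(field))
print(f"recovered strain: Exx = {exx:.4f}, Eyy = {eyy:.4f}, Exy = {exy:.5f}")
print(f"expected Green-Lagrange strain for a 5% radial stretch: {0.5*(1.05**2-1):.4f}")
print(f"Poisson deflection (nu=0.5, eps=10%, h=100 um): {poisson_deflection(0.5, 0.10, 100.0)} um")
print(f"implied strain rate at 2 bar/s: {implied_strain_rate(8.0, 0.35, 2.0):.0f} %/s")
print(f"stretch cycles in 18 h at 20 s period: {cycles_in_duration(18*3600, 20.0)}")
```

prints

```
recovered strain: Exx = 0.0513, Eyy = 0.0514, Exy = 0.00000
expected Green-Lagrange strain for a 5% radial stretch: 0.0513
Poisson deflection (nu=0.5, eps=10%, h=100 um): 2.5 um
implied strain rate at 2 bar/s: 46 %/s
stretch cycles in 18 h at 20 s period: 3240
```

The recovered equibiaxial strain matches the analytic tensor ½(FᵀF − I) of
the prescribed 5% radial stretch to well under half a percent of strain, and
the two components agree as radial symmetry demands. The 46 %/s figure is
the strain rate implied by a 2 bar/s evacuation when 8% strain is reached at
0.35 bar vacuum depth.

Three end-to-end in-silico experiments (strain–vacuum sweep with linear
fit, long-term cyclic stability, four-mode stretch switching) are available
through `stretchfield.pipeline` or the CLI:

```sh
stretchfield run strain_vacuum_sweep --out results/sweep --seed 1
stretchfield pneumatics simulate --out results/pneu --duration 400
```

## Layout

- `src/stretchfield/synthgen.py` — ground-truth generators
- `src/stretchfield/dic.py` — multi-pass window-deformation DIC
- `src/stretchfield/strainfield.py` — Green–Lagrange strain and series statistics
- `src/stretchfield/cell_readouts.py` — speed, fluorescence, morphometrics
- `src/stretchfield/pneumatics.py` — waveforms, lag model, rate statistics
- `src/stretchfield/pipeline.py` — end-to-end experiments and configs
- `docs/methods.md` — models, assumptions, parameter choices, limitations
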