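# Methods

This note documents the models and estimators implemented in `stretchfield`,
the defaults chosen where the design was open, and what validation on
synthetic data does and does not demonstrate.

## Coordinate and sign conventions

Pixel centers sit at integer coordinates, origin top-left, x rightward
(columns), y downward (rows). A deformation is described by its gradient F
acting about a center c (default: the image center), with ground-truth
displacement U(x) = (F − I)(x − c); the displacement at the stretch center
is exactly zero. DIC reports U mapping relaxed coordinates to stretched
coordinates, so a feature at x in the relaxed frame sits at x + U(x) in the
stretched frame. Strain is dimensionless; displacement gradients are taken
on the calibrated (µm) grid, so results do not depend on the µm/px
calibration. Pressure is absolute: 1 bar is atmosphere, and v % vacuum
corresponds to (1 − v/100) bar.

## Synthetic data generator

The generator provides the ground truth that every estimator is scored
against.

*Speckle.* Tracer particles render as isotropic Gaussians (default
σ = 1.2 px, emulating 0.2–0.5 µm particles at a 10–20x air objective). The
particle count is Poisson(density · area) with positions uniform over a
margin-extended field, so density is unbiased up to the image border.
Default density 3·10⁻³ px⁻² gives roughly 19 particles per final 80 px
interrogation window — comfortably above the ~10-particle rule of thumb for
stable correlation. Noise is additive Gaussian (default σ = 3 gray levels on
a 0–255 range), clipped. No point-spread function, photobleaching or
defocus is modeled: the generator supports correlation validation, not
optics research.

*Deformations.* Affine warps use inverse mapping with bicubic interpolation
(nearest-neighbor for label masks so labels stay integral); out-of-frame
content is filled with the background level (label 0 for masks). Radial
stretch is homogeneous equibiaxial strain U = ε_r (x − c), the idealisation
of a radially symmetric membrane stretch observed to be homogeneous in the
field of view.

*Monolayers.* Cells are a seeded Voronoi tessellation (a complete label
image — segmentation is an input contract, mirroring the use of an external
segmenter on real data). Junction fluorescence is a Gaussian ridge confined
within a fixed half-width (2 px) of label boundaries, scaled per frame by an
amplitude schedule; it carries no additive noise so that the
boundary-confinement invariant holds exactly. The phase-like channel is
per-cell shading plus smoothed granularity plus edge ridges, with read
noise. Collective migration is a rigid translation at a set µm/h drift
speed. Real monolayers rearrange, divide and move heterogeneously; passing
the drift-recovery test shows the speed estimator is unbiased for coherent
motion, not that it handles T1 transitions or division events.

## Digital image correlation

The estimator is multi-pass windowed cross-correlation with window
deformation, the standard architecture for finite-strain speckle DIC:

1. **Preprocessing.** CLAHE with 64 px tiles (clip limit 0.01), applied
   identically to both frames, normalizes speckle contrast.
2. **Correlation.** Windows are zero-meaned and correlated by *zero-padded*
   FFT; the plane is divided by the triangular overlap factor and by the
   window energies, giving unbiased correlation-coefficient estimates.
   Circular (unpadded) correlation was measurably biased toward zero on
   broad-peaked textures — up to tens of percent on smooth phase-contrast
   texture — which motivated the linear form. The peak is searched within a
   quarter window of zero lag (the PIV one-quarter rule); at larger lags the
   overlap normalization amplifies noise into spurious peaks.
3. **Subpixel.** 3-point Gaussian fit per axis, falling back to a parabolic
   fit when a correlation lobe is non-positive.
4. **Validation.** A window is invalid if its peak sits at the search-region
   edge or its primary/secondary peak ratio is below 1.3. The normalized
   median test (threshold 2.0, regularisation 0.1 px) flags outliers; both
   are replaced by the local median for the next pass but stay flagged in
   the output and are excluded from all averages.
5. **Window deformation.** Between passes the deformed image is warped by
   the linearly interpolated current field and the grid is refined
   (320/160 → 160/80 → 80/40 px by default, 50% overlap). The predictor
   handed to the next pass is lightly smoothed (Gaussian, σ = 0.8 grid
   units, mirror boundary so linear ramps are preserved); unsmoothed
   grid-scale noise in the warp field otherwise stalls convergence. The
   final pass runs twice (`final_iterations = 2`): the second iteration
   measures a near-zero residual, where all remaining multiplicative biases
   vanish.

On the default 1000×1000 px speckle fixtures, pure translations are
recovered to ≈0.006 px RMS and 8–12% homogeneous strains to ≈0.1 px RMS
over the interior grid. Accuracy degrades in the outermost grid ring, where
stretched content genuinely leaves the frame — precisely the boundary
artifact that the strain stage crops.

## Strain analysis

E = ½(∇U + ∇Uᵀ + ∇Uᵀ∇U) with central differences interior and one-sided
differences at the grid edges. Spatial averages exclude a border ring
(default margin 1 grid point), invalid DIC vectors, NaNs and any
user-supplied exclusion mask (e.g. defocused regions — no automatic
noise-based detection is attempted). Series are normalized per component to
the t = 0 value; a zero baseline is an explicit error. Stability metrics
report max |norm(t) − 1| per component and max |avg(t) − avg(0)|.

With a 40 px final-pass step and calibration 0.5675 µm/px, the strain grid
spacing is ≈22.7 µm and a centered 500 × 500 µm region of interest resolves
484 strain data points (22 × 22).

The Poisson membrane deflection dz_P = ½ ν ε h (ν ∈ [0, 0.5]) gives the
focal-plane drop of the top surface of an incompressible elastomer membrane
under equibiaxial strain: 2.5 µm for ν = 0.5, ε = 10%, h = 100 µm.

## Cell readouts

*Speed.* Single-pass correlation (32 px windows, 16 px step, two
iterations) between consecutive *unstretched* frames only, so stretch
displacement never contaminates motility; mean displacement magnitude over
valid windows divided by the frame interval (default 2 min), reported in
µm/h and normalized to the first interval. On cell-like texture the
aperture problem along straight junctions leaves a residual low bias of a
few percent — well inside the ±10% validation band.

*Fluorescence.* Rolling-ball background subtraction (100 px disk) per
frame, then the whole-FOV sum, normalized to frame 0. Large radii use the
ImageJ-style acceleration: block-minimum shrink (factor up to 8), ball on
the shrunk image, bilinear enlargement. The block minimum drops structures
narrower than the block, so junction ridges never contaminate the
background estimate; narrow-ridge peak heights survive within 5% and smooth
backgrounds are removed to within 5% of their amplitude.

*Morphometrics.* Perimeters use the Crofton multi-direction estimator —
naive boundary-pixel counting overestimates perimeter and biases
circularity low; a rasterized disk of radius ≥ 30 px yields circularity
within [0.98, 1.02] and shape factor within 1% of the isoperimetric bound
2√π ≈ 3.545. Tracking matches nearest centroids frame to frame under a
15 µm/frame gate, ties broken by smallest relative area change; tracks end
at border contact or lost match, and generator label identity is ignored so
the tracker works on arbitrary masks. Per-cell normalization requires
presence from frame 0; the population summary is mean ± SEM (ddof = 1; SEM
is reported as 0 for a single cell).

## Pneumatic model

Set-point waveforms are slew-rate-limited (default 17.5 bar/s) and sampled
(default 10 ms). Rectangular cycles have 50% duty — the stretched (vacuum)
plateau occupies half of each period — with the evacuation opening each
period so every period contains one evacuation and one venting transition.

The valve/plumbing dynamics are unknown; the response is modeled as the
simplest LTI system consistent with the two characterised figures: an
underdamped second-order lag with ζ = 0.5 and natural frequency set so the
step response first crosses its final value 300 ms after the step
(ω_n ≈ 8.07 rad/s), which also settles within ±2% well before 1.5 s. A
first-order lag (time constant τ) is available where no overshoot is
wanted; damping ≥ 1 degenerates to a monotone response. Rate analysis uses
central differences (one-sided at the trace ends) and per-period extreme
rates, summarised as mean ± SEM over complete periods.

Implied strain rate assumes the observed linear strain–vacuum relation:
s % strain at depth d bar gives sensitivity s/d %/bar, so a rate r bar/s
implies (s/d)·|r| %/s, rounded to the nearest integer as conventionally
reported (8% at 0.35 bar with 2 and 1.3 bar/s gives 46 and 30 %/s).

## In-silico experiments and problem sizes

The pipeline funnels all randomness through one seed per run and is
bit-reproducible. The vacuum → deformation map targets *Green–Lagrange*
strain linearly in vacuum percent (the quantity that is observed to be
linear), converting to stretches via λ = √(1 + 2E); radial sensitivity
8%/35% vacuum, uniaxial 12%/35% axial with −4%/35% lateral contraction.

Defaults are sized so each experiment runs in minutes on one CPU as the
package's standard desk-scale configuration: sweeps and mode switches use
768 × 768 px speckle frames (512 × 512 in the test suite), and the
long-term stability run analyses 13 pairs at 10-min spacing (a 2 h slice of
the 18 h protocol; the full 109-pair protocol is a config choice). The
same particle field is reused across a stability run — the physical
membrane keeps its tracers — while read noise is redrawn per frame.

## Known limitations

- The DIC outer grid ring is unreliable at large strains (content leaves
  the frame); consumers must respect the crop margin.
- The monolayer generator's rigid drift cannot validate estimators against
  cell rearrangement, division, or heterogeneous motion.
- The LTI pneumatic model is constrained only by the 300 ms evacuation and
  1.5 s settling figures; its internal parameters are not identifiable from
  those two numbers and should not be interpreted physically.
- No automatic detection of defocused/noisy strain regions is attempted;
  exclusion masks are the caller's responsibility.
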