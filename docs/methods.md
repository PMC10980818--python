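# Methods

## The model

propsim models projection imaging in a tilted-sheet microscope (OPM/LLSM
geometry).  The coverslip defines the x (scan) and y axes; z is height.
The light sheet spans y and the in-plane unit vector (sin φ, 0, cos φ);
at scan position s the sheet occupies {(s + t·sin φ, y, t·cos φ)}.  During
one camera exposure the sheet is swept across the sample (the focal sweep)
while the image is translated ("sheared") over the camera by
g(s) = r·s + q(s) + b, and a rolling shutter of width W tracks the shear
with a row offset c0 and a time delay τ.

Three closed forms follow from the row residual
u − u_sh = z/cos φ + q(s) − c0 − v_u·τ (v_u = r·v_s is the shutter row
speed):

- **slab selection** — z_depth = W·cos φ, z_center = (c0 + v_u·τ)·cos φ;
- **viewing angle** — tan ψ = tan φ − 1/(r·cos φ); the projection lines are
  x = x0 + z·tan ψ, and r = 1/sin φ gives the top-down view;
- **curved selection** — a nonlinear waveform q(s) selects the layer z*(x)
  solving z/cos φ = c0 + v_u·τ − q(x − z·tan φ).

The residual is independent of x and of r, which is the essential property:
depth selection (shutter) and viewing direction (shear rate) are decoupled,
and the projection depth is decoupled from the sheet thickness and the
detection depth of focus.

### Assumptions

- Magnification is fixed at 1; camera rows are expressed in sample-space µm
  and a helper converts rows ↔ µm through the pixel pitch.
- The sheet profile is Gaussian across the sheet with 1/e half-thickness
  `sheet_sigma`; 0 means an ideally thin sheet (used wherever sharp slab
  edges matter, including all headline measurements).
- The shutter edge is a hard binary mask at row granularity; sub-row
  partial exposure is not modelled.
- Detection depth-of-focus blur and optical aberrations are not modelled —
  the model isolates the selection geometry, which is independent of them.
- Sign conventions (arbitrary, fixed here): positive delay τ moves the slab
  towards +z; positive ψ tilts the viewing direction towards +x.

## Frame coordinates

Simulator frames are reported on a *sample-space row grid*: the camera row
u is divided by the shear rate r, which is the global scale ("warp") stage
of the shear-warp factorisation.  A point at (x, z) then lands at frame row
x − z·tan ψ for any linear waveform, so optical frames and digital
(renderer) frames live on one grid and can be compared pixel-by-pixel.
Simulator frames are indexed (row, column) = (sheared x, y) and tagged
`axes="uy"`; renderer frames are (y, x), tagged `axes="yx"`;
`compare_frames` aligns the two automatically.

## Numerics

- **Sweep discretisation.**  One sweep step per row-pixel of travel
  (Δs = pixel pitch) by default.  With linear interpolation the sampled
  triangular kernels form an exact partition of unity at this spacing, so a
  full-open top-down frame integrates exactly the volume intensity
  (verified to < 1% with interior beads, and exactly in the partition
  checks).  Frame-level convergence is second order: halving the step
  changes a bead-phantom frame by NRMSE ≈ 0.7% (relative to the frame
  dynamic range), and a further halving by ≈ 0.2%.
- **Interpolation.**  Trilinear sampling of the sheet plane
  (`scipy.ndimage.map_coordinates`, order 1); out-of-volume samples read 0.
  Accumulation into frame rows uses linear splatting, so centroids are
  sub-pixel accurate (≤ 0.05 px in the bead tests).
- **Hard slab membership.**  A plane belongs to the slab iff its centre
  lies in the *closed* interval [z_c − Δz/2, z_c + Δz/2]; exact-boundary
  ties are included, deterministically.  The optical shutter mask reduces
  to the identical criterion, which is why optical and digital projections
  agree to numerical precision when interpolation nodes coincide.
- **Waveform design.**  s(x) = x − z*(x)·tan φ must be strictly increasing
  (invertibility bound max|dz*/dx|·tan φ < 1); the inverse x(s) uses
  monotone PCHIP interpolation, and q is resampled on the sweep grid and
  held constant beyond it.
- **Surface prediction.**  The implicit equation for the selected layer is
  solved by fixed-point iteration from z = cos φ·(c0 + v_u·τ − q(x)).  The
  plain iteration map has derivative −β/(1−β) (β = surface slope · tan φ)
  and stops contracting at β = 1/2, well inside the invertible regime
  β < 1; the iteration is therefore relaxed with the optimal factor
  α = 2/(2 − lo − hi) computed from the waveform's own slope bounds
  [lo, hi] of the map derivative.  For q ≡ 0 this reduces to the plain
  iteration (α = 1).  Tolerance 0.01 µm, cap 50 iterations; the designed
  arc round-trips to ≤ 0.13 µm.
- **Gaussian slab weighting** (`weighting="gaussian"`) uses an
  FWHM-matched window σ = Δz/2.355 for realism; all quantitative checks
  use the hard window, which is the oracle definition.

## Synthetic phantoms: what they emulate, and what they do not

All generators are seeded and return ground-truth tables sufficient to
compute every recovery statistic without re-inspecting the volume.

- **Beads** — isotropic (optionally z-anisotropic) Gaussians; used as point
  probes for slab edges, parallax and energy accounting.  The headline
  measurements use *bead ladders*: beads stepping finely through z, each at
  its own (x, y) raster position so every bead occupies a disjoint frame
  window.  A bead counts as "included" when its frame peak exceeds 50% of
  an isolated bead's response; with a symmetric z-profile this measures the
  slab edge at half-maximum, so the bead-ladder z-range recovers the slab
  depth to within one ladder step.  Ladder steps and volume z-sampling are
  chosen a factor ≳ 50 finer than the measured depths, so discretisation
  contributes ≲ 2% to any reported value.
- **Vessels** — cubic-spline tubes of radius 2–4 µm with a soft parabolic
  cross-section; spatially extended, overlapping structures for the
  oracle-equivalence checks.  No attempt at topological realism.
- **Curved shell** — a cylindrical arc z*(x), invariant in y, decorated
  with on-surface blobs and flagged off-surface distractors; the
  curved-projection analogue of imaging a curved embryo surface.
- **Two-layer calcium movie** — soma-like Gaussian cells in two z-layers;
  fluorescence F(t) = F0·(1 + Σ A·k(t − t0)) with the double-exponential
  kernel k(t) = (1 − e^(−t/τ_r))·e^(−t/τ_d), defaults τ_r = 0.05 s,
  τ_d = 0.5 s, A = 0.5 (GCaMP-like kinetics; the kinetic form and defaults
  are this package's choice).  Optional seeded Poisson noise.
- **Haze** — a deliberately simple scattering surrogate: each plane blurred
  with σ(z) = σ0 + k·z (periodic boundaries, so per-plane photon count is
  conserved exactly) plus a smooth positive pedestal of mean
  pedestal_frac × plane mean.  It reproduces the *phenomenology* that
  matters for shutter-width trade-offs (background grows with integrated
  depth) but is not a radiative-transfer model: passing haze-rejection
  tests shows the selection geometry rejects out-of-slab signal, not that
  any particular tissue's scattering is predicted.

More generally, phantom tests validate the acquisition *geometry* and the
analysis chain under a linear, aberration-free imaging model; they say
nothing about resolution limits, PSF shape, photobleaching or motion, which
are out of scope.

## Measurement and analysis choices

- dF/F baseline defaults to the 20th percentile of the trace (configurable;
  a stated-window mean is also available).  ROI traces are plain means over
  a mask.
- Static-background subtraction uses the temporal median (or minimum) per
  pixel and clamps at zero for display; the raw signed residual is
  available with `clamp=False`.
- SBR is mean(foreground)/mean(background) over disjoint masks.
- Galvo calibration is an ordinary least-squares line with r² and the
  maximum absolute residual reported as the linearity assessment.

## Problem sizes

Default test scale is a 96³–128³ voxel phantom at 1 µm isotropic sampling;
the mesoscopic wide-shutter measurement uses a 0.5 × 2 × 2 µm grid over a
400 µm z-range (812 × 124 × 128 voxels, 801-bead ladder).  The full test
suite runs in well under a minute and the acceptance script in a few
seconds on one CPU; these sizes were chosen so that discretisation error is
negligible relative to the measured quantities, as quantified above.

## Known limitations

- The shear is one-dimensional, so curved selections vary along x only
  (matching single-galvo optics); 2-D surfaces z*(x, y) are out of scope.
- The nonlinear waveform perturbs the local viewing angle through the
  effective rate r + dq/ds; `local_view_angle` exposes this as a
  diagnostic, but no quantitative claims are attached to it.
- Camera effects below row granularity (line-by-line exposure timing,
  saturation, fixed-pattern noise) are not modelled.
- `simulate_stack` is an idealised plane-by-plane acquisition used for
  data-size and projection-equivalence accounting, not a model of any
  specific stage/piezo implementation.
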