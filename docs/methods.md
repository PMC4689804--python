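# Methods

This note documents the models, numerical choices and limitations of
`histotract` at the level of detail a maintainer or reviewer needs; the
README gives the user-facing overview.

## Coordinate and angle conventions

Images are indexed `(row, col)`; physical coordinates are `x = col`
(rightward) and `y = row` (downward). All orientations are reported as
`theta = atan2(v_y, v_x)` in degrees, reduced to `[-90, 90)`. Positive
angles therefore rotate from +x toward +y, i.e. clockwise on screen; a
screen-counterclockwise image rotation by φ *decreases* theta by φ
(mod 180). One convention is used everywhere — structure-tensor output,
phantom ground truth, hue mapping, streamline colors — so recovered and
true angles compare directly without sign juggling.

## Preprocessing

Two dialects reflect the two consumers of a section image:

- **hsb**: luminance (Rec. 601) grayscale, then 8-bit inversion, so stained
  (dark) fibers become bright texture. Input to orientation mapping and the
  HSB render.
- **tract**: red-channel extraction, CLAHE, linear normalization to
  [0, 255]. Input to the tractography substrate. The nominal "0–256" target
  range of such normalizations is read as the representable 8-bit range
  [0, 255]; both bounds are configurable (`prep.out_range`). CLAHE
  parameters are unstated in the protocol this pipeline follows; the
  defaults are standard practice (normalized clip limit 0.01, 8×8 tile
  grid) and both are exposed. Whether channel extraction should be combined
  with inversion is left switchable (`prep.invert`), since stains and
  scanners differ in polarity.

Down-sampling from the native scan (0.23 µm at 40X) is block-mean with edge
truncation: anti-aliasing, mean-preserving on exact blocks, and exactly
testable against a loop oracle. Output dims are `ceil(n/factor)`; the pixel
size scales with the factor.

## Structure tensor

`G = w_sigma ⋆ (∇I ∇I^T)` with reflected boundaries. The default gradient
is the cubic-spline derivative (B-spline prefilter, then the `[−1/2, 0,
1/2]` derivative kernel); central difference is available for pipelines
that do not prefilter. The Gaussian window default is **sigma = 5 px**,
the convention of structure-tensor plugins that parameterize the window by
its standard deviation.

A numerical floor zeroes tensor components whose trace is below
`(64·eps·max|I|)²` — pure floating-point dust such as the spline
prefilter's residue on constant images — so constant inputs yield exactly
zero tensors and coherency never divides round-off by round-off. The floor
scales with the squared intensity, preserving scale invariance of all
derived maps.

The eigen-solution is the closed 2×2 symmetric form. **Fiber orientation is
the minor eigenvector**: the structure tensor's major eigenvector points
along the intensity gradient, i.e. across the stained fibers. Isotropic
pixels (eigenvalue gap ≤ 1e−12 × trace) take `theta = 0`, coherency and
FA_2d 0, by convention.

FA_2d defaults to the form with denominator `sqrt(λ1² + λ2²)` (range
[0, 1/√2], rank-1 limit 1/√2); an alternate `(λ1+λ2)²` denominator (range
[0, 1/2]) sits behind `st.fa_denominator="sum"`. The two are monotonically
related, so thresholded behavior is unchanged up to a re-mapped threshold.

Known estimator bias: with separable derivative kernels, the component
ratio `I_y/I_x` of a plane wave is `sin(ω_y)/sin(ω_x)` rather than
`ω_y/ω_x` (the spline prefilter cancels in the ratio), which pulls oblique
orientations slightly toward 45°: ≈1.4° at stripe period 8 px, ≈0.6° at
period 12 px. This motivates the phantom default period below.

## Pseudo-tensor embedding and masks

The 2D tensor is embedded in 3×3 form with all z components zero, giving a
single-slice 4D NIfTI (dims X×Y×1×6, components dxx, dxy, dxz, dyy, dyz,
dzz; affine = identity × voxel size, origin at the image corner). The
default embedding is the eigen-swap `T = (λ1+λ2)·I − G` — same
eigenvectors, eigenvalues exchanged — so the *principal* eigenvector of the
exported tensor lies along fibers, which is what deterministic trackers
follow; embedding the raw G would produce streamlines orthogonal to every
fiber bundle. The literal embedding is retained
(`tensor.track_convention=false`) for comparison with pipelines that
compensate downstream. FA_2d is invariant under the swap.

Tensor down-sampling (default factor 4) block-means the six components —
tensors average linearly — and then *recomputes* FA from the averaged
tensors; averaging FA itself is biased upward wherever fibers cross within
a block.

The brain mask is Otsu thresholding, morphological closing (disk radius
5 px), hole filling, and largest-connected-component selection; each step
can be toggled, because histological backgrounds vary more than any single
recipe. Seeds are in-mask pixels with FA_2d at or above the nearest-rank
95th percentile of in-mask FA — the top 5% of anisotropy, read as a
high-pass cut ("keep top 95%" would seed nearly the whole section and
defeat the purpose of a seed mask. The percentile is configurable).
FA for seeding is computed at full resolution, down-sampled with the
tensors, and recomputed at the coarse resolution where seeding happens.

## Tracking

Classical RK4 through the principal-eigenvector field, with:

- **Probabilistic nearest-neighbor interpolation**: at a continuous
  position, one of the ≤4 surrounding voxels is drawn with probability
  equal to its bilinear weight; that voxel supplies both the tensor and
  the FA used for the stopping test (a consistent substrate, rather than a
  bilinear FA estimate over voxels the tracker never visited).
- **Per-stage sign alignment** to the incoming step direction (tensor
  fields are axial; eigenvectors have no preferred sign).
- **Step renormalization**: the combined RK increment is rescaled to length
  exactly `step_px` (default 2), so point spacing is uniform by
  construction.
- **Stopping rules**, in precedence order at every stage and step: exit of
  the brain mask or grid; FA ≤ 0.1; turning angle ≥ 75°; step cap; locally
  isotropic tensor. The curve threshold is enforced both between
  consecutive steps and for each RK stage against the incoming direction —
  without the stage check, the four-stage averaging smears a sharp
  orientation discontinuity (e.g. 80°) into two sub-threshold turns and
  slides through it.
- **Iterations**: 10 stochastic repetitions per seed voxel (they differ
  only through the interpolation draws); launches are bidirectional
  (two antiparallel starts joined at the seed) unless disabled.
- **Defaults that are package choices, not protocol constants**:
  `max_steps = 2000` per launch direction and `min_points = 5` (shorter
  polylines are discarded as seed-local noise). Both configurable.

Reproducibility: seed voxel `i` consumes RNG substream
`default_rng([run_seed, i])`, so output is bit-identical for a fixed seed
and independent of iteration order.

Streamlines are written as legacy ASCII VTK polydata (POINTS, LINES, and a
per-point `COLOR_SCALARS eigvec_color 3` array). Colors come from the same
orientation hue wheel as the HSB render, applied to the local segment
direction. A VTK dependency is deliberately avoided; the writer is ~40
lines and a minimal parser ships for round-trip testing.

## Phantoms: what they emulate, and what they do not

The generators produce inverted-stain-like images — bright fiber texture on
dark ground — with exact per-pixel truth:

- `make_stripe_phantom` — band-limited (sinusoidal) parallel fibers at any
  angle. Sinusoids rather than binary bars keep gradient estimators
  well-behaved; the **default period is 12 px**, chosen once so the
  estimator's intrinsic direction bias (see above) stays well under 1°
  relative to the σ = 5 analysis window.
- `make_arc_phantom` — concentric-ring texture in an annulus around a dark
  "ventricle": fiber direction exactly tangential, the geometry of a
  C-shaped periventricular bundle.
- `make_layered_wall_phantom` — the laminar anisotropy signature of the
  fetal telencephalic wall: dim directionless VZ, bright tangential IZ with
  a configurable radial crossing fraction, low-contrast crossing SP,
  radially striped CP.
- `make_perpendicular_phantom` — a jittered bright-dot field (the in-plane
  appearance of axons cut across the section) beside in-plane stripes:
  high intensity, near-zero in-plane coherency.
- `make_crossing_phantom` — additive superposition of two stripe fields
  with a mixing fraction; truth records both angles and the dominant one.
- `make_angle_field_volume` — bypasses imaging entirely and constructs the
  tensor volume for a prescribed angle map; used to state tracking
  contracts (step length, curve threshold, FA floor) exactly.

What passing on phantoms does *not* show: real sections have stain
gradients, tearing and folding artifacts, out-of-focus regions and
non-sinusoidal fiber texture; the phantoms model none of these, so phantom
results certify the algorithmic chain, not robustness to histological
artifacts. Tissue damaged during processing is known to produce spurious
streamlines and should be screened before interpretation.

## Measurement sizes in tests and the acceptance script

The interior-median orientation deviation is a heavy-tailed, spatially
correlated statistic at high image noise: at noise SD 25 its sampling SD is
≈0.8° on a 512-px phantom and ≈0.4° at 1024 px, against a population value
of ≈0.3°. Orientation-recovery checks therefore use 128/256/1024-px
phantoms for noise SD 0/10/25 — a precision choice for the measurement, not
a change of the noise or contrast conditions. Tracking scenarios bound
runtime by problem size only (phantom canvas 256 px, every n-th seed,
`max_steps` 150–300); the protocol parameters (step 2, curve 75°, FA floor
0.1, 10 iterations, percentile 95, down-sample 4, σ = 5) are never altered.

## Known limitations

- Strictly 2D: through-plane fibers appear as punctate, low-coherency
  texture and cannot be tracked; the pipeline reports them only indirectly
  as streamline-density reductions.
- Single-section: no serial-section stacking or registration to MRI.
- The probabilistic interpolation makes streamline *families* informative;
  a single iteration is not a confidence statement.
- CLAHE tiling can imprint faint seams whose gradients perturb local
  orientation estimates near tile boundaries (visible as a minority of
  off-axis voxels on otherwise uniform phantoms).
- No native whole-slide pyramid reading; sections must be exported to
  TIFF/PNG/JPEG first.
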