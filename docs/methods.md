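# Methods

This note documents the models, numerical choices and limitations behind
`psfqc`. It describes what the code does and why; every number quoted here is
computed by the test suite or by `scripts/acceptance.py`, not asserted from
memory.

## The measurement model

A sub-resolution fluorescent bead images as the microscope's point spread
function. `psfqc` models the recorded spot as a Gaussian: an elliptical 2D
Gaussian in the focal plane through the intensity maximum,

    I(x, y) = B + A · exp(−(u²/2σ_a² + v²/2σ_b²)),

with (u, v) the coordinates rotated by the inclination θ of the major axis to
the image X axis, and a 1D Gaussian along z through the same point. The
Gaussian is an approximation — a diffraction-limited PSF is an Airy pattern
and aberrated PSFs take many shapes — but it is the model every common QC tool
fits, so it is the right common currency for width comparison. Widths are
reported as FWHM = 2√(2 ln 2)·σ ≈ 2.3548·σ (the exact half-maximum relation
for a Gaussian) and converted to nanometres with the voxel calibration; when
the calibration is absent the values stay in pixel units and the report marks
the missing metadata `NA` rather than guessing.

## Detection

The detector must work with no user parameters, over bead sizes spanning more
than an order of magnitude in pixels.

* **Scale space.** The volume is blurred with isotropic Gaussian kernels of
  width σ ∈ {1, √2, 2, 2√2, 4, 4√2, 8, 8√2, 16} px — a half-octave ladder, the
  standard subdivision for difference-of-Gaussians (DOG) detectors. Blurring
  uses periodic boundary handling so each copy conserves the stack's total
  intensity exactly; detections near the border are discarded before fitting,
  so wrap-around cannot affect measurements.
* **Scale normalisation.** On a constant-ratio grid the adjacent-scale
  difference already approximates the scale-normalised Laplacian
  ((k−1)σ²∇²G), so the raw differences are comparable across scales without an
  extra weight; an additional σ² factor would double-count and bias the
  detected scale towards ≈2× the true blob width. The characteristic feature
  size is the geometric mean of the two kernel widths of the globally
  strongest difference — the centre of the maximising band-pass. The unit
  tests verify this against a dense analytic scan of the DOG response of an
  ideal 3D Gaussian blob, which peaks near 0.82 σ_blob in 3D.
* **Threshold.** Candidate maxima must exceed the cross-entropy-minimising
  (Li) threshold of the scale-collapsed DOG volume, computed by the fixed
  point t ← (μ_below − μ_above)/(ln μ_below − ln μ_above), iterated to an
  absolute tolerance of 10⁻⁶ of the value range. Negative DOG values are
  clipped to zero and zeros lifted to 10⁻⁹ of the maximum so the log-means are
  defined; because the lift scales with the data, thresholding is exactly
  equivariant under intensity rescaling. The tests pin this implementation
  against exhaustive minimisation of the cross-entropy objective and against
  scikit-image's independent implementation (comparing the induced
  foreground/background partition — inside an empty inter-mode gap the
  criterion is flat and any threshold in the gap is equivalent).
* **Maxima and exclusion.** Peaks are strict maxima over the 26-neighbourhood;
  a plateau contributes its first voxel in (z, y, x) scan order so results are
  deterministic. The strongest 200 are kept. Any two peaks closer than five
  pixels laterally are both removed: their fitting discs would overlap and
  neither could be trusted. Peaks are located in 3D, so two beads at the same
  lateral position but different focal planes are detected as two features.

## Fitting

* **Patch geometry.** The lateral fit uses a circular disc around the peak: a
  pixel belongs to the disc when its centre lies within radius + ½ px (97
  pixels at the default radius 5). The disc radius adapts to the detected
  feature size as max(5, ⌈2.5 × characteristic scale⌉) so that finely sampled
  spots (tens of pixels across) still fit inside their window, while the
  five-pixel floor matches the exclusion rule. The axial fit uses the single
  (y, x) column through the peak over the full z range — at a bead's centre
  the axial profile is exactly the 1D Gaussian of the model, and averaging
  laterally would mix in off-axis broadening.
* **Initial values and bounds.** Offset starts at the patch-border median,
  amplitude at peak − offset, centre at the peak voxel and both widths at the
  characteristic scale. Widths are bounded to [0.5 px, patch radius]
  (axially, half the stack depth); a solution pinned at a bound, a
  non-converged optimiser or a vanishing amplitude is recorded as
  `fit_failed`, never silently averaged. R² is computed about the mean of the
  unmasked pixels.
* **Canonical orientation.** Fits are normalised so σ_major ≥ σ_minor with θ
  the major-axis inclination folded into (−π/2, π/2]; rotating a patch by 90°
  shifts θ by π/2 (mod π), which the tests check explicitly.
* **Summaries.** Field averages are arithmetic means with sample (n−1)
  standard deviations over features with status `ok`; failures are counted,
  not imputed. With one feature the s.d. is reported absent. Heat-map grids
  (8 × 8 cells, mean value per cell) expose field-dependent variation.

## Ellipse projections

Tools that fit axis-aligned Gaussians report X/Y widths; elliptical fits
report (max, min, θ). The mapping projects the inclined ellipse with semi-axes
a = FWHM_max/2, b = FWHM_min/2 onto the axes. The projection is computed from
the boundary points where the rotated ellipse's tangent is vertical
(parametric angle ε_x with tan ε_x = −(b/a)·tan θ) or horizontal
(tan ε_y = (b/a)·cot θ); the central chord through each pair of extreme points
has length 2√(a²cos²ε + b²sin²ε) and its axis projection is the full extent.
The result equals the closed-form bounding box X′ = 2√(a²cos²θ + b²sin²θ),
Y′ = 2√(a²sin²θ + b²cos²θ), which the tests use as an independent oracle
(together with a sampled-boundary brute force). Note X′ ≥ 2a·cos θ always —
the naive cosine projection underestimates. Inclinations fold into [0, π/2]
by |θ| mod π and reflection about π/2; the projection is invariant under this
folding, and the circle and axis-aligned cases short-circuit the tangent
equations (which would otherwise divide by zero). The reverse mapping
X/Y → (max, min, θ) is underdetermined and deliberately not provided.

## Synthetic data

The simulator renders what the benchmark needs: a known-truth spot in
realistic counts.

* Model: 3D Gaussian, lateral FWHM 273 nm and axial FWHM 1036 nm —
  approximately the theoretical PSF of a 1.15 NA water-immersion objective at
  515 nm emission — on a uniform background B = 100 counts, evaluated at voxel
  centres.
* Noise: each voxel is replaced by a Poisson draw with the noise-free value as
  its mean (shot-noise-dominated detection), using one explicit seed per
  dataset; the mean of many realisations converges back to the noise-free
  volume (checked at reduced size).
* Sweep: lateral pixel sizes {10, 40, 80, 160} nm — from 0.85× to 13.65× the
  Nyquist pixel size of 136.5 nm (half the lateral FWHM) — crossed with peak
  amplitudes {50, 100, 150, 200, 300, 500, 750, 1000} counts, i.e. SBR
  (A+B)/B from 1.5 to 11; 32 datasets plus a CSV manifest of every parameter
  and seed. The axial step is fixed across the sweep; the default
  dz = 100 nm puts ~10 samples across the axial FWHM and is configurable.
* Geometry: the default volume is sized automatically to hold the spot's 3σ
  support plus the fitting margin (e.g. 37×95×95 voxels at dx = 10 nm,
  37×33×33 at 160 nm); a spot whose 3σ support would leave the volume is a
  placement error, not a silent truncation.

What the simulator does **not** emulate: Airy rings and aberration structure,
detector read noise and gain, multiple beads with size dispersion, background
gradients, refractive-index mismatch along z. Passing the synthetic benchmark
therefore demonstrates correct width recovery under shot noise for a
Gaussian-shaped spot — not robustness to every artefact of real acquisitions.

## Benchmark conventions

Lateral error is the RMS of the X and Y FWHM errors as a percentage of the
true width, 100·√(((X_E−W)² + (Y_E−W)²)/2)/W — note the ÷2 inside the root: it
is a true root *mean* square over the two axes (an unaveraged variant would
read √2 larger). Axial error is the absolute percentage error. Both cap at
100 %, and an analysis that returns nothing scores the default 100 %. Scores
classify into the bands <10, 10–20, 20–30, 30–40, >40 % for grid rendering.
When a dataset contains several detected features the per-dataset estimate is
the mean over features.

Self-benchmarking this pipeline on the default noisy sweep lands the high-SBR
cells (SBR ≥ 4 at fine sampling, SBR ≥ 8.5 everywhere) in the best band and
degrades towards the low-SBR, coarse-sampling corner, where detection of a
sub-2-pixel spot under shot noise eventually fails outright — the failure mode
the 100 % default exists to record. The acceptance suite asserts the
deterministic noise-free round trip (lateral and axial FWHM recovered to well
under 2 % at 10 nm sampling) and, stochastically, a median lateral RMSE below
10 % over 20 seeds at SBR 11, dx = 40 nm.

## Problem sizes and determinism

The test suite and the acceptance script regenerate all data at run time; the
largest routine volumes are the 10 nm-sampling model stack (37×95×95 voxels)
and a 250-spot detection field (25×272×272), both chosen as the smallest
geometries that leave the measurements unconstrained by the volume border.
All randomness flows through explicit seeds (`numpy.random.default_rng`);
reports embed an ISO-8601 UTC timestamp which is excluded from determinism
comparisons.

## Known limitations

* Lateral nm conversion uses the X pixel size for the rotated max/min widths;
  rectangular lateral pixels (dx ≠ dy) are faithfully recorded in metadata but
  the elliptical fit itself is performed in pixel space.
* The five-pixel exclusion radius is a fixed convention; densely packed bead
  fields lose both members of each close pair, and under strong noise a
  spurious peak near a real bead can remove it.
* The axial fit assumes the bead's axial profile is symmetric; spherical
  aberration skews real profiles and biases a Gaussian fit.
* Only TIFF input is supported (plain z-stacks or ImageJ-style hyperstacks);
  proprietary formats must be converted first. Ambiguous axis metadata is an
  error by design — silently misreading axes would corrupt every width.
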