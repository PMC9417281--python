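# Methods

This note records the model assumptions, parameter conventions, numerical
choices and known limitations of `nanoshape`.  It states no empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Shape descriptors

Contours are simple closed polygons in pixel coordinates (x = column,
y = row, origin top-left, pixel centers at integer coordinates), stored
counter-clockwise (shoelace area > 0).  All moments are evaluated in closed
form from the vertex list via Green's theorem after resampling to at least
256 equal arc-length points; because resampling commutes exactly with
similarity transforms, the Hu invariants are stable to ~1e-15 under
rotation/scale/translation of a polygon, and to the stated 1e-4 for
arbitrary convex inputs.

Only H₁ and H₂ are used as classification features for convex particles;
H₃–H₇ are available (`n_hu` up to 7) but unused by default, since for
convex shapes the first two carry the discriminating power and keep the
feature space interpretable.  The feature is log₁₀(H + ε) with ε = 1e-12:
H₂ vanishes for circularly symmetric shapes and the feature must stay
finite.  Shapes with H₂ below 1e-10 are flagged isotropic and assigned
orientation 0.

The shape-eigenvalue convention is fixed by the requirement that a
unit-area ellipse yield its semi-axes: with λ₁,₂ = (H₁ ± √H₂)/2 the
eigenvalues of the unit-area inertia tensor, we report η₁,₂ = 2√λ₁,₂.
Checks: a unit-area circle gives η₁ = η₂ = 1/√π (its radius); a 2:1
unit-area ellipse gives η = (√(2/π), 1/√(2π)); perfect ellipses satisfy
η₂ = 1/(π η₁).  Aspect ratio is η₁/η₂.  Effective diameter is the
equal-area-circle diameter, d = 2√(A/π) · pixel size — the standard
metrology convention, and identical to the generator's size convention so
truth and estimate are directly comparable.

## Preprocessing

Denoising: radial Fourier low-pass with a raised-cosine roll-off between
the cutoff and 1.25× the cutoff (DC untouched, so total intensity is
preserved exactly), or a Gaussian.  Thresholding: Otsu by default on a
polarity-normalized signal (bright-field particles are minima, dark-field
maxima), followed by morphological hole filling so internal core–shell
contrast cannot fragment a particle.  Contour tracing is sub-pixel
boundary following (marching squares at the 0.5 level) per connected
component; on a binarized image this is equivalent to edge detection plus
edge linking while avoiding hysteresis parameters.  Border-touching
components are always excluded — their shape is unmeasurable.  Triage uses
solidity (area / convex-hull area) with default threshold 0.95 and an area
window; low-solidity or oversized components are routed to the aggregate
pass, sub-minimum components are debris.

## Mixture classification

EM for the full-covariance Gaussian mixture is implemented in the package
(k-means++ seeding, 10 restarts, best log-likelihood kept; log-sum-exp
responsibilities; covariance eigenvalues floored at 1e-6 × mean feature
variance).  The per-iteration log-likelihood trace is retained; it is
non-decreasing up to a relative tolerance of 1e-6 (the floor and finite
precision can produce sub-tolerance wiggles on nearly degenerate feature
clouds, e.g. exact ellipses, whose within-class scatter is essentially
one-dimensional).  Determinism: a fixed master seed spawns all restart
seeds, so refits are bit-identical.

Class-count selection defaults to BIC over K = 1..K_max (K also capped by
the identifiability requirement N > K·d), followed by pruning of
components with weight < 0.01 and refitting; a pure weight-pruning path is
also available.  Classes are reported in descending order of total
responsibility Σ, so class 1 is always the majority class.  Weighted
standard deviations use the biased (1/Σ) normalization.

## Synthetic scenes

The generator defines the study conditions and is first-class, tested
code.  Shape families (hexagonal platelet, rod, ellipse, rounded cube,
regular polygon) are built from a symmetric base shape with rounded
corners (radius = rounding fraction × inradius) and then stretched by an
area-preserving anisotropic map with factor √AR.  Because the base shapes
have isotropic inertia tensors, the descriptor-measured aspect ratio
equals the requested AR exactly for every family — truth/estimate
comparisons are sharp by construction.  Enclosed area equals
π(size/2)² exactly (the contour is rescaled after construction).

The canned scenarios use: 38 hexagons (64.5 ± 3.0 nm, AR 1.03 ± 0.02) plus
5 rods (49.0 ± 1.1 nm, AR 1.76 ± 0.05) for the dispersed distinct-shape
case; two overlapping rounded-cube classes (AR 1.12 ± 0.05 and
1.25 ± 0.08, ~12 nm, with per-particle corner-rounding jitter sd 0.08) for
the non-distinct continuum; and a cube-like majority with an elongated
minority for the dark-field core–shell case.  AR draws are truncated at 1;
corner-rounding values are free parameters of the generator, not
calibrated to any measured sample.

Rendering uses a projected-thickness-like dome per particle: a steep tanh
rise (width 0.8 px) keeps the half-amplitude crossing at the particle
edge, so thresholding recovers the contour without bias, while a
√(distance) term (weight 0.3) gives the interior the concave profile of
thickness contrast, so the intensity Laplacian has a definite sign inside.
A faint fringe of the same contrast sign just outside the edge (amplitude
0.35 of the dome, centered 0.8 px out) emulates the slight defocus fringe
of real TEM edges; it extends the curvature-sign region marginally past
the contour without moving the intensity step.  Thickness is additive
across overlapping particles, which creates the saddle (opposite-curvature
crease) between touching particles that the binary DoG exploits.
Backgrounds: constant, linear gradient, or a low-order 2-D polynomial plus
band-limited noise.  Dark-field inverts the contrast sign; core–shell adds
a brighter central plateau.  The generator does not attempt physical image
simulation (no multislice, no contrast transfer function) — only the
contrast structure the pipeline consumes.

Touching groups are constructed by sliding one shape towards another until
first contact (bisection on shapely intersection, 60 iterations);
"connected" necks overlap by 6% of the contact distance; aggregates are
three pairwise-connected particles.

## Binary DoG and affine fitting

DoG = G(σ) − G(1.6σ); the ratio 1.6 is the standard
Laplacian-of-Gaussian approximation, and σ defaults to 5% of the median
isolated-particle diameter.  The particle-interior sign is DoG < 0 for
bright field (particles are intensity minima) and DoG > 0 for dark field;
a dead zone of 1e-10 × max|I| keeps exactly-flat regions background.

Templates are averaged from the hard-assigned members of each class: each
contour is normalized to unit area, rotated to its principal orientation
where defined, residual n-fold symmetry resolved by maximal circular
cross-correlation of centroid radius profiles (sub-bin parabolic
refinement), profiles averaged, Fourier-smoothed (default 25 harmonics)
and resampled to 360 arc-length points.  Radius profiles are valid because
convex shapes are star-shaped about their centroid.

Fitting rasterizes the template contour as a 2-px-wide interior ring and
computes its overlap with the mask for every integer translation at once
via FFT cross-correlation (overlap counts are integers, so the FFT result
is rounded and matches direct correlation exactly).  Because rendered
particle interiors carry the interior sign throughout, a contour shrunk
into a particle also scores 1 on the inner ring; placements are therefore
scored two-sidedly: the ring just outside the contour must fall outside
the mask (`outer_score`, default minimum 0.6).  Acceptance is greedy by
combined score with suppression of fits overlapping an accepted fit by
more than 20% area IoU.  The affine grid defaults to rotation step 2°
(reduced by the template's symmetry order), s_x, s_y ∈ [0.8, 1.2] step
0.05 and skew ∈ [−0.15, 0.15] step 0.05; the test suite and acceptance
script use a documented coarser grid (rotation step 4°, scales
0.9–1.1, no skew) that resolves the synthetic scenes while keeping the
sweeps small.  When fitting is restricted to a triaged aggregate region,
the mask is cropped to that region (plus a template-sized margin) and the
mask FFT is cached across the whole grid.

## Problem sizes

Tests and the acceptance script run on: a 1024² scene with 43 particles
(distinct-shape scenario), feature-space ensembles of ~500 particles
(continuum and recovery experiments, 50 seeded replicates), a 900² scene
with 20 particles in isolated/touching/connected/aggregated groups, and
640² scenes for determinism checks.  These sizes resolve every behaviour
the larger-scale method exercises while keeping the suite fast.

## Limitations

- Convex particles only: triage sends non-convex (low-solidity) regions to
  the aggregate pass rather than measuring them; genuinely non-convex
  single particles are not classified.
- The synthetic generator's corner rounding, edge softness, fringe
  amplitude and noise levels are plausible defaults, not calibrated to a
  measured instrument; passing tests demonstrate pipeline correctness
  under dome-like thickness contrast, not performance on any specific
  microscope's data.
- The binary DoG pass assumes aggregate members share the shape classes of
  the isolated particles (templates come from the prior analysis); novel
  shapes appearing only inside aggregates would be missed or mis-labelled.
- Per-particle overlap fractions in projection, and any 3-D shape
  recovery, are out of scope.
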