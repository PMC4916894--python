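# Methods

`laminafluct` quantifies how punctate one nuclear-lamina protein is along
the nuclear envelope relative to another.  The pipeline has four stages:
synthetic image generation (or TIFF loading), z-projection, envelope
segmentation, and the per-nucleus fluctuation index.  This note describes
the model behind each stage, the parameters that matter, the numerical
choices, and the known limitations.

## The biological setting

Mature lamin A/C and lamin B form a near-continuous meshwork at the nuclear
periphery, so their fluorescence along the envelope is smooth.  Prelamin A
— the unprocessed precursor — incorporates at discrete sites, producing
punctate rim staining.  Given a reference channel with continuous rim
signal (lamin B) and a test channel (lamin A/C or prelamin A), the
fluctuation index measures the excess spatial fluctuation of the test
signal relative to the reference, per nucleus.

## Segmentation

1. **Initial boundary.** The counterstain (DAPI-role) maximum-intensity
   projection is thresholded by Otsu's method (histogram between-class
   variance maximization, 256 bins by default).  Holes are filled,
   8-connected components below `min_area` (default 500 px²) are dropped,
   and each remaining blob's boundary is traced sub-pixel with
   `skimage.measure.find_contours`, resampled to `n_contour_points`
   (default 200) uniformly in arc length, and oriented counter-clockwise
   (screen convention: x right, y down) via a signed-area check.
2. **Refinement.** The reference-lamin projection provides the external
   energy.  The edge map is the Gaussian-smoothed image itself
   (`edge_mode="ridge"`, smoothing sigma 2 px), min-max scaled to [0, 1].
   A bright rim is a *line* feature: the gradient magnitude of a ridge
   peaks ~sigma to either side of the crest, and a snake attracted to it
   systematically undershoots the rim centerline (~2 px on our fixtures);
   using the intensity itself as the edge map — the standard gradient
   vector field (GVF) choice for line-like features — puts the force
   equilibrium on the crest.  `edge_mode="gradient"` (gradient magnitude
   of the smoothed image) remains available for step-edge channels.
3. **GVF.** The edge gradient is diffused by iterating
   `v += dt·(mu·∇²v − |∇f|²·(v − ∇f))` with `mu = 0.2`, `dt = 1`, 80
   iterations, from the raw gradient (so 0 iterations return the gradient
   itself).  The scheme requires `dt·mu ≤ 0.25` for stability and is
   checked.  Diffusion gives the snake a capture range of tens of pixels,
   so the Otsu boundary need only be roughly right.
4. **Snake.** A closed parametric contour evolves for 75 iterations under
   semi-implicit updates: `(A + γI)·p⁺ = γ·p + κ·F(p)`, where `A` is the
   circulant pentadiagonal tension/rigidity matrix (`alpha = 0.05`,
   `beta = 1.0`), `γ = 1` the viscosity, `κ = 2` the external-force weight,
   and `F` the GVF sampled by bilinear interpolation (coordinates clamped
   to the frame with a warning).  Defaults were fixed once against the
   synthetic fixtures.  The contour is resampled to uniform arc length
   every 10 iterations and after the last one, always preserving the point
   count — derivative-based metrics downstream need near-uniform spacing,
   and a fixed count keeps profiles comparable across nuclei.

On the synthetic fixtures with default noise this recovers ground-truth
ellipses to ~0.2 px mean boundary error (~0.4 px Hausdorff).

## The fluctuation index

Given reference and test profiles sampled at the same `n` contour points
(bilinear interpolation; the contour is sub-pixel, so "pixels" are sampled
positions):

1. circular central differences `d[i] = (v[i+1] − v[i−1])/2` (indices mod
   n), each channel's derivative array divided by its maximum absolute
   value;
2. per-position ratios of derivative magnitudes in both directions
   (reference/test and test/reference), then each ratio array min-max
   normalized to [0, 1];
3. the fraction of positions with normalized ratio above the threshold
   (default 0.15), expressed as a percentage per direction, summed.

The index lives in [0, 200].  It is invariant to positive per-channel gain
(normalizations absorb it) and symmetric under swapping the channels
(the two direction fractions swap).

**Degenerate-input rules.**  A constant array min-max- or max-abs-
normalizes to all zeros.  For the ratios: where both derivatives are zero
the ratio is 1 — the continuous limit of equal derivatives; where only the
denominator is zero the position is assigned the maximum finite ratio in
that direction (1.0 if none exists).  These rules make the identity
anchor exact: a test profile identical to the reference gives a constant
ratio array, which the min-max step maps to zeros, hence index exactly 0 —
for *every* profile, including those with flat stretches.  Assigning 0 to
the both-zero case instead would break that identity whenever any
derivative vanishes exactly.

**Noise sensitivity (important limitation).**  The min-max step divides by
the *largest* ratio in the array.  If the reference derivative is pure
noise centered on zero — as it is on the idealized synthetic rim, whose
reference intensity is exactly constant along the boundary — the ratio
array is heavy-tailed (Cauchy-like), its sample maximum is erratic and
large, and the 0.15 threshold lands far above the structural signal.  Both
punctate and uniform nuclei then score low single digits and the group
contrast shrinks to a small median shift that does not survive a strict
rank-sum bound at realistic cohort sizes.  Noise-free, the separation is
clean (index 0 vs ~30 for strong puncta).  On real micrographs the
reference rim has structural intensity variation well above the noise
floor, which keeps the ratio denominators conditioned; the idealized
constant-rim phantom is therefore the metric's worst case, and synthetic
cohort comparisons here understate the metric's contrast on real data.

**Linescans.**  For display parity with annotated micrographs,
`linescan_profile` samples each channel along a user segment and scales it
so its maximum is 100 (an all-zero channel stays zero).

## Synthetic nuclei

Each phantom is a three-channel 2D image on a 0-based pixel-center grid:

- **counterstain**: a filled ellipse (default semi-axes 55 × 40 px in a
  256² frame, interior intensity 100) with a soft edge from the PSF —
  bimodal enough for Otsu, like real DAPI;
- **reference**: a rim of constant along-boundary intensity
  (`rim_amplitude` 120) with Gaussian falloff normal to the boundary
  (`rim_width` sigma 1.5 px).  Per-pixel rim geometry (normal distance and
  nearest boundary angle) comes from a KD-tree over 4096 densely sampled
  boundary points;
- **test**: the same rim modulated along the boundary by
  `b + (1−b)·c·Σ bumps`, peak-normalized, where `b` is
  `baseline_fraction`, `c` is `focus_contrast`, and each bump is a
  wrapped Gaussian of angular sigma `focus_arc_sigma` at a focus angle
  (uniform-random by default, equally spaced on request).  With no foci or
  `b = 1` the test pattern equals the reference pattern exactly.

All channels are blurred by a Gaussian PSF (sigma 1 px), offset by a
background of 10, and corrupted by Poisson photon noise (25 photons per
intensity unit — ~3000 photons at the rim crest, emulating deconvolved
16-bit widefield data) plus Gaussian read noise (sd 0.5).  The noise level
is calibrated so two channels sharing a spatial pattern correlate above
0.99.  Everything is a pure function of the spec, including its seed.

Default punctate nuclei use 8 foci, `focus_arc_sigma` 0.12 rad,
`focus_contrast` 4, `baseline_fraction` 0.35 — chosen once to look like
punctate prelamin A rims; they are free parameters, not estimates of real
foci statistics.  Cohorts jitter center (±12 px), axis scale (0.85–1.15)
and orientation (0–π) per nucleus, with matched pairs across groups
sharing geometry and seed so the groups differ only in punctateness.

What the phantoms deliberately omit: 3D optics, deconvolution artifacts,
chromatic aberration, touching nuclei, intranuclear texture, and —
importantly — along-rim structural variation of the reference channel (see
the noise-sensitivity note above).  Passing tests on phantoms therefore
validate the arithmetic and the segmentation geometry, not the metric's
effect size on real tissue.

## Projections and I/O

Stacks are (channel, z, y, x) float64 arrays with named channel roles;
original dtype is kept for provenance.  Quantification always runs on
maximum-intensity projections; average projections over a physical window
(e.g. 1 µm = 5 slices at 0.2 µm step) are provided for display parity.
TIFFs are written as (C, Z, Y, X) pages with a JSON sidecar carrying the
layout, roles and (for phantoms) ground truth, so round-trips are
bit-identical; 8/16-bit and float TIFFs are accepted.

## Blot densitometry

The immunoblot module consumes measured band signals (not gel images):
each channel is divided by its maximum across samples, the per-sample
ratio prelamin A / (lamin A + prelamin A) is formed *after* that
normalization (the order matters and is asserted by tests), and groups are
compared with a two-tailed Welch t-test.  Replicate structure is taken as
given columns and never inferred.

## Batch pipeline

`run_analysis` maps the stages over TIFF paths or in-memory cohorts,
isolating per-image failures (a batch fails only if every image fails),
and writes one report row per nucleus plus the resolved config.  Group
summaries use a Mann-Whitney U test — a reporting convenience for
distribution-level comparisons, chosen because per-nucleus indices are
bounded and non-normal.  Fixed seed + config ⇒ byte-identical reports.

## Problem sizes

Defaults used throughout the examples and tests: 256² frames, 200 contour
points, 80 GVF iterations, 75 snake iterations, 20-nucleus recovery
studies and 44-per-group cohorts — one nucleus segments and scores in
well under a second on a laptop core.
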