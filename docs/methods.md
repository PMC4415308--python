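# Methods

## Problem and measurement model

The input is a single-view laser-triangulation scan: an organized grid
of 3D points in mm, one RGB color per point, with a nominal grid pitch
(default 0.25 mm, the scale of such devices' stated accuracy). A
single-view scan is a 2.5D height field — z is a graph over (x, y) — and
every quantity below exploits that.

Three quantities describe the wound:

* **Perimeter**: length of the closed wound edge, lifted onto the
  virtual-healthy-skin surface.
* **Area**: area of the virtual-healthy-skin patch enclosed by the
  edge (that is, the area of the skin that would cover the wound, not
  the area of the cavity walls).
* **VDW** (volumetric deviation of the wound): with d = z_measured −
  z_vihs, VDW = V⁺ + |V⁻| where V⁺ integrates max(d, 0) and V⁻
  integrates min(d, 0) over the wound polygon. Absolute values are
  summed so cavity and protrusion cannot cancel.

Deviation is measured along the scan z axis, not along the surface
normal: for a height field this makes the integral a well-defined prism
decomposition. This is a documented limitation for strongly overhanging
healthy skin, which a single-view scanner cannot observe anyway.

Perimeter and area are deliberately evaluated *on* the ViHS instance.
Since 31 instances are averaged, these quantities must depend on the
instance for the averaging to be meaningful; the alternative (area of
the measured surface inside the edge) is not what the ensemble
protocol averages over.

## Wound edge

Segmentation runs on the scan's 2D color image (pixel (r, c) is the
color of grid cell (r, c)). Three back-ends produce a wound mask:

* **Canny pipeline**: operator-chosen channel (R/G/B/gray/hue/sat),
  Gaussian pre-smoothing σ = 1.4 px, hysteresis thresholds,
  morphological closing (disk radius 2 px default), optional manual
  stroke polylines from a JSON file, bridging of residual endpoint gaps
  up to 10 px, then border flood fill; the enclosed interior plus the
  inner half of the Canny ridge is the mask. If nothing closes, the
  caller gets a specific error (add strokes or raise the closing
  radius).
* **GrowCut**: cellular automaton on the 8-neighborhood; neighbor q
  conquers p iff (1 − ‖C_p − C_q‖/d_max)·θ_q > θ_p with d_max = √3·255;
  seeds start at strength θ = 1 and can never be conquered (attack
  strength is strictly below 1). Runs to a fixed point; the sweep is
  fully vectorized, so convergence on a 280² image takes well under a
  second.
* **GrabCut-style**: iterated 5-component full-covariance Gaussian
  mixtures for wound and background colors, alternated with a min-cut
  labeling (Boykov–Jolly graph: contrast-adaptive 8-neighbor n-links
  with β = 1/(2·E‖ΔC‖²), γ = 50; seed pixels get infinite t-links). The
  min cut is computed with an integer max-flow on a sparse graph and
  the source-side partition read off the residual network. Mixture
  initialization is seeded from the configuration, so reruns are
  bit-identical.

After every back-end the largest 4-connected component is kept, holes
are filled, and foreground on invalid cells is discarded. Interior
"healthy islands" are therefore counted as wound; this mirrors tracing
a single outer contour and is the documented convention.

Two edge representations exist on purpose:

* `mask_to_edge` — the classic Moore-neighbor clockwise trace: integer
  vertices, consecutive vertices 8-neighbors. Used for round-tripping
  and export.
* `trace_edge_subpixel` — the measurement edge: marching-squares
  contour at level 0.5 (the mid-crack boundary, unbiased in position
  for digitized smooth shapes), resampled to uniform arc length and
  smoothed with a periodic 3 px moving average. An 8-connected digital
  contour overestimates the length of a smooth curve by several
  percent; the smoothed mid-crack contour brings perimeter error below
  ~0.5 % at 0.25 mm pitch while shifting the area by O(10⁻⁴). The
  3 px window is small enough that genuine edge indentation at the mm
  scale survives.

## Virtual healthy skin

**Anchoring.** The minimal-area enclosing rectangle of the edge's xy
points (exact hull-edge enumeration; one side of the optimum is
collinear with a convex-hull edge) fixes the four anchor vertices. The
rectangle's orientation is deterministic (long axis reported in
[0°, 180°)), which keeps the ViHS orientation consistent across visits
to the same wound.

**Ensemble.** Each vertex is displaced independently and uniformly in a
square of side 5 mm aligned with the rectangle's own axes (axis-aligned
scatter keeps the geometry consistent under wound rotation);
self-intersecting quads are redrawn. One initial + 30 scattered
instances = 31. All randomness flows from one master seed.

**Surface form.** Non-rational tensor-product cubic B-spline (all
weights 1), 8 × 8 control net, open-uniform knots. Unit weights keep
the fit linear; an 8 × 8 cubic net resolves skin shapes with curvature
radii ≥ 30 mm to well under 0.1 mm over a 30–40 mm quad.

**Fit.** Three stages per instance:

1. *Boundary curves*: the measured surface is sampled every 0.5 mm
   along each quad edge through an inverse-distance-weighted lookup
   restricted to valid, non-wound cells (radius 3 pitches);
   wound-covered spans are linearly interpolated in arc length from
   flanking healthy samples; an entirely wound-covered edge raises an
   under-constrained error. Each edge becomes a least-squares cubic
   B-spline with clamped endpoints at the (healthy-sampled) corners.
2. *Coons patch*: the interior control net is the discrete Coons blend
   of the four boundary control polygons (Greville-weighted). A Coons
   patch is exact for any surface of the form f(u) + g(v), so a
   cylindrical leg is already represented well before refinement.
3. *Penalized least squares*: control-point z (all except the four
   corners) is refined against healthy cells inside the quad,
   minimizing ‖residual‖²/N + λ·‖Δ²(z − z_coons)‖²/T with second
   differences along both net axes plus a mixed term. Two choices
   matter and were made deliberately:
   * The penalty acts on the *correction to the Coons patch*, not on
     the surface itself. Where no data exists (the wound interior) the
     penalty-minimizing correction is zero, so the surface stays on
     the Coons patch instead of being flattened toward zero curvature —
     penalizing absolute curvature would bias a cylindrical leg upward
     under the wound.
   * Edge (non-corner) control points are refined too. They are first
     estimated from a thin 1D line of samples and therefore carry
     correlated sensor noise of order σ/2; the 2D data band inside the
     quad corrects them, while the correction penalty keeps unsupported
     spans (where the quad edge touches the wound) on the boundary
     curves.

   λ defaults to 0.02, set so that a noise-only fit (plane + σ = 0.1 mm
   noise) leaves a residual below the noise floor while a 50 mm
   cylinder under a 10 mm wound is reconstructed to < 0.03 mm RMS;
   the bias experiment is insensitive to λ across 0.01–0.2. With fewer
   than 50 healthy interior samples the refinement is skipped and the
   Coons patch stands.

The spline is evaluated by polynomial extension in a thin collar
(0.2 parameter units beyond [0, 1]²). The initial rectangle is tangent
to the wound edge, so an inward-scattered vertex would otherwise
truncate the wound domain and clip area and volume by several percent
per instance; the collar (2.5 mm scatter ≈ 0.08 parameter units) makes
truncation impossible at the default settings.

## Integration

Per instance, a regular xy grid at step h (default 0.25 mm, matching
the device scale; configurable) covers the union of quad and edge.
ViHS z and slopes come from vectorized Newton inversion of the spline's
(u, v) → (x, y) map (affine initial guess from the quad corners,
tolerance 10⁻⁶ mm; divergence on more than 1 % of mandatory cells
aborts the instance). Measured z is bilinear interpolation of the
organized grid; in-wound cells are decided by point-in-polygon against
the measurement edge. V⁺/V⁻ are cell sums of d·h²; the area element is
h²·√(1 + z_x² + z_y²) from the spline slopes; the perimeter densifies
the edge to ≤ h spacing before lifting. Halving h changes VDW by less
than 0.5 % on all generator wounds.

Summary statistics use the sample (n−1) standard deviation, matching a
repeatability-as-one-standard-deviation convention, and the summary is
exactly recomputable from the stored per-instance triples.
`repeatability_stats` wraps Levene's test and the one-way
Kruskal–Wallis test (95 % confidence convention); an all-ties input
reports p = 1 rather than an error.

## Synthetic scans and ground truth

The generator emulates a lower-leg scan: a cylinder section (radius
90–250 mm) plus optional low-amplitude sinusoidal undulation plus
per-point Gaussian range noise (default σ = 0.05 mm, a realistic
triangulation noise floor well below the 0.25 mm systematic accuracy of
such hardware), colored with skin / wound-tissue textures blended over
a blurred rim. The wound is an elliptical cavity with either a
cosine-taper wall (smooth, zero-slope rim) or a normalized
super-Gaussian profile (steep wall, flat bottom); the depth reaches
zero exactly on the ellipse, so the true mask is the exact ellipse
rasterization. Wounded and healthy surfaces share the same noise
realization and are bitwise identical outside the ellipse.

Ground truth is computed by an independent brute-force oracle on the
*noise-free* analytic base (dense grid at pitch/8 with 4 × 4
subsampled boundary-cell coverage; perimeter from a dense lifted
ellipse polyline; area with central-difference metric factors). The
oracle shares no integration code with the measurement path — agreement
between the two is evidence, not circularity — and refining its grid
2× changes each value by < 0.2 %. Because truth lives on the noise-free
base while the analysis sees the noisy surface, measured-vs-expected
differences include a realistic noise contribution.

The standard verification suite holds three shape families — shallow
and flat on a near-planar base, deep and steep-walled on a 90 mm
cylinder, and a tilted elongated ellipse on an undulating base — each
as a larger "before" and smaller "after" wound (simulated healing).
Depths span 3–6 mm and cavity volumes roughly 800–2200 mm³.

What passing the bias experiment does *not* show: the synthetic wounds
are smooth analytic shapes with a well-defined edge and a
high-contrast texture; real wounds add blurred and debatable edges,
specular and occluded scan regions, deformed surrounding skin, and
operator variability in seeding — none of which the generator models.
The suite bounds the bias of the *analysis procedure*, not of a whole
clinical measurement.

## Numerical details and degenerate inputs

* Invalid cells: NaN coordinates internally; sentinel code 0 in 16-bit
  depth files; black + flagged in the color image.
* PLY: our writer emits full-precision ASCII with grid metadata in
  header comments, so organized surfaces round-trip exactly; foreign
  colored clouds are accepted (ASCII or binary) and resampled by
  inverse-distance weighting within 2 pitches, with exact-hit
  passthrough so regular grids reproduce identically. Colinear or
  coincident clouds are rejected.
* Rectangle ties in the hull-edge enumeration are broken by a 10⁻¹²
  area tolerance toward the first hull edge, making the orientation
  deterministic.
* A single-pixel mask, an empty seed class, a non-enclosing Canny map,
  an all-wound quad edge, and an off-quad wound polygon each raise a
  dedicated exception; the CLI maps every exception class to a
  distinct nonzero exit code.
* Instance failures during the ensemble are dropped with a recorded
  warning; if fewer than half survive the analysis aborts.

## Default problem sizes

Unit tests run on 0.5 mm-pitch surfaces (~90 × 80 cells) to stay fast;
the bias suite and the acceptance script use the full 0.25 mm device
pitch (~230 × 260 cells per wound, 31 spline fits and deviation fields
each), which completes in well under a minute per wound on one core.
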