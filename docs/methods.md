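# Methods

## Data model

A **morphomovie** is an ordered sequence of 2D triangle meshes
`t = 0 … T−1` (one per developmental hour) describing a growing tissue
domain, with optional fine substep frames inside each hour (default 10
developmental minutes per substep) and a remesh at every hour boundary that
restores a uniform element size. Coordinates are Cartesian, y-up, in
arbitrary but movie-consistent units; only relative geometry matters.
Meshes are stored as ASCII OFF (PLY accepted on input, z dropped) plus a
JSON manifest; triangle winding is normalised to counter-clockwise on load,
and degenerate (area ≤ 1e−14) triangles are rejected.

The substeps matter for one thing beyond rendering: the *last* substep frame
of hour `t` and the fresh mesh of hour `t+1` describe the same domain
instant (their areas must agree within 2%), and it is in this common frame
that lineage overlaps are computed. Without substeps the hourly mesh itself
is used, at the cost of a growth-sized outline mismatch (a warning is
emitted above 2%).

## Lineage and tracks

For each hour boundary, every pair of bounding-box-intersecting triangles
(STR-tree index; shapely polygon clipping) contributes an edge weighted by
overlap area; overlaps below 1e−12 × the mean triangle area are discarded as
clipping slivers. The exposed `triangle_overlap_area` primitive implements
Sutherland–Hodgman clipping directly — the intersection of two convex
polygons is convex, so its shoelace area is exact up to rounding — and is
cross-checked in the tests against shapely and a Monte-Carlo estimate.

Track extraction is deterministic and two-phased. Phase 1 walks backwards
from every final-hour triangle, at each boundary taking the predecessor with
maximal overlap; exact ties go to the lowest triangle index. Phase 2 scans
hours ascending, then triangle indices ascending, and completes every
still-uncovered triangle into a full-span track backwards *and* forwards by
the same argmax rule (the forward rule mirrors the backward one; the scan
repeats until coverage is total, which a single ordered pass achieves since
every seed covers itself). Tracks are many-to-many: early triangles are
shared by many tracks because the domain grows; this is intended — the
tracks approximate average tissue motion, not a cell-level fate map.

## Digitization

A staged image is a grayscale raster in [0, 1] with an hour assignment, a
polarity flag, and an affine transform from pixel centers (row-down) to mesh
coordinates; registration itself is assumed done upstream. Each triangle
receives the mean of the pixel intensities whose centers fall inside it
(point-in-triangle by matplotlib's trapezoid-map finder); triangles too
small to contain a pixel center fall back to a bilinear sample at their
centroid, and triangles entirely outside the raster get 0 with a warning.
Internally 1 always means high expression: `high_is_dark` images
(e.g. BCIP/NBT chromogenic stains, where published display conventions are
inconsistent) are inverted on entry, and renderers may invert for display.

## Temporal B-spline

Expression along one track is sampled once per (image, hour) pair; multiple
images at one hour are averaged. The per-hour means, in time order, are the
control points of a **uniform cubic B-spline curve in the (hour, intensity)
plane**. Each curve section is shaped by its four neighbouring control
points, so control is local and the curve is C² — the rate of expression
change never jumps. Reflected phantom endpoints (`P₋₁ = 2P₀ − P₁`) make the
curve interpolate the first and last means while preserving the exact
reproduction of constant and collinear data (collinear control points of a
parametric B-spline trace the exact line for any parameterisation). Interior
means are control points in the classical sense: the curve is attracted to,
but not forced through, them — a deliberate mild temporal smoothing of
per-hour intensity fluctuations, and the property that makes the bootstrap
(below) act at all. At least 4 distinct sampled hours are required.

Evaluation at an arbitrary hour inverts the monotone hour component of the
curve (dense piecewise-linear initial guess, six Newton iterations, accurate
to ~1e−12). Outside the sampled span the value is clamped to the nearest
endpoint mean — conservative, and avoids cubic blow-up. All outputs are
clipped to [0, 1].

Reassembly evaluates every track's spline at every hour and averages tracks
sharing a triangle. Because all tracks of one dataset share the same sampled
hours, the parameter inversion and basis weights are computed once and the
whole assembly collapses to a matrix product; the per-track path
(`fit_track_spline` + `assemble_reconstruction`) is retained as the
reference API and tested for agreement.

## Histogram matching and the bootstrap

Matching uses B = 256 equal-width bins on [0, 1] (8-bit convention) and the
textbook CDF rule: source bin `z` maps to the smallest reference bin `z'`
with `CDF_r(z') ≥ CDF_s(z)`; the mapping is monotone by construction and is
applied to binned triangle values. The achievable CDF agreement is limited
by the largest single-bin mass of the distributions involved (the bound
`max(source, reference) bin mass + 1/B` is asserted in the tests).
Matching operates on digitized triangle fields, not raw pixels: the
reconstruction that serves as reference only exists as triangle fields.
Histograms are unweighted by triangle area, since remeshing keeps element
sizes roughly constant.

One **bootstrap cycle** (the default) builds a first reconstruction R0 from
the raw fields, matches each raw field against R0's field at its hour
(a uniform reference field degenerates to a constant mapping — allowed, with
a warning), and rebuilds the reconstruction from the matched fields.

Honesty about what this can and cannot do: if every image differs from a
common underlying pattern only by a monotone intensity distortion (a global
gain and offset), histogram matching is rank-preserving and maps each raw
field onto R0's field at its hour, up to binning — the tests pin this
collapse. The refined reconstruction then differs from R0 only by a second
pass of temporal smoothing, which evens out per-image intensity scales
across hours but cannot repair the shared bias and slightly blurs fast
pattern dynamics. The bootstrap earns its keep on data whose images carry
*rank-breaking* differences — specimen-to-specimen pattern variation and
local artifacts — which is exactly the situation in real staged-image
datasets; the acceptance script reports the before/after comparison under
the purely monotone synthetic corruption without editorialising.

## Reconstruction accuracy

The comparison of a reconstruction R against a reference field D fits the
piecewise-linear intensity transform

    g(D) = x + (y − x) · (D − D_min) / (D_max − D_min),   clipped outside
           [D_min, D_max],   with (D_min, D_max) the observed range of D,

minimising `f(x, y) = Σᵢ (Rᵢ − g(Dᵢ))²` over `(x, y) ∈ [0, 1]²`. The
objective is linear in (x, y), so the fit is seeded at the closed-form
least-squares solution projected into the box and polished with L-BFGS-B;
a 101×101 grid search serves as the optimality oracle in tests. A constant
reference degenerates to fitting the intercept alone (x = y, with warning).
Squared differences are used throughout. Residual curves evaluate one fitted
SSD per reference field, averaging multiple references at one hour;
`normalize=False` gives the plain SSD instead.

The **subset experiment** measures reconstruction error as a function of the
number of input images k: the subset always contains the youngest and oldest
image, two random intermediate frames at further distinct hours (so the
B-spline's four-timepoint minimum is met), and random extras up to k;
n_controls (default 5, matching the evaluation protocol above) control
images are drawn from the excluded remainder and scored by fitted SSD.
Everything is reproducible from the seed.

## Synthetic data

The generator emulates the study conditions end to end:

- **Outline**: a half-ellipse on the x-axis with a distally elongating bulge,
  expressed in polar form r(θ, t) about the origin — star-shaped, so a purely
  radial map carries domain points exactly onto any other hour's outline.
  The scale factor is chosen per hour so the outline area compounds at
  `area_growth_per_hour` (default 6%/h, a brisk but realistic organ-bud
  growth rate); the bulge amplitude ramps from 0.15 to 0.6 over the movie.
- **Meshing**: boundary points by arc length (0.75 × target edge, so the
  polygon hugs the curve), interior points on a seeded, jittered hexagonal
  lattice, scipy Delaunay, clipped to the outline by centroid membership.
  The default target edge (0.16 units) yields meshes of a few hundred
  triangles — large enough for spatial structure, small enough that the full
  test suite runs in well under a minute per dataset.
- **Substeps** (default 6 per hour): linear interpolation of each vertex
  toward its radial image on the next hour's outline; the final frame lands
  on that outline exactly, so hour boundaries tile a common domain.
- **Patterns**, in bounding-box-normalised coordinates: `simple_front` is a
  sigmoid front (steepness 0.08) sweeping the domain over the movie;
  `complex_stripes` is a central domain that splits smoothly (C¹ smoothstep
  in time) into 3 stripes (width 0.09, spacing 0.28) after a quarter of the
  movie — Dusp6-like vs Sox9-like in spirit. Per-triangle ground truth is
  the pattern averaged over each triangle (6-point degree-4 quadrature),
  matching the semantics of digitization.
- **Images**: the pattern rasterised over the mesh (default 300 px wide,
  ~100 px per triangle), background 0, with the exact affine registration
  attached; corruption applies a per-image gain (default U(0.6, 1.0)) and
  offset (U(0, 0.2)) plus additive pixel noise (sd 0.02) and clips to [0, 1].

What the generator does **not** emulate — and what passing tests therefore do
not show about real data: specimen-to-specimen pattern variability, staging
error (the assigned hour is exact here), registration error (the affine is
exact), spatially structured artifacts, and anisotropic or
clone-data-derived tissue flow. The radial growth map is smooth and
star-shaped; real limb tissue flow is not radial.

## Numerical choices

- Overlap sliver threshold 1e−12 × mean triangle area; lineage tie-breaks to
  the lowest index everywhere, making the whole pipeline deterministic.
- Outline handover tolerance 2% of area (validation), conservation of
  overlap mass holds to 1% on generated movies (tested).
- Histogram bins B = 256; matched values land on bin centers, so a single
  matching costs at most 1/(2B) quantization per value.
- Spline parameter inversion: 8 samples per section for the initial guess,
  6 Newton steps with the derivative floored at 1e−12.
- Transform fit: closed-form seed, box constraints [0, 1]², analytic
  gradient.
- All randomness flows through explicit integer seeds
  (`numpy.random.default_rng`); rerunning any stage with the same config and
  seed reproduces outputs bit-for-bit (tested).

## Known limitations

- Strictly 2D; no volumetric generalisation.
- No spatial smoothing across neighbouring triangles — interpolation is
  purely temporal by design, so single-triangle digitization noise survives
  into the reconstruction (the bootstrap mitigates scale, not shape, noise).
- Images must arrive registered to mesh coordinates; no staging or
  elastic registration is provided.
- Tracks are argmax paths, not probabilistic assignments; no uncertainty is
  propagated.
- The subset experiment requires ≥ 4 distinct imaged hours, so reconstructions
  from 3 images are out of reach by construction.
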