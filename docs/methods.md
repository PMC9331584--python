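# Methods

## Measurement model

All measurements operate on per-view raster masks with the ear oriented
vertically: raster row 0 is the image top, the ear base is at the maximum
row, and every profile is reported bottom -> top.  Pixel units are
converted once through the pixel scale (px/cm), which is a required input
(the generator records its own; real acquisitions must be calibrated).

**Central axis and length.**  Per silhouette row the centre is the
midpoint of the leftmost/rightmost contour pixels (rows with interior
holes use the outermost extent — silhouette semantics).  Ear length is
`1 + sum of Euclidean steps` between consecutive row centres, so a
one-row mask has length 1 px and a straight rectangle of `n` rows has
length exactly `n`.  Euclidean (not chessboard) path length was chosen;
for rasterized curved centrelines the contour midpoint staircases at
half-pixel resolution and a naive step sum systematically overestimates
the curve length, so the centre sequence is regularized by a 9-row
truncated running mean before the path is measured.  This leaves straight
ears untouched and brings a sinusoidally bowed ear within ~0.3% of the
analytic arc length (the unsmoothed error is ~+5%).

**Arc correction.**  A horizontal distance on the image is a chord of the
ear's circular cross-section.  With signed offsets `x1, x2` (cm) from the
central axis at the grain's row and radius `R = Diameter_i/2`, the arc is
`R |asin(x2/R) - asin(x1/R)|`, offsets clamped to the limb.  The signed
formulation is the only one consistent for grains straddling the
centreline.  Grain rectangles are axis-aligned (height along the ear
axis), and the chord endpoints are the outer pixel edges of the bounding
box, matching the `right - left + 1` convention of the diameter.

**Cohort assignment.**  Iterative bottom-up grouping with window = 0.5 x
mean grain bbox width (px), window boundary inclusive, seeded at the
lowest unassigned barycentre ("lowest grain" = lowest centroid, not
lowest bbox edge).  The window factor is configurable.

**Counting profiles.**  Horizontal 1-px segments (bbox horizontal extent
at the barycentre row) counted per column give the cohort-count profile;
its maximum is the per-view cohort count, and the per-ear cohort number
is the mean of the six per-view maxima.  Vertical 1-px segments (bbox
vertical extent at the barycentre column) give, per row, the crossing
columns whose consecutive arc-corrected gaps average to `Dist_i`; the
grains-per-cohort estimate is `pi * Diameter_i / Dist_i`, undefined below
two crossings.  The wrap-around gap is excluded (only the visible side
carries grains; the ratio extrapolates to the full circle).  Two
refinements stabilize the estimate:

* crossings farther from the centreline than `sin(capture_arc/2) * R`
  (default capture arc 120°, i.e. beyond ±60°) are discarded — there the
  chord-to-arc inversion is ill-conditioned;
* a grain's barycentre is the midpoint of its projected chord, which for
  a grain of width `w` wrapped on a cylinder sits at
  `R sin(theta) cos(w/2R)` — compressed towards the centreline by the
  known factor `cos(w/2R)`.  Offsets are divided by this factor (using
  the mean measured grain width) before arc correction, removing a ~3–4%
  overestimation of grains per cohort.

**Grain number per ear.**  Per view, the over-estimator is the mean
defined grains-per-cohort over the median third of ear rows times the
maximum cohort count; the under-estimator sums, over the basal, median
and apical thirds, the zone's mean grains-per-cohort times the zone's
mean per-column crossing count (over columns crossed at least once; a
barren zone contributes 0).  The exact under-estimator composition is not
uniquely determined by its verbal definition, so it is a configurable
strategy (`zonal`, default, or `global` = whole-profile mean x whole-view
mean crossing count).  The view value is the mean of the two estimators
and the ear value the mean over views.

**GSR and zones.**  Raw GSR per ear row = grain pixels / contour width;
grain pixels outside the silhouette are still counted but flagged as a
registration fault.  Smoothing is a centred running mean over
`max(1, round(0.02 x ear rows))` rows, truncated and renormalized at the
profile ends (no reflected data is invented).  The fertile zone is the
*envelope* from the first to the last row with smoothed GSR strictly
above 0.5 — the ear is modelled as one fertile span flanked by basal and
apical aborted zones, so interior dips (inter-cohort furrows) stay
inside it.  Zone lengths are row fractions of the measured ear length and
therefore partition it exactly; when no row crosses the threshold the
fertile length is 0 and each aborted zone takes half the ear length.
Zones are measured per view and then averaged (the alternative —
averaging profiles first — is available by composing the same functions).

**Clustering.**  Smoothed profiles are interpolated onto 100 equally
spaced relative positions (0 = base, 1 = apex; the grid size is a free
choice, configurable) and averaged over views.  Ward agglomeration on
Euclidean distances is the default backend with the tree cut at k; seeded
k-means is the alternative — the two are reconciled by relabelling
clusters 1..k by decreasing mean-profile integral, so cluster 1 is always
the least aborted regardless of backend label arbitrariness.  Rows are
processed in ear-id order, making the result independent of input order.
Summaries report P(cluster | treatment) per treatment group (each sums
to 1), mean ± sd ear length per cluster, and a one-way ANOVA (F, p) of
length across clusters (NaN below two occupied clusters).

## Acquisition geometry

No-slip rolling contact gives an ear rotation of
`roller_step x roller_diameter / ear_diameter` per image; view k is
centred at cumulative rotation `k x step` with the first image taken
before any rotation.  Coverage is the measure of the union of closed
arcs of width `view_arc` at those centres, computed analytically by
interval merging after modular normalization — exact, with no raster
resolution artefact (a 36,000-bin discretization serves as the test
oracle).  `view_arc = 360` trivially yields 100%.  Roller slip and
rubber compliance are not modelled.

## Synthetic ear generator

The generator is the package's study-condition definition, not a
visually realistic renderer.  Grains sit on a cylinder at `n_cohorts`
heights (pitch = length / n_cohorts) x `grains_per_cohort` angular files;
files are angularly aligned across cohorts, as true maize rows are — this
alignment is what makes the maximum-crossing cohort count exact.
Defaults emulate a densely set dent ear: 12 cm x 4 cm, 24 cohorts x 14
files, grains 0.85 x 0.46 cm (nearly touching: the chord pitch at 4 cm
diameter and 14 files is 0.89 cm), 40 px/cm.  Diameter profiles:
cylinder, tapered (linear to 65% at the apex) or barrel (sine bulge, 75%
at the ends); an optional sinusoidal centreline bow of given amplitude
is rendered identically in every view (a 3D bow would project
view-dependently; ground-truth length is the analytic arc length of the
bowed centreline).

**Rendering.**  Each view is an exact orthographic projection of the
cylinder: a grain at angular distance `dtheta` from the view axis spans
the chord `[R sin(dtheta - w/2R), R sin(dtheta + w/2R)]` and is drawn as
a filled ellipse over that span and its height — so the arc correction
inverts the rendering by construction, and grain width recovery is exact
up to rasterization.  All grains on the camera-facing hemisphere are
drawn (configurable `render_arc`, default 180°), as in a real photograph;
the 120° `view_arc` of the acquisition plan is the *reliably captured*
arc used by the coverage model and by the measurement-side limb cutoffs.
A 1-px gap between neighbouring labels is enforced (pixel rounding at
the limb is shrunk silently; a genuine overlap — spec width exceeding
the arc pitch, e.g. under strong taper — shrinks with a warning).
Labels are global grain ids, so grains can be matched across views and
against the ground-truth table.  Pseudo-IR is flat bright on grains and
dim on cob; pseudo-RGB adds deterministic per-grain colour jitter.  Both
exist only to feed the baseline segmenter.

**Abortion models.**  `none`, `apical`, `apical_basal`, `full`,
`scattered`.  Graded models set the per-cohort set probability by a
logistic edge across the stated boundary fraction, with a 10–90% span of
2 cohorts (the gradient shape is a modelling choice; no quantitative
shape is established for real ears).  Within a cohort the number set is
the rounded expectation `round(K p)` — not i.i.d. Bernoulli — and the
set files are spaced evenly around the ring at a random rotation.  This
variance reduction keeps the planted fertile boundary well defined at
single-ear scale and makes each view representative of a partially
aborted cohort; the scattered model (pollination failure) remains fully
Bernoulli per grain.  Archetypes 1–5 fix (apical, basal) aborted
fractions at (0.05, 0), (0.30, 0), (0.30, 0.10), (0.45, 0.20) and full
abortion, giving monotonically decreasing fertile fractions 0.95, 0.70,
0.60, 0.35, 0.

**Ground truth.**  Per grain: cohort, file, angle, height, set flag.  Per
ear: true length, diameter profile, zone extents, set counts per third,
and two GSR truths: a per-raster-row, band-resolved profile (angular
coverage of set grains including the elliptical vertical footprint — what
the measured raw profile approximates, agreement ~0.01 mean absolute) and
a cohort-envelope curve on the normalized grid (nearest-cohort coverage,
gaps filled — what smoothed, length-normalized profiles approximate; used
for clustering tests).  For the scattered model zone extents are nominal
(whole ear fertile if set probability > 0.5, else the degenerate rule).

## What the generator does and does not emulate

It emulates the lattice geometry, projection and foreshortening, graded
and scattered abortion, multi-view acquisition, and instance-mask
semantics.  It does not emulate photometric variability, husk/silk/fungus
debris, irregular grain shapes, segmentation errors, or cohort
misalignment (spiral ears).  Passing the ground-truth recovery suite
therefore validates the measurement algorithms and their geometric
corrections, not robustness to real segmentation noise — the latter is
bounded separately by the baseline segmenter tests, which feed the
pipeline from rendered images rather than perfect masks.

## Baseline segmentation

A deliberately simple stand-in so the pipeline runs from images: merge
IR and RGB luminance (IR-weighted, weight 0.6, configurable), restrict to
the reliably captured 120° window of the silhouette, threshold by Otsu
over ear pixels, split touching grains by watershed on the distance
transform with seed separation of half the expected grain width
(estimated from the median connected component if not given).  It is one
possible source of label masks, not a reference segmenter; downstream
modules accept masks from any source.

## Problem sizes and numerical choices

Default rasters are ~480 x 170 px per view (40 px/cm); the ground-truth
recovery panel uses 50 ears x 6 views and runs in well under a minute on
one CPU.  Clustering tests use 50 profile curves with i.i.d. N(0, 0.05)
noise.  All randomness flows through explicit integer seeds
(`numpy.random.default_rng`); reruns of the full pipeline under a fixed
configuration are byte-identical, and test oracles (binned coverage,
polygonal arc length, naive running mean, exhaustive crossing counts)
are implemented independently of the code paths they check.

## Known limitations

* The under-estimator composition is one reading of a verbally defined
  procedure; both implemented strategies agree on regular ears but can
  diverge on scattered ones.
* The cohort-envelope fertile-zone rule cannot represent ears with two
  genuinely separate fertile zones.
* Near-limb grains (beyond ±60°) are measured but flagged; their widths
  are unreliable and they are excluded from gap statistics.
* The grain-number over-estimator counts partially aborted cohorts at
  full strength and overshoots on heavily aborted ears; the composite
  stays within 10% of truth across archetypes 1–4 but is biased high
  (~+3%).
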