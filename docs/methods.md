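# Methods

## The recognition problem and the model

A harvesting robot with an eye-in-hand depth camera must find citrus fruit
at close range (roughly 160–700 mm), where a frame contains a handful of
fruits, leaves and branch segments in front of a distant background. The
depth camera reports, per pixel, the perpendicular distance to its focal
plane; converting a pixel's depth `z` through its viewing angles gives a 3D
point at radial distance `r = sqrt(x² + y² + z²)` from the focal-plane
center.

The core idea is purely geometric. Cutting the scene with a *depth sphere*
— the set of points at a fixed radial distance `RC` — intersects a
spherical fruit along a closed, nearly circular curve, but intersects a
leaf (locally a plane) along an open arc, and a thin branch along a short
sliver. No colour, texture or training data is involved.

For an ideal fruit sphere of radius `R` whose closest point sits at radial
distance `RA`, a cut at `RC = RA + L` (cutting depth `L`, mm into the
surface) crosses the fruit on a plane at chord offset

    b = (2R² + 2·RA·(R − L) − L²) / (2·(RA + R))

from the fruit center, along a circle of radius `RC' = sqrt(R² − b²)`
(so `b² + RC'² = R²` identically, and `b = R` at `L = 0`). The cutting
depth obeys the closed form
`L = RC − sqrt(RC² − RC'²) + R − sqrt(R² − RC'²)`, which the test suite
inverts to 1 nanometre over random geometry.

The expected number of depth pixels on the intersection circle is its
angular circumference times the coarser pixel density, derated by a safety
factor `ka ∈ (0, 1]` absorbing shape error and peel roughness:

    N1 = 2·ka·π·(RC'/RC)·min(m/θ₀, n/φ₀),

with `m×n` the resolution and `θ₀×φ₀` the field of view. `ka = 0.8` is the
default. Per-variety cutting depths (3–6 mm) and measured polar/equatorial
diameters for six citrus varieties ship as a built-in table; where the
geometry needs a single radius, a spheroid is reduced to `(Dp + De)/4`.

## Pipeline

Per frame: depth window (160–700 mm, which removes background walls and
near clutter) → point cloud → clustering → branch filter →
isolated/adherent split → depth-sphere cutting → double-threshold
classification of curve regions → merging → detections. Choices the
sources leave open were resolved as follows.

**Clustering.** Connected components under "8-neighbour pixels AND
|Δr| ≤ 10 mm". Deterministic, linear in the pixel count, and equal (by
test) to a quadratic union-find over all point pairs.

**Branch filter.** An aggregate whose pixel footprint has an
ellipse-equivalent minor-axis length under 6 px and an axis ratio above 4
is a branch-like line and is discarded. Thicker branch segments survive to
the cut stage, where their slivers fail the double threshold instead.

**Isolated/adherent split.** A fixed point-count threshold `N0` cannot
separate one-object from multi-object aggregates across the whole depth
window: a two-fruit clump at 520 mm has fewer points than one fruit at
350 mm. The default split is therefore range-adaptive: an aggregate is
adherent when its count exceeds 1.2× the projected pixel footprint of the
largest configured-variety fruit at the aggregate's own closest distance,
or when its depth extent (98th–2nd percentile of `r`) exceeds 1.5× that
fruit's radius — either way it cannot be a single fruit. A fixed `N0` can
still be configured and then applies verbatim (isolated `< N0`, adherent
`≥ N0`).

**Cut anchoring.** Cuts are anchored at a noise-robust closest point: the
minimum of 3×3-median-filtered radial distances. The raw minimum over
thousands of noisy pixels is biased low by about three noise standard
deviations, which both mis-anchors the schedule and turns grazing cuts of
gently curved leaves into broad shallow bands. On noise-free data the
robust anchor agrees with the exact closest point to within the surface
curvature across one pixel.

**Cut schedule.** Isolated aggregates get one cut at the variety's cutting
depth; if it yields no candidate the cut is deepened by 2 and then 4 mm (a
deeper cut produces a larger, better-populated circle). Adherent
aggregates get successive cuts from 2 mm upward in 2 mm steps through the
aggregate's whole depth extent, so cuts reach fruits behind the clump's
closest object. Shell half-width is 1.5 mm (~1.5× the depth-noise SD);
points with `|r − RC| ≤ w` form the shell.

**Classification.** Shell pixels are decomposed into 8-connected regions.
Each region carries its pixel count `AN` and eccentricity `E` — from the
eigenvalues of the second-central-moment matrix, 0 for a circle, 1 for a
line. For classification the moments are taken in angular coordinates
(pixel indices scaled by the per-axis pixels-per-radian); otherwise the
unequal horizontal/vertical densities of the 640×480 preset give even a
perfect circle `E ≈ 0.37` and destroy the fruit/leaf separation. A region
is a fruit candidate iff `E ≤ E0` and `AN ≥ AN0`. The pipeline adds a
size-consistency ceiling: a candidate whose `AN` exceeds 1.5× the modelled
shell-ring pixel count of the largest configured fruit at its range is a
leaf band, not a fruit ring, and is dropped. Aggregates shallower than
0.6× the smallest configured fruit radius are vetoed outright — a sphere
is at least one radius deep from pole to limb; only grazing leaf patches
are that shallow.

**Localization and merging.** A curve's raw 3D center (mean of member
points) sits on the cut plane, `b` millimetres in front of the fruit
center; the pipeline pushes it outward along its viewing ray by `b`
(computed for the nominal variety radius) to report the fruit center
itself. Curves whose implied centers fall within the merge radius (0.8×
the smallest variety's mean radius, ≈19.6 mm) are single-linkage grouped
into one detection at the count-weighted mean.

**Threshold calibration.** `calibrate_thresholds` renders a labelled
training set — all six varieties at five depths spanning the window, two
poses each (60 fruits), 40 leaves, branches — cuts each object at its
closest point, and sets `E0` to the midpoint between the 95th percentile
of fruit-curve eccentricities and the 5th percentile of leaf-curve
eccentricities, `AN0` to half the smallest observed fruit count, and `N0`
to 1.2× the largest single-fruit cloud. With the default generator it
lands near `E0 ≈ 0.78`, `AN0 ≈ 110`. All campaign replicas run with one
calibrated parameter set.

**Scoring.** Detections are matched to true fruit centers greedily
(nearest pair first, one-to-one) within the fruit's own mean radius.
Matched fruit = success; unmatched fruit = miss-recognition; unmatched
detection = misrecognition. Leaf-only scenes count as correct when no
detection is emitted. The one-fruit-one-leaf campaign additionally
requires zero spurious detections for a scene to count, per its design.

## The synthetic canopy generator

The generator replaces the physical camera. The virtual sensor is a
640×480 angular grid with a 73°×59° field of view (the optics are not part
of the published range/resolution sheet, so they are preset configuration,
not results), valid range 160–1200 mm, additive Gaussian depth noise of
1 mm SD and 1% pixel dropout. Primitives are rendered by exact analytic
ray casting with a z-buffer:

* **fruits** — spheroids (quadric–ray intersection) with polar diameter
  `Dp` along a random axis and equatorial diameter `De`; diameters drawn
  uniformly within each variety's measured bounds, constrained to the
  variety's measured `Dp/De` spread (independent draws would produce
  shapes outside every measured specimen, whose cut curves are genuinely
  leaf-like);
* **leaves** — elliptical patches bent onto a cylinder along the midrib
  (flat at zero curl), semi-minor 0.35–0.6 of semi-major (lanceolate
  blades), tilt distributed uniformly over the spherical cap within 60° of
  frontal, curling toward or away from the sensor with equal probability;
* **branches** — thin finite cylinders;
* optionally a constant-depth backdrop wall beyond the close-shot window.

Ground truth per scene: class and object-id label images from the
noise-free z-buffer, each fruit's visible fraction (occluded-render pixels
over solo-render pixels), and contact pairs (object pairs whose noise-free
surface clouds come within 2 mm). A fruit's adhesion level is "little"
when over half its surface is visible and nothing touches it, otherwise
"serious".

Campaign designs mirror the physical experiments: 64 isolated-fruit +
120 isolated-leaf scenes; fruit–leaf collocations in six plan rows with 8
turn-table rotations of 45° per arrangement (the one-fruit-one-leaf row
places the leaf with a dominantly vertical offset and screens candidate
arrangements with a low-resolution ground-truth render so no rotation
hides more than 30% of the fruit — a condition on the scenes, not on the
detector); six varieties × 10 arrangements × 6 rotations of 60°; and 10
on-branch collocations of 3–4 fruits (one adhering pair), three leaves and
a branch over 8 rotations with an 850 mm backdrop.

What the generator does **not** emulate: peel texture and surface
roughness (absorbed into `ka` and the noise), leaf venation and doubly
curved or torn blades, multipath/flying-pixel artefacts at silhouettes,
variable dropout with range, and outdoor illumination. Passing replicas
therefore show that the geometry pipeline meets the reported rates under
idealized close-shot conditions; they do not certify performance on
physical sensor data.

## Numerical choices and degenerate inputs

Ties in `closest_point` break on (row, column). Single-pixel regions have
eccentricity 0; exact pixel lines have infinite elongation in the branch
filter. `chord_offset` rejects cuts past the fruit equator (`b < 0`).
Cloud clustering, rendering and scoring are fully deterministic given the
scene and seed; every stochastic stage takes an explicit integer seed, and
campaign sub-seeds derive from one master seed.

## Known limitations

* A curled leaf cut at a coincident angle can produce a closed, fruit-like
  curve; isolated-leaf misrecognition is non-zero (≈1–3% over seeds), and
  leaves adhering to fruit occasionally add a spurious detection in
  cluttered scenes.
* Fruits occluded beyond ~50% of their surface are usually lost — the
  successive schedule only reaches surfaces the sensor saw.
* The single-radius reduction of a spheroid biases the center estimate by
  a few millimetres for strongly oblate specimens.
* The range-adaptive split assumes the configured variety bounds the fruit
  sizes present; mixed plantings of very different calibres would need the
  fixed-`N0` mode or per-frame variety hints.
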