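# Methods

## Scope and model

canopyscan estimates growth parameters of greenhouse fruit vegetables from
two scanner products: a colored point cloud (x, y, z in a declared unit plus
RGB in 0–255) and a triangle surface model. Everything downstream is
geometry: no radiometric calibration, reconstruction, or learning is
involved. The internal unit is the centimetre (areas in cm², volumes in
cm³), and the coordinate frame is z-up with z increasing with height; both
conventions are normalised at read time because a unit or axis mix-up is
the dominant failure mode in multi-tool scan pipelines.

### Surface area and leaf area

A triangle's area is half the cross-product magnitude of its two edge
vectors anchored at the first vertex; total model area is the plain sum
over all polygons. The estimator deliberately does **not** halve areas for
"double-sided" leaf sheets: whether a reconstructed leaf is a single or
double sheet depends on the meshing software, and in field use that scale
factor is absorbed by the empirical regression between estimated and
measured values. A `calibration` multiplier (default 1.0) is the explicit
escape hatch when the sheet convention is known.

Trimming, which a scan-based workflow otherwise does by hand, is provided
as two deterministic operations: `crop_mesh` keeps triangles whose centroid
lies in a half-open axis-aligned box (no triangle is split — edge triangles
are ~mm² and irrelevant to organ-scale areas, while half-open bounds make
partitioning boxes conserve area exactly), and `remove_small_components`
drops edge-connected components below an area floor, which removes the
small floating polygon patches that drift-point noise produces. Component
connectivity uses exact vertex welding only; tolerance welding is left to
the user because any tolerance is scene-dependent.

### Allometry, LAI, height, structure, dry weight

The allometric relation `area = a · length · width` uses per-species
coefficients a = 0.25 (tomato), 0.87 (cucumber), 0.59 (paprika). The fitter
is least squares through the origin, since the relation has no physical
intercept; its R² is reported against the mean-centred total sum of squares.

LAI divides canopy leaf area by a user-supplied cultivation area in m². The
denominator is deliberately an input, not a constant: bench layouts differ,
and the generator records the footprint it used (layout bounding box padded
by half a plant spacing per side) so synthetic LAI is self-consistent.

Plant height is `z_max − z_base` with `z_base` a configurable percentile of
vertex z (default 0, the minimum); a small percentile discounts residual
floor points on imperfectly trimmed models.

Canopy structure assigns each triangle's whole area to the height bin
containing its centroid (default bin 10 cm, configurable). Centroid
assignment rather than area-weighted clipping is a conscious trade: scan
triangles are millimetre-scale against decimetre bins, so the clipping
error is negligible while the centroid rule keeps the profile exactly
conservative (bin areas always sum to total area, to round-off).

Dry weight is an ordinary least-squares line on leaf area, with intercept
by default (the biologically safer general form) and a through-origin
option. Prediction floors at 0 g.

### Fruit detection and weight

Gating uses strict per-channel inequalities exactly as stated (tomato
R > 140, G < 100, B < 100; paprika R > 150, G > 110, B < 50). Instances are
the connected components of the eps-neighbourhood graph (default eps 2 cm,
points linked when within eps), with components under `min_points`
(default 50) discarded as noise; this definition is order-independent by
construction. Defaults are sized to a scanner with ~3.4 mm lateral
resolution and fruits ≥ 5 cm across, and all three knobs are CLI-exposed.

Volume uses voxel counting on the gated cluster directly. The cluster's
bounding box is rasterised at `voxel_size` (default 0.5 cm); point-bearing
cells are the shell. The exterior is flood-filled from the box boundary
with 6-connectivity (26-connectivity would leak through diagonal gaps in
the shell), and unreached empty cells are interior. Interior cells count
fully; shell cells straddle the true surface and count **half**:

    V = (interior + shell / 2) · voxel³

The half weight is a midpoint rule. Counting crossed cells whole biases
the volume outward by roughly half a cell times the surface area
(≈ +17 % for a 3 cm sphere at 0.25 cm voxels); crediting them half cancels
that first-order term (measured −0.2 % on the same sphere, +3.9 % at
0.5 cm). The rule slightly under-counts solids whose faces lie exactly on
grid planes (a grid-aligned cube), where shell cells are wholly interior —
an accepted corner case, since scanned fruit surfaces are never
grid-aligned. Clusters with fewer than 4 points or with a vanishing third
singular value (coplanar/collinear) are rejected as degenerate; the yield
pipeline skips such clusters with a warning instead of failing.

Weight is volume × density, ρ = 0.84 g·cm⁻³ (tomato) and 0.59 g·cm⁻³
(paprika), both fruit-averaged water-displacement values. Cucumber ships
with no fruit parameters, so yield runs on cucumber raise a config error.

### Accuracy reporting

`accuracy` regresses estimated (y) on measured (x) and reports slope,
intercept, R², and RMSE computed on the raw pairs,
`sqrt(mean((est − meas)²))` — not on regression residuals — so a perfectly
correlated but biased estimator still shows its bias in the RMSE.

## Synthetic scenes and what they do (not) show

The generator exists because no public scan archive accompanies the method;
its defaults encode the study conditions: six-plant canopies on a zigzag
layout with 33 cm spacing, plant heights around 60–180 cm, and fruit radii
of 3–4 cm (five fruits per default scene, inside the 3–23 mature fruits a
tomato canopy carries).

Leaves are planar 16-gon ellipses, so each leaf's true area is an exact
shoelace value rather than a quadrature — the strongest possible oracle for
area integration. Leaf lengths are drawn from species-typical normals
(tomato 25 ± 5 cm, cucumber 20 ± 3 cm, paprika 10 ± 2 cm, clipped to
[0.3, 2] × mean) with fixed width-to-length ratios. The stem is a thin open
cylinder whose area is recorded separately, so tests can quantify stem
contamination of "leaf" area — the same bias a field regression absorbs
silently. Leaf attachments are placed so no leaf rises above the stem top;
the mesh z extent therefore equals the requested height exactly.

Fruit scenes sample uniform shell points on spheres at ~40 points/cm²
(several-fold oversampling of a 0.5 cm voxel grid), colored uniformly
*strictly inside* the species gate; foliage clutter is colored from a
region provably outside both gates (R < 140 with G > 120), which makes
gate tests exact set comparisons rather than statistical ones. An optional
hemisphere dropout removes each fruit's far side (y > center), reproducing
the single-view occlusion that makes scanned volumes underestimates: the
open shell lets the flood fill reach the inside, so only half-weighted
shell cells remain.

What passing tests on these scenes does **not** show: robustness to real
scanner artefacts. The generator has no drift points between leaflets, no
depth-dependent noise, no color-temperature shifts, no curved or serrated
leaves, and no partial occlusion beyond the fruit-hemisphere switch. Exact
recovery here validates the geometry and bookkeeping, not field accuracy;
field accuracy lives in the measured-vs-estimated regressions the
evaluation module produces.

All generators are deterministic given their integer seed (NumPy
`default_rng`); canopies derive per-plant seeds from the canopy seed.

## Numerical choices and degenerate inputs

- Degenerate triangles (collinear) have area 0 by construction, not error.
- STL dialect sniffing: ASCII requires a leading `solid` *and* a `facet`
  token; otherwise the binary layout must be exactly self-consistent
  (declared count vs body length), and a mismatch is a format error rather
  than a best-effort parse.
- PTS rows accept 6 or 7 columns (the 7th layout carries an intensity
  field, discarded); parse errors name the offending line. An optional
  single-integer header must match the data row count.
- PTS writing uses six decimals in cm, bounding round-trip error below
  10⁻⁴ cm — an order under scanner accuracy (2–10 mm).
- Through-origin R² can be negative for pathological data; it is reported
  as computed, not clamped.
- Empty meshes yield area 0 with a logged warning; empty gate results and
  empty cluster lists are valid outcomes, not errors.
- Cluster report order is sorted by centroid to keep CLI output stable
  across runs and point orderings.

## Problem sizes

The test suite and the acceptance script run on scenes of 2–6 plants
(≈ 250–1500 triangles), 10⁴–10⁵ random triangles/colors for the oracle
comparisons, and fruit clouds of ~5 × 10⁴ points; each estimator's
tolerance (10⁻⁹ relative for area oracles, 10⁻⁶ for exact-area recovery,
0.1 cm for height, 2–15 % for noisy parameter and volume recovery) is
stated at the test site. These sizes already expose every failure mode the
estimators have; larger scenes change runtimes, not conclusions.
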