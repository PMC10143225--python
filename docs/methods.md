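# Methods

This note documents the models, parameter choices, and numerical
conventions behind `stemscan`, and what the synthetic validation scenes do
and do not demonstrate about field data.

## Coordinate and unit conventions

All geometry is metric, z-up, in an arbitrary local frame (x east, y
north). The single unit conversion in the package is at the reporting
layer: radii fit in metres become DBH in centimetres (`dbh_cm = 200 r`).
Above-ground height (AGH) of a point is its z minus the terrain height at
its XY position.

## Ground classification and terrain

**Octree rule.** The cloud is voxelised on a grid anchored at its minimum
corner (default edge 0.10 m). Within each occupied XY column, points in
the lowest occupied voxel are ground; everything above is vegetation. The
rule has a documented failure mode: a column containing only canopy still
yields a "ground" voxel. Anchoring at the minimum corner makes the result
reproducible without a global datum and invariant to whole-voxel XY
translations.

**Voxel-size wording.** Voxel parameters quoted as "10 cm", "5 cm",
"2 cm", "10 mm" cells are read as *edge lengths* throughout, matching how
octree and cloth-filter tools parameterise their grids.

**Cloth simulation filter (CSF).** The cloud is inverted vertically so the
former ground is the upper envelope, and a particle grid falls onto it
under gravity. Defaults: grid resolution 0.24 m, classification threshold
0.03 m, time step 0.6 s, iteration budget 1000, rigidity 3 (three
internal-constraint passes per step, each pulling a movable particle
halfway to the mean of its four neighbours). Implementation specifics the
cloth parameters do not pin down:

- *Gravity*: 0.5 m s⁻², so a Verlet step falls g·dt² = 0.18 m; collision
  pinning makes the result insensitive to this choice, it only sets how
  fast the cloth settles.
- *Collision heights*: sampled on a 4× finer subgrid and taken as the
  maximum inverted height over a 3×3 subcell neighbourhood of each
  particle's centre subcell. Using the whole 0.24 m cell minimum would
  bias the cloth half a cell's worth of slope low; using a single subcell
  can leave a particle colliding on vegetation where ground sampling is
  sparse.
- *Pinning*: a particle that meets the surface is fixed permanently.
- *Convergence*: iteration stops early when the maximum per-step particle
  displacement drops below 5 mm; exhausting the budget sets a
  non-convergence flag on the result rather than raising.
- *Classification*: a point is ground when its height is within the class
  threshold of the settled cloth, bilinearly interpolated between particle
  centres (particles sit at cell centres, hence a half-cell shift in the
  interpolation indices).

**Percentile fallback.** Where dense understory hides the ground from a
sensor, a scalar ground height is used instead: the height below which the
lowest 2% of points lie, computed as the order statistic z₍ceil(0.02 n)₎.
The phrase this implements is ambiguous between the 2nd and 98th
percentile; the 2nd-percentile reading is adopted because the quantity
must sit near the cloud bottom to serve as a ground height.

**Terrain model.** A regular grid (default 0.5 m) holding the lowest
ground point per cell; empty cells are filled from the nearest non-empty
cell, and height queries use nearest-cell lookup rather than
interpolation, keeping AGH reproducible and order-independent.

## Stem segmentation

Vegetation points are voxelised (working edge 5 cm). Each occupied voxel
gets a descriptor from the PCA of its k = 10 nearest occupied-voxel
centroids: λ₁/(λ₁+λ₂+λ₃) weighted by the absolute vertical component of
the first eigenvector — near 1 on vertical line-like structure, near 0 on
flat or isotropic clutter. Neighbour distances are measured with z
compressed by a factor of 3 (PCA itself uses unscaled coordinates): an
isotropic neighbourhood on a stem *surface* is a curved patch whose
descriptor saturates around 0.5, whereas the vertically elongated
neighbourhood follows the stem and scores ≳ 0.8. The descriptor details
(k, the anisotropy, the weighting) are reconstruction choices — the
segmentation tool this mirrors does not publish its algorithm — and all
are exposed in `SegmentationParams`.

Voxels with descriptor ≥ 0.70 and AGH ≥ 0.5 m seed 26-connected
components; five growth passes then let unassigned voxels adjacent to a
segment join it (ties go to the lowest segment id, deterministically).
Components under 100 voxels are discarded. Suspected multi-stem segments
can be re-run at a 2 cm voxel edge on their member points only
(`refine_segment`), which separates stems ~0.3 m apart that merge at 5 cm.

## Stem base and DBH

**Base position** is the component-wise median of the member points with
0 < AGH ≤ 1 m — the basal band tolerates basal sweep, which would drag a
full-height centroid away from the measurement location. The band
wording could also be read as "above 1 m AGH"; the 0–1 m reading is
adopted because sweep lives in the lowest section. Medians use the lower
median on even counts so results are exactly reproducible. An empty band
falls back to the lowest 10% of member points by AGH, flagged.

**DBH** comes from the point slice at 1.3 ± 0.05 m AGH (slice thickness is
not externally specified; 10 cm total is common terrestrial practice and
keeps ≥ hundreds of points at depth-camera densities). Slice points
project to XY and a circle is fit in two stages: the algebraic Kåsa
solution (linear least squares on x² + y² = 2ax + 2by + c) initialises a
Gauss–Newton minimisation of Σ(‖pᵢ − c‖ − r)², iterated to a 10⁻⁸ m step
tolerance or 100 iterations. Geometric least squares is the standard
reading of an under-specified "least-squares fit" and is markedly more
robust on partial arcs. Non-convergence returns the algebraic fit with a
flag; fewer than 5 slice points marks the stem `failed_other`. Each record
carries the fit RMS residual, slice point count, and the angular coverage
of the slice around the fitted centre (360° minus the largest angular
gap) so single-face captures of small stems can be flagged downstream.

## Proximity and understory metrics

Stem proximity is the XY distance to the next closest stem base; it is
undefined (absent, logged) for a single stem. A stem is "within duplicate
capture range" of a device when that distance is ≤ the device's duplicate
radius, boundary inclusive. Built-in device profiles (sensor range /
duplicate radius / subplot radius, metres): kinect 3.0/2.0/2.0, zed
3.5/2.5/2.5, ipad 5.5/4.5/4.5; the subplot radius is the sensor range
minus the 1 m operator standoff.

Understory metrics for a stem are computed inside its device subplot:
crop, keep points ≤ 1.3 m AGH, remove ground with the CSF (same defaults),
remove the target stem (points within fitted radius + 5 cm of the base
axis; the margin absorbs fit noise without eating adjacent shrubs), then
voxelise at 10 mm on a grid anchored at the subplot bounding box, with
each column's z measured from the terrain height at the column centre so
slopes do not inflate volume. The column-fill rule: the highest occupied
voxel in a column and all voxels beneath it count as filled, since upper
foliage occludes everything below it. A return exactly on a voxel
boundary belongs to the voxel beneath it, so an analytic surface at
k·edge fills exactly k layers.

Reported quantities: `volume_m3` = filled voxels × edge³; `volume_pct`
normalises by the subplot's 0–1.3 m column capacity (the percentage needs
*some* normaliser and subplot capacity is the natural one — the original
definition is not stated); `cover_pct` = share of subplot columns holding
at least one vegetation point (likewise a documented choice).

## Comparison statistics

Errors are device-minus-reference DBH in cm (overestimation positive).
RMSE, bias (mean signed error), and RMSPE = 100·RMSE / mean *reference*
DBH of the same stems — the definition under which all six published
within/outside-range value pairs re-derive exactly at printed rounding
(8.9, 9.0, 16.6, 28.2, 10.9, 8.2%). Welch's t uses the unequal-variance
statistic with Welch–Satterthwaite degrees of freedom (kept unrounded
internally, floored for display); Pearson's r reports df = n − 2 and a
two-sided p through the t transform. Failure summaries report per-cause
percentages of all failures at integer rounding (25/31 → 81%, 47/51 →
92%). Reporting rounds RMSE and bias to 2 decimals and RMSPE to 1.

## Synthetic scenes: what they emulate and what they do not

The generator produces, deterministically in the config seed:

- **Terrain**: a sum of three seeded sinusoids (wavelengths 5–15 m) scaled
  to the requested relief amplitude — smooth, low-frequency ground of the
  kind parkland and open woodland sites have; no cliffs, ditches or rocks.
- **Ground returns** on a jittered grid (default 5 cm spacing, 5 mm
  vertical noise).
- **Stems**: surface-sampled tapered cylinders (default sampling spacing
  1 cm; the study-scale runs here use 2 cm to keep point counts at
  hundreds of thousands rather than millions), with optional lean, linear
  basal sweep (axis displaced `sweep_offset` metres at 1.3 m), radial
  Gaussian surface noise, and restricted angular coverage to emulate
  single-face captures. The diameter at 1.3 m above the base terrain
  equals `dbh_true` exactly before noise.
- **Understory patches**: boxes, half-ellipsoids and hemispheres below
  1.3 m, with uniform interior sampling plus a dense jittered sampling of
  the analytic top surface (default 5 mm spacing). The dense top matters:
  the column-fill rule responds only to the highest return per 10 mm
  column, and real TLS/depth-camera shrub captures are dominated by upper
  surface returns. The analytic volume oracle rasterises the same shapes
  with the same grid anchoring and fill rule, independent of point
  sampling.
- **Artifacts**: (a) duplicate faces — the arc of a stem facing another
  stem's capture position is copied and rigidly shifted when that position
  is within sensor range; (b) signed radial backscatter — a fraction of
  each stem's points is displaced along the surface normal, positive
  outward (inflating fitted diameters, the time-of-flight direction) or
  negative inward (the noise-filtered / stereo direction). Because a
  circumnavigating capture places every azimuth on the sensor silhouette
  in some frame, edge pixels are drawn uniformly over the stem surface
  rather than by a fixed-viewpoint normal test; (c) drift — a rigid
  translation growing linearly with simulated path length (greedy
  stem-to-stem tour at 1 m standoff), applied per 30° observation sector.
  The drift rate default (0.002 m per m of path) is a free parameter: no
  quantitative drift magnitude is available to calibrate it.

Not emulated: radiometry and colour, actual SLAM (feature matching, loop
closure, tracking loss), canopy above what stems provide, wind movement,
occlusion shadows behind stems, and range-dependent noise. Consequently,
passing tests demonstrate that the *measurement pipeline* recovers truth
under controlled artifact models — not that any particular sensor will
achieve those errors in the field, and not the spatial-tracking failure
process itself (failed captures enter the statistics as data, via the
capture-status machinery, not as simulated SLAM collapse).

## Validation scales

The test and acceptance runs use plots of 4–12 m radius, 1–50 stems,
2 cm stem sampling and 5 cm ground sampling (≈ 30k–600k points per
scene), chosen so the whole suite replays in a couple of minutes on one
core while keeping every estimator comfortably inside its operating
densities. The CSF label-accuracy floor of 95% on the sinusoidal scene
was frozen after an oracle run that measured ≈ 99%.

## Known limitations

- The octree ground rule mislabels canopy-only columns by construction.
- The CSF snags on understory that touches the ground within the class
  threshold; points within 3 cm of the terrain are inherently ambiguous.
- The segmentation reconstruction does not claim equivalence with the
  original tool's unpublished algorithm; thresholds transfer only
  approximately.
- Circle fits on arcs ≪ 180° are reported but carry large centre
  variance; downstream users should filter on `arc_coverage_deg` and
  `n_slice_points`.
- `volume_pct` and `cover_pct` follow this package's documented
  definitions; comparisons against other tools need the same normaliser.
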