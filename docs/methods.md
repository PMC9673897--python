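# Methods

This note documents the models and procedures implemented in `sdindex`,
the parameters that matter, what the synthetic generator does and does not
emulate, and the numerical choices made where the method leaves room.

## The spacing model

The population-density score rests on an idealised hexagonal tessellation:
each person occupies one regular hexagon, and the apothem *d* (centre to
mid-side) is half the centre-to-centre spacing between people. A 2 m
distancing requirement corresponds to *d* = 3 m — a person can move 2 m in
any direction while staying 2 m from everyone else. The hexagon area is
*A(d)* = 2√3·*d*² and the compatible maximum density *T(d)* = 10⁶/*A(d)*
people per km². Sweeping *d* from 3 m to 11 m in 1 m increments gives nine
thresholds mapped monotonically to scores 10 (at 3 m) down to 2 (at 11 m);
non-zero densities below *T*(11 m) score 1, zero density scores 0.

Two conventions matter:

* **Comparisons use unrounded thresholds.** The familiar printed pair
  (*A* = 31.18 m², *T* = 32,075 /km²) only co-exists if *T* is computed
  from the unrounded area: 10⁶/31.1769… = 32,075.01, whereas
  10⁶/31.18 = 32,072. Densities are classified against the double-precision
  *T(d)*; rounding happens only in reports.
* **Band edges are lower-inclusive**: density ∈ [*T(d)*, *T(d−1)*) takes
  the score of apothem *d*, and density ≥ *T*(3 m) scores 10.

The model is deliberately obstruction-free: it bounds what perfect spacing
could achieve, not what a real street block allows, so real feasible
spacings are worse than the score suggests.

The intermediate apothem→score assignment (4 m → 9 … 10 m → 3) is the
unique monotone one-score-per-metre mapping consistent with the stated
endpoints; the package parametrises the model by apothem directly rather
than by distancing requirement, since only the 2 m → 3 m correspondence is
defined.

## Urban extents

Settlement-model classes 21–30 count as urban. Components use
8-connectivity (queen moves): diagonal strings of settlement cells are
common and 4-connectivity would split them. Components qualify only if
they intersect the polygon of an urban centre whose quality flag equals 1.
Each component is buffered by 3 km and replaced by its convex hull; hulls
whose interiors overlap are merged — transitively, and iterated to a
fixpoint because a merged hull can grow into new overlaps — and clipped to
the national land polygon. The coastline is consumed as a pre-polygonised
water mask subtracted from the admin polygon, which is equivalent to
clipping to the coast without requiring line-side topology. Extent IDs are
`{ISO3}{nnnn}` in (latitude, longitude) order of centroids so reruns
number identically.

## Spatial units

All unit construction happens in planar metres. For geographic inputs each
extent is projected into a local spherical azimuthal-equidistant plane
centred on its centroid; at city scale (≲20 km) the scale distortion is
below 10⁻⁶, and a spherical line-integral area formula serves as an
independent cross-check (agreement required within 0.1%, observed ~10⁻⁸).

Lines, land-use outlines and the extent boundary are noded by geometric
union and polygonised. Polygonisation emits nested rings (an island
land-use polygon floating inside a block) as overlapping faces; contained
faces are punched out of their hosts so the faces exactly partition the
extent. Land-use interiors therefore become standalone units (an airport
is its own block).

Fringe handling: faces larger than 100,000 m² whose geometry intersects
the *boundary curve* of a built-up or small-settled-area extent (hamlets
excluded) are re-polygonised with residential-area outlines; faces without
intersecting residential data pass through unchanged. "Intersects the
boundary" is read strictly as touching the boundary curve — a large face
wholly inside a settlement is not fringe.

Sub-hectare faces are merged iteratively, smallest first, each into the
neighbour sharing the longest common boundary; ties break to the larger
neighbour, then the lowest stable face id. The loop terminates (each merge
removes one face) and conserves total area to float precision. A
sub-threshold face with no line-sharing neighbour is kept with a warning.
Extents with fewer than 30 units are discarded *before* scoring — the
filter reflects whether a place supports meaningful street blocks at all,
not what its scores are.

## Scoring

Density per cell is population count divided by the cell's surface area
(km²), at unchanged resolution. The unit mean uses cells whose centroids
fall inside the unit; units too small or thin to contain a centroid fall
back to bilinear interpolation at the unit centroid over the four nearest
cell centres, dropping nodata neighbours with weight renormalisation.
Units fully outside the raster (or with all-nodata coverage) get −99,
which propagates to `POPscore` and `INDEXvalue`. Densities are carried in
double precision and never rounded before classification.

Building footprints are dissolved (unioned) before measurement so
overlapping digitised footprints cannot push `BUILT_PROP` above 1, then
clipped to each unit: a building straddling a boundary contributes exactly
its clipped share to each side, so built area is conserved under
splitting (tested to 10⁻⁶ relative). Built-score bins are deciles with
inclusive upper edges; a 10⁻¹² guard absorbs float noise at exact edges.

## The synthetic country

The generator plants a grid city inside a toy country and provides every
pipeline input with known truth:

* **Layout**: 4×4 blocks of 200 m by default, aligned to the 100 m
  population grid (the 3 arc-second analogue), inside a 15 km domain with
  a settlement-model cluster (classes 30/23/21 including one diagonal
  cell), a quality-flagged centre, a qa = 0 distractor centre, a
  centre-less urban blob, water cells matched by a water mask, an airport
  land-use polygon, BUA/SSA/hamlet settlement extents and a residential
  fringe patch.
* **Built truth is exact**: each block holds 25 square buildings of
  combined area exactly `target × block area`; the seed only jitters
  positions within free sub-cell margins, never areas.
* **Density truth is exact**: cell counts are written as
  `target density × cell surface area`, so the zonal mean equals the
  target identically. Population is only allocated to cells intersecting
  footprints (a zero-built block must be zero-density), emulating
  constrained gridded population data; unsettled cells inside the raster
  are 0 and the area beyond the raster footprint exercises the −99 path.
* **Planted targets sit mid-bin.** Targets are never placed on
  classification boundaries: realised values match targets to ~10⁻⁷ at
  best in the geographic variant, and a boundary-sitting target would make
  the planted score ill-defined. Density targets likewise stay clear of
  the unrounded *T(d)* values (note 32,075 itself lies just *below*
  *T*(3 m) = 32,075.015).
* **Geographic variant**: the same layout mapped linearly onto a
  3 arc-second grid near 8.4° N (1 layout-metre → 1/120000°), with
  per-row spherical cell areas. This keeps raster/block alignment while
  exercising every degree/metre conversion.
* The edge-case bundle (400 m blocks, 26 km domain) adds a thin 80 m-wide
  unit with no cell centroid, a sub-hectare sliver that must merge away, a
  building straddling two blocks (truth adjusted by its exact clipped
  shares), and a second city whose 28 parallel streets cut its extent into
  exactly 29 units, which the 30-unit filter must drop.

What the generator does **not** emulate: realistic building shapes and
size distributions, population heterogeneity within blocks, raster/vector
misregistration, digitisation noise and invalid geometries at scale, or
the sheer size of national datasets. Passing tests demonstrate the
correctness of the algorithms under clean conditions, not the quality of
any production dataset.

Default problem sizes (a 15 km domain, one extent, ~40 units, 12×12 to
16×16 raster cells) were chosen so the whole suite exercises every stage
in seconds while every stage still has non-trivial work to do.

## Validation procedure

Scored units are classified Informal/Other either by area overlap with
informal-settlement polygons (≥ 50% of unit area) or by the modal type of
intersecting buildings (ties and building-less units → Other, a
documented choice since the tie rule is otherwise unspecified). Joint
(POPscore, BUILTscore) proportions are computed within each class and
exceedance proportions P(score ≥ t) compared between classes; −99 units
are excluded from numerator and denominator. On fixtures where informal
blocks are planted denser than others, informal exceedance at
POPscore ≥ 7 must strictly exceed the other class — the qualitative
pattern reported for real informal-settlement comparisons.

## I/O and formats

Vector layers are GeoJSON (with a top-level `crs` member distinguishing
the local-metric fixture plane from geographic coordinates); rasters are
single-band GeoTIFFs written with ModelPixelScale/ModelTiepoint,
a minimal GeoKey directory and GDAL-style nodata tags. The three published
layers are schema-validated field-by-field before writing; −99 is always
written as a number, never null. Rotated rasters are not supported.

## Known limitations

* Spherical (not ellipsoidal) geodesy: adequate at city scale
  (≲10⁻⁶ relative), not for continental measurement.
* The merge rule for sub-hectare faces is one of several defensible
  choices (e.g. preferring same-land-use neighbours); results can differ
  in slivers near land-use boundaries.
* `POP_DENS` is a residential (night-time) density; daytime population
  and socioeconomic constraints on distancing are out of scope.
* Building height/floor space is not considered, so high-rise areas are
  scored only by footprint coverage.
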