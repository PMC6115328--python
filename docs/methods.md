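# Methods

## Model and procedure

The pipeline treats vulnerability to snakebite envenoming as the spatial
conjunction of an ecological exposure layer and three health-system
deficits. The exposure layer is a stack of per-species presence rasters;
the deficits are absence of any listed antivenom for the species present,
remoteness from urban centres (a proxy for access to care), and a low
Healthcare Access and Quality (HAQ) Index decile (a proxy for quality of
care). Population on cells where all conjuncts hold is enumerated and
aggregated to second-level administrative units, countries, and deciles.

### Occurrence cleaning and availability groups

Records are deduplicated within species on the (collection year,
latitude, longitude) tuple, coordinates rounded to 6 decimal places
(~0.1 m, far below any grid resolution used). A literal reading of
"shared year *or* coordinate" would delete distinct sites that merely
share a collection year, so the conjunctive tuple is used. Records
missing either coordinate, or with a coordinate outside valid WGS84
ranges, are dropped with a logged tally. Missing-year records are kept
and collapse only with other missing-year records at the same rounded
coordinates. Group assignment (A: no EOR and no use; B: EOR, < 5
records; C: EOR, ≥ 5 records) uses post-deduplication counts; species
with records but no EOR map are unmappable and are folded into the
excluded group A with a prominent warning.

### MESS

The multivariate environmental similarity surface is a per-covariate
piecewise score (see README for the four branches) minimised across
covariates; a cell scores negative exactly when at least one covariate
value leaves the training envelope. Numerical conventions:

- *f* (the percentage of training values below the candidate) uses the
  strictly-below convention; ties count as not below.
- The interpolation threshold is ≥ 0: the training extremes are
  attainable environments, so the envelope boundary counts as
  interpolation.
- Degenerate training (all values identical) scores 100 at the constant
  and −100 elsewhere; a constant environment offers no scale on which to
  grade departure.
- Fewer than two usable within-EOR training records refuses the fit and
  the species keeps its EOR (signalled, not fatal).
- Covariate values are taken from the cell containing a point — no
  bilinear interpolation; the analysis works at cell resolution
  throughout.
- Points on polygon boundaries count as inside (deterministic, inclusive
  convention, applied uniformly to EOR membership tests and
  rasterization).
- The surface is evaluated over a window covering the EOR and every
  outside record's buffer disc, padded by 10% of the buffer radius and
  snapped to cell edges. Window cells coincide with parent-grid cells,
  so the classification is independent of the window choice; the window
  only bounds cost on large grids.

### Range amendment and rasterization

MESS-positive records outside the EOR are buffered by 0.898 decimal
degrees. Buffers are planar discs in degree space — the radius is
specified as an angle, so no geodesic construction is implied; the
≈ 100 km equatorial equivalence is reported, not enforced. Discs are
approximated by 64-segment polygons (area within 0.2% of the true
circle) and split at the antimeridian when they overflow ±180°. The
buffered union is intersected with the union of interpolation cells
(converted to square cell polygons — "cells of interpolation" is
cell-based, so the mask is cell-based) and merged with the EOR. The
result therefore always contains the EOR, and equals it exactly when no
outside record is MESS-positive. Rasterization marks a cell present when
its centre lies in the geometry (an all-touched variant is available by
configuration); whether buffered areas reach beyond usable land is
governed by covariate nodata, since nodata cells cannot be
interpolation and are therefore masked out of any amendment.

### Richness layers

Presence rasters are summed per cell into six strata: all included
species, WHO category 1, category 2, and the same three restricted to
species with no listed antivenom. Counts are stored as 16-bit integers
(observed maxima are small). A cell is nodata only where every input is
nodata; with any valid input, species missing there count as absent.

### HAQ deciles

Countries are ranked ascending by HAQ value (decile 1 = lowest quality,
matching the "lowest decile" usage) and the unit at 1-based rank r of N
receives decile ⌊10(r−1)/N⌋ + 1, so group sizes differ by at most one.
Ties spanning a boundary are broken by unit identifier for determinism.
Subnational units never enter threshold construction; they are placed by
value into the national deciles using (lower, upper] intervals with
clamping at both extremes — the source material gives no boundary rule,
so this is a documented package choice.

### Travel time and delay scaling

"More than 1 h / 3 h away" is read strictly (minutes > threshold); a
cell at exactly the threshold is not remote. The delay–mortality factor
is linear: 1.01 percentage points of excess mortality per hour between
envenomation and antivenom administration, a statistic estimated on a
Nigerian cohort. Its linear extrapolation to delays of a day or more is
an assumption, flagged as such in the output summary metadata.

### Enumeration

Pixel-to-admin assignment is by cell centre; on shared borders the unit
listed first wins (deterministic). Masked population on cells outside
every polygon is reported in an explicit "unassigned" bucket rather than
silently dropped. Populations are carried as reals and rounded half-up
to whole persons only when reports are written. Countries with zero
vulnerable population are omitted from the wide country-by-decile
matrix but appear with zeros in the full per-admin CSV. The published
country-by-decile table bundled in `snakevuln/data/` is consumed by the
same `decile_table` code path as pipeline output.

## Synthetic scenarios and what they show

The generator emulates the statistical structure the analysis consumes,
not real biogeography. Default scenario: a 60 × 60 grid of 0.25° cells,
8 covariate bands, 12 species (2 of them group B), 6 countries × 3
admin-2 units, 14 additional "offstage" countries in the HAQ table so
decile construction has ≥ 10 nationals, piecewise-constant population
(5–50 persons/cell) and travel-time (30/120/240 min) fields per admin
unit. It runs end-to-end in seconds; these sizes were chosen so the full
suite and the acceptance script stay interactive on one CPU.

Covariate bands vary along longitude only (sinusoids of varying period,
amplitude, phase, and trend, plus one strictly monotone band), and
inside-EOR records sit on a 3 × 3 sub-grid of cells. This gives two
construction guarantees: any cell sharing a longitude column with a
training record is certainly interpolation, and any cell beyond the
training longitude span is certainly extrapolation — so planted
outside-record labels always exist for any seed. Outside records are
then selected from cells classified by the brute-force oracle (requiring
a 10⁻⁶ margin on the extrapolation side so a label can never sit on a
floating-point knife edge), which makes the planted labels exact ground
truth. Two columns of covariate nodata exercise nodata propagation.
Planted duplicate and missing-coordinate occurrence rows exercise
cleaning.

The oracle recomputes presence, strata, and population sums with
explicit per-cell Python loops and its own scalar MESS implementation,
sharing no pipeline code. It does construct record buffer discs with the
same 64-segment approximation the range builder documents — the
approximation is a stated design parameter, and using it is what allows
boolean layers to be compared exactly rather than within a tolerance.

What passing does **not** show about real data: the generator's
covariates are one-dimensional and noiseless, its polygons are
axis-aligned rectangles snapped to cell edges, its population and travel
fields are piecewise constant, and records sit at cell centres. Real
occurrence data carry positional error, real polygons have complex
topology (the EOR repair path is exercised only by unit tests), and real
rasters disagree about grids — the pipeline refuses grid mismatches
rather than resampling, so real use requires an explicit `regrid` step.

## Degenerate inputs and tie-breaks (summary)

- duplicate records: first occurrence wins; cleaning is idempotent;
- empty buffer geometry, empty mask, or no outside records: EOR kept;
- all-species-covered or empty-filter richness strata: valid all-zero
  layers, not errors;
- < 10 countries: decile construction is an error, not a guess;
- population nodata: counted as zero persons; travel nodata: never
  remote; covariate nodata: never interpolation;
- grid mismatch anywhere: hard error naming both layers.

## Known limitations

- Raster I/O is plain-text ESRI ASCII grid; no compressed or tiled
  formats, so very large grids are better pre-tiled.
- Buffers are planar in degree space; at high latitudes a 0.898° disc is
  not ~100 km east–west. An equal-area workflow would need projected
  inputs, which the grid model does not provide.
- Antivenom availability is a per-species boolean (market listing), not
  in-field stock or efficacy.
- The delay–mortality slope is a single-cohort statistic applied
  globally and linearly.
- Subnational HAQ handling assigns deciles by value but the bundled
  synthetic scenarios exercise national units only.
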