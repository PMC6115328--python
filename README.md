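# snakevuln

Global mapping of populations vulnerable to snakebite envenoming.

Snakebite is a neglected tropical disease whose burden falls on people who
live where medically important venomous snakes occur *and* where health
systems are least able to respond. `snakevuln` implements that triangulation
as a reusable pipeline for epidemiologists and geospatial analysts:

1. **Species registry** — clean occurrence records (duplicate and
   missing-coordinate removal), group species by data availability
   (group A: no expert-opinion range (EOR) map and no records, excluded;
   group B: EOR but < 5 records; group C: EOR and ≥ 5 records), and join
   WHO antivenom-availability flags.
2. **MESS range refinement** — fit a species-specific multivariate
   environmental similarity surface (MESS) on the covariate values at
   within-EOR records. Per covariate, with *f* the percentage of training
   values strictly below a candidate value *v* and [min, max] the training
   envelope:

   ```
   f = 0:         S = 100 (v − min)/(max − min)
   0 < f ≤ 50:    S = 2 f
   50 < f < 100:  S = 2 (100 − f)
   f = 100:       S = 100 (max − v)/(max − min)
   ```

   The cell score is the minimum of S over covariates; S ≥ 0 is
   environmental interpolation ("MESS-positive"). Valid MESS-positive
   records outside the EOR are buffered by 0.898° (≈ 100 km at the
   equator), masked to interpolation cells, and merged with the EOR to
   form the contemporary range, which is rasterized onto the shared
   analysis grid.
3. **Richness stacking** — per-cell species counts, overall and stratified
   by WHO category (1/2) and by absence of any listed antivenom.
4. **Health-system metrics** — Healthcare Access and Quality (HAQ) Index
   deciles (countries ranked ascending into ten equally sized groups;
   subnational units placed by the national value thresholds), strict
   travel-time remoteness masks (> 1 h, > 3 h to a ≥ 50 000-person
   centre), and the linear delay–mortality scaling of 1.01 percentage
   points of excess mortality per hour of treatment delay.
5. **Vulnerability enumeration** — a cell is vulnerable when it is within
   ≥ 1 species' range, more than 3 h from an urban centre, and in HAQ
   deciles 1–3 (optionally restricted to species with no therapy);
   gridded population is summed over vulnerable cells and aggregated to
   admin-2 units, countries, and deciles.

A first-class synthetic-data module generates complete, internally
consistent inputs (covariates, EORs, labelled occurrence records,
population, travel time, HAQ tables, admin mosaics) with planted ground
truth and an independent brute-force oracle, so the whole pipeline is
testable without downloads.

Rasters are read and written as ESRI ASCII grids (plain text,
GDAL-compatible); vectors as GeoJSON; tables as CSV.

## Worked example

```sh
snakevuln simulate --seed 1 --out scen
snakevuln run --input scen --out out
```

prints `vulnerable_total_all: 1536` and writes an output tree whose
`summary.json` contains (excerpt):

```
n_amended_species: 7
population_in_range_all: 37146.0
population_in_range_remote: {"60": 29818.0, "180": 18959.0}
vulnerable_total_all: 1536.0
vulnerable_total_no_therapy: 1536.0
```

Seven of the twelve synthetic species had MESS-positive records outside
their EOR, so their ranges were amended; 37 146 of the scenario's people
live within ≥ 1 species' range, 18 959 of them more than 3 h from an
urban centre, and 1 536 additionally fall in HAQ deciles 1–3 — here all
within the range of a species lacking antivenom, in country C01
(`vulnerability_country_by_decile_no_therapy.csv`):

```
country  decile_1  decile_2  ...  decile_10
C01          1536         0  ...          0
Total        1536         0  ...          0
```

Every number above matches the generator's `ground_truth.json`, which is
computed by an independent per-cell brute-force oracle.

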