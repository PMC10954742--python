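# Methods

## Model

`nispread` treats the spread of a non-indigenous species through a basin
as a sequence of *momenta*: t₀ is the species' first record anywhere, and
t_x its first record in the (x+1)-th distinct country, in ascending year
order. The model is deliberately agnostic — it fits no mechanism, makes no
environmental assumptions, and reads timing and direction purely from the
record table. Its assumptions are therefore those of the data reduction:

- A country (EEZ) is the spatial unit; presence is boolean per country.
  Repeat records inside an occupied country never advance the momentum.
- Spread duration is measured between *first* records, so detection lag is
  folded into the gaps; the framework measures apparent, not biological,
  spread speed.
- Gaps pooled over species at one step are exchangeable; their eCDF median
  is the step summary. Medians are used because the gap distributions are
  strongly right-skewed; the even-n median is the midpoint of the two
  central order statistics and may be fractional (half-years).
- The cumulative curve (prefix sums of step medians) is a *population*
  summary: it estimates how long a typical species needs to reach momentum
  t_k, not any one species' history. The inferred duration at momentum k
  is the sum of the first k step medians — a t₀ match contributes the
  first transition's median, since momentum 0 itself carries no elapsed
  time.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `max_momentum` | 10 | analysis window t₀..t₁₀; later momenta are too thinly populated to summarize |
| `buffer_deg` | 1.0 | planar dilation (degrees) of hotspot polygons before union; the method calls for 1°–3°, and outside that range the package warns (or raises in strict mode). One fixed buffer is used at every momentum; the value is echoed in output metadata |
| `dominant_threshold` | 50% | a momentum's dominant hotspot is the minimal count-ranked country prefix strictly above this cumulative share (ties broken alphabetically, so selection is deterministic) |
| `entry_point` | 32.32°E, 31.28°N | trajectory anchor; the Mediterranean mouth of the Suez Canal near Port Said |
| `window` | 5 years | trailing moving-average window for validation centroid tracks (`centered=True` available) |
| country→MSFD defaults | GR→EMED, IT→CMED, TN→CMED, LY→EMED, MT→CMED | multi-subregion countries need a record-independent assignment; configurable per run, and a per-record `msfd` column overrides it |

## Scenario 2 (dominant-hotspot subset)

The delta pool at step k is restricted to species whose momentum-k country
lies in the dominant hotspot *of momentum k* (the arrival side of the
transition). Gating on the departure momentum instead would be equally
defensible; the arrival convention was chosen because the hotspot
selection and the gap both describe where the species newly appears. The
scenario-deviation denominator is the all-cases (scenario 1) median; both
medians zero gives 0%, a zero reference with a nonzero comparator is
flagged undefined rather than reported as infinite.

## Geometry

All polygon work (buffer, union, centroid) is planar in WGS84 degree
space, matching a GIS workflow over lon/lat layers; at Mediterranean
latitudes (~31–45°N) the departure from geodesic centroids is small
relative to EEZ extents. Only the validation matching uses great-circle
(haversine) distance, where a nearest-centroid decision is being made.
Hotspot geometry is driven by country membership, never by record
coordinates. The packaged EEZ polygons are synthetic coarse boxes intended
for tests and examples; a loader accepts real Marine Regions GeoJSON.
Buffered polygons are not clipped to a sea mask by default (a `clip`
geometry is accepted).

## Validation arithmetic

Actual duration counts both endpoint years (2008–2022 → 15 years).
Temporal validation is 100·min(a, b)/max(a, b): symmetric, 100 iff the
durations agree, and monotone as the inferred duration approaches the
actual one. This formula reproduces the three published benchmark
percentages exactly from their printed durations (15 vs 13.5 → 90;
17 vs 19.5 → 87.2; 19 vs 13.5 → 71 at integer precision, 71.1 at one
decimal), which is why it was adopted; no other rendering choice survives
all three. Endmost-centroid matching is nearest-neighbour with ties to the
lower momentum. The trajectory verdict is a net-displacement sign test
(Δlat > 0 and Δlon < 0 from the first to the endmost moving-average
centroid), with per-step bearings reported as diagnostics; a qualitative
"follows the expected north-west course" is thereby made falsifiable.

## Synthetic data

The generator emulates the *structure* of a first-record table: every
species enters at one configurable region in a uniform random year, then
advances along an ordered east→west country chain with i.i.d. integer
gaps (fixed k, geometric on {1, 2, …}, or an explicit table), truncated at
`max_steps` or at the chain's end; `established_fraction` instead assigns
that share of species ≥ 2 onward steps and the rest ≤ 1, making the
establishment share exactly recoverable. An optional additive detection
lag (off by default) shifts recorded years. Everything derives from one
mandatory seed; identical config reproduces identical bytes.

What it does not emulate: environmental forcing, species interactions,
uneven or time-varying sampling effort, multiple entry points,
back-and-forth or skipping spread, and correlated gap speeds within a
species. Passing recovery tests therefore demonstrates that the numerical
pipeline is correct and unbiased under its own assumptions — not that
those assumptions hold for real records.

Default study conditions used by the recovery tests: geometric(p = 0.4)
gaps (true median 2 years), 500 species for the headline recovery run
(hundreds of gaps per step keep the 3σ binomial order-statistic band
around the sample median at the true median itself), smaller n (20–120)
for end-to-end and CLI tests to keep the suite fast.

## Numerical choices

- Same-year momentum ties: input row order (`source_rank`), deterministic
  and permutation-stable.
- Hotspot ranking ties: alphabetical by country code.
- Steps with one observation still report a median (the value itself) and
  are flagged `low_n`.
- Degenerate zero-area geometry has no centroid and raises.
- Record cleaning accepts years in [1800, current year] — a guard band
  wider than any plausible first-record table — and drops, with counted
  reasons, unknown countries, half-present coordinates and exact
  (species, country, year) duplicates.
- Pipeline outputs are byte-deterministic under a fixed config; raster
  plots are opt-in (presentation only) and the run manifest records input
  and output SHA-256 hashes.

## Known limitations

- Country-level resolution hides within-EEZ spread; a species "reaching"
  a large EEZ may be thousands of kilometres from its centroid.
- One fixed buffer per run: if the original analysis varied the buffer by
  momentum, its exact trajectory cannot be reproduced without that
  schedule.
- The cumulative curve adds medians of different species pools per step,
  so it is not the median of any per-species total.
- No uncertainty is attached to medians or centroids (no bootstrap); the
  scenario deviation is the only built-in robustness probe.
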