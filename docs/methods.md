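# Methods

## Data model

A study is a set of fixed *water points* — pipes/cisterns, drainage channels,
ocean sites, or combined sites — each visited roughly monthly. A visit yields
an **epidemiological sample** (fecal coliform count in CFU/100 mL by the mFC
agar method, plus optional in-situ physiochemistry: temperature °C, turbidity
NTU, total dissolved solids mg/L, pH, dissolved oxygen mg/L, salinity ppt)
and an **environmental survey** (ordinal 1–5 scores for mud, standing water,
trash and human activity, 1 = least).

The calendar month is the analysis granularity: full dates are stored, but
uniqueness, charts, sliders and joins key on `(year, month)` — one sample and
one survey per point per month, latest-wins upsert on re-entry. The store is
in-memory with CSV persistence; queries are pure and never mutate it.
Coordinates are WGS84 decimal degrees (internal argument order lat, lon;
GeoJSON output order lon, lat per the standard). Distances use the haversine
formula with a fixed mean Earth radius of 6,371,000 m; at the 30 m – 1 km
scales of a settlement, geodesic corrections are far below the data's
positional accuracy.

## Exploratory statistics

**Percent-of-max.** For a site with FC history `fc(·)`, the month `t` is
reported as `100 · fc(t) / max fc`. The denominator is the maximum over the
site's *entire* observed history including the queried month, so the value is
always in [0, 100] and equals 100 at the argmax; an all-zero history returns
0 by convention (avoiding 0/0). The alternative — a max-to-date denominator —
would make early months incomparable across sites; we use the all-time max.
The ratio is computed as `100 · (value / peak)` so the argmax month is
exactly 100 in floating point.

**Rank tables.** Points in scope (a list of ids, a neighborhood code, or
"all") are ordered by a variable's value in one month, descending; ranks are
dense 1..n, ties take consecutive ranks ordered by point id, and points
without an observation that month are excluded and listed separately. Output
is therefore deterministic and invariant to scope order.

**Spike rule.** Month `m` is flagged when

    value(m) > K · (offset + median of all other months' values)

with defaults `K = 100`, `offset = 1`, requiring at least three observed
months. Rationale: FC anomalies are multiplicative (orders of magnitude), so
the threshold scales with a robust location estimate of the rest of the
series; the median resists the spikes themselves; the `+1` offset keeps the
rule meaningful on an all-zero baseline, where any count above 100 is
anomalous. On the three published case-study series the rule flags exactly
the narrated months: one (July 2017) for M13, three (May–July 2017) for S17,
two (May–June 2017) for P1 — and the 855 CFU/100 mL background months at S17
are correctly left unflagged because the median of the remaining series
lifts the threshold above them.

**Rainfall correlation.** Monthly FC (a single point's series or any
pre-aggregated monthly series — how to aggregate across sites is a user
decision, not fixed here) is aligned with monthly rainfall totals (mm) on
common months; Pearson's r is computed by `scipy.stats.pearsonr` after
dropping explicitly excluded months, which are recorded in the result. At
least 3 pairs and nonzero variance in both series are required; otherwise the
correlation is undefined and an error is raised. The exclusion mechanism
exists because a single extreme contamination month can mask (or invert) an
otherwise positive rainfall association.

## Cartographic computations

**Marker styling.** Site categories map bijectively to marker colors:
pipe/cistern yellow, drainage green, ocean blue, combined white.

**Proportional symbols.** Radius = `r_min + (r_max − r_min) · sqrt(v /
v_max)` with defaults 4–20 px: square-root scaling makes symbol *area*
proportional to the value, the standard proportional-symbol convention. If
every value is zero all radii collapse to `r_min`. The focus point is the
unique red symbol; all others are green.

**KDE heatmap.** Each point with an observation contributes a normalized 2-D
Gaussian kernel centered on its location, weighted by the variable value and
truncated at 3 bandwidths (retained mass `1 − exp(−9/2) ≈ 0.9889`).
Intensity is evaluated at cell centers of a north-up grid covering the scope
points' extent padded by 3 bandwidths, so `sum(cells) · cell_area` recovers
the total input weight to within the truncation loss plus a midpoint-rule
error (< 1% at the defaults). Defaults — 50 m bandwidth, 10 m cells — were
chosen to resolve the ~30 m separations between neighboring water points
while keeping a neighborhood grid small. Metric distances come from a local
equirectangular projection about the scope centroid, accurate to well under
a cell at sub-city extents. Weights are the raw variable values by default
(a 3.6×10⁷ count *should* dominate its month); `log_weights=True` switches
to `log10(1 + value)` for displays where the dynamic range hides structure.

**Time slider.** All frames share one grid geometry (the scope's union
extent), so cells are comparable across months and a month with no
observations renders as an all-zero frame. Intensity is on an absolute scale
shared across frames; per-frame renormalization is a display decision left
to the consumer, since it destroys cross-month comparability.

## Interchange formats

CSV (UTF-8, comma, mandatory header, ISO-8601 dates) in three schema files —
`water_points.csv`, `epi_samples.csv`, `env_surveys.csv` — with exact
roundtrip fidelity: coordinates are written `%.6f` (≈0.1 m, and the
synthetic generator emits coordinates already rounded to 1e-6°), all other
floats via `repr`, blanks for absent optional fields. GeoJSON is written
with stdlib JSON (sorted keys, fixed indentation). Shapefile export is a
minimal self-contained ESRI point-layer writer (.shp/.shx/.dbf/.prj, WGS84
in the .prj): DBF field names are truncated to 10 characters with
deterministic `_1`, `_2` … de-duplication, dates are encoded as `YYYYMMDD`
strings, and the DBF header stamp is a constant so identical inputs produce
byte-identical files. All writers are deterministic by construction.

## Synthetic study generator

The original field data are confidential; the generator exists to exercise
the pipeline with realistic structure, not to model Haitian hydrology or
weather. Defaults mirror the deployment: 38 points split round-robin across
the neighborhoods M, S, P; months 2016-10 through 2017-12; one sample and
one survey per point-month.

*Geometry.* Each neighborhood is a compact cluster around a fixed coastal
anchor: consecutive points step 20–200 m in a random direction from the
previous point, with rejection of placements closer than 20 m to any sited
point or farther than 600 m from the anchor — every point's nearest neighbor
lies in the 20–200 m band.

*FC baseline.* Contamination is temporally coherent in real series — a site
is either clean month after month or persistently elevated around a site
level — so the generator draws a per-point regime: ~65% of points are clean
(FC 0 every month); the rest carry a site level `b` log-uniform in [1, 500]
with monthly values `b × U`, `U ~ Uniform[0.5, 2]`, and a 15% chance of a
zero month. Marginally over point-months this yields ≈70% zeros with nonzero
values spanning roughly 1–1000 CFU/100 mL. A structural consequence is that
ordinary variation can never trip the default spike rule at its own site
(`2b < 100·(1 + b)` for all `b ≥ 0`), which is what makes the detector's
zero-false-positive calibration meaningful rather than accidental.

*Spikes.* Injected independently per point-month with probability 0.02, as
`multiplier × (1 + baseline)` with the multiplier log-uniform in [10³, 10⁶]
(the `+1` keeps spikes nonzero at clean sites). Spike months add +3 (capped
at 5) to the water and mud survey scores, emulating the standing-water
conditions repeatedly observed around contaminated sites; ordinary months
draw those scores from {1, 2, 3}.

*Rainfall.* `generate_rainfall` draws monthly totals from a Gaussian
(default mean 120 mm, sd 60 mm) truncated at zero — a stand-in series for
exercising the correlation workflow, not a climatology.

All randomness flows through one `numpy.random.default_rng(seed)` (PCG64)
generator, so a config is reproducible across platforms. The printed
case-study fixtures (`case_study_fixture`) are hard-coded, not generated:
M13 (35,800,000 in July 2017, zero otherwise) beside M1 (all zero, placed
exactly 30 m south), S17's seven published months, and P1's five.

*What passing tests do and do not show.* The generator reproduces the
*structure* the methods rely on — monthly cadence, mostly-zero heavy-tailed
counts, spike/environment coupling, cluster geometry — but not the true
field distributions, spatial autocorrelation of contamination between
neighboring sites, seasonality, or missing visits. Detector sensitivity and
false-positive rates measured on synthetic studies therefore validate the
implementation and its calibration under these stated conditions, not field
performance.

## Numerical conventions and degenerate inputs

- Ties in ranks and in nearest-neighbor distances break by point id.
- `percent_of_max` of an all-zero history is 0; proportional symbols with an
  all-zero month all take `r_min`.
- Missing months are omitted everywhere, never imputed or zero-filled.
- Temporal query intervals are closed on both ends; an inverted interval is
  an empty result, not an error.
- Spike detection refuses series with fewer than 3 observations; correlation
  refuses fewer than 3 pairs or zero variance.
- The published rainfall correlations (−0.098 with the M13 July outlier,
  0.46 without) derive from confidential counts and external rainfall and
  are not reproducible here; the operation is validated against a
  from-scratch Pearson formula to 1e-12 and by reproducing the *direction*
  of the outlier-exclusion effect on synthetic series.

## Known limitations

- Shapefile support is write-only and point-only — sufficient for exporting
  the package's own layers to GIS, by design.
- The heatmap's equirectangular projection is inappropriate above ~city
  scale or at polar latitudes; the intended domain is a settlement.
- The store is in-memory; studies orders of magnitude larger than the
  hundreds of point-months seen here would want a real database.
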