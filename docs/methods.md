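# Methods

`medseas` operationalises the ecosystem-services *cascade* for five marine
and coastal services of a Mediterranean-like basin: every service is scored
by indicators of **capacity** (what the ecosystem could deliver), **flow**
(what people actually receive) and, where meaningful, **benefit/demand**
(what people require), each aggregated to four sub-basins (Western,
Adriatic, Central, Eastern) and three assessment periods, and finally
classified into endpoint trends (increase / decrease / stable / undefined).
The upstream models whose outputs such an assessment would normally consume
(a food-web model, a coupled hydrodynamic–biogeochemical model, a coastal
geographic model, ecological niche models, a recreation model) are emulated
by seeded generators, which is what makes the whole chain testable on a
desktop.

## Indicators

| Service | Capacity | Flow | Benefit |
|---|---|---|---|
| Food provisioning | biomass of pilchard+anchovy (`BM_PA`) and hake (`BM_HK`), t km⁻² | catch of the same species (`Cat`, t km⁻² yr⁻¹); trophic level of the catch (`TLC`) | — |
| Water purification | kinetic energy of surface currents (`EKE`, m² s⁻²) | primary-production nutrient uptake (`PPR`, mmolN m⁻² d⁻¹); sediment detritus burial (`Sed`, mmolN m⁻²) | — |
| Coastal protection | `CPcap` | `CPsup` | `CPdem` |
| Lifecycle maintenance | frequency of favourable spawning/nursery habitat (`BFThab`, `HKhab`, %) | hake recruit biomass index (`HKBMI`, kg km⁻²) | — |
| Recreation | recreation potential (`RPI`, 0–1) | recreation opportunity spectrum (`ROS`, class 1–9) | — |

Definitions used:

* `TLC = Σᵢ TLᵢ Yᵢ / Σᵢ Yᵢ` over retained groups with positive catch,
  pooled over the years of a period (the source indicator is defined for
  "all retained species"; discarded groups enter biomass only).  It is
  invariant to a uniform rescaling of all catches and bounded by the
  extreme trophic levels present.
* `KE = ½(u² + v²)` per cell and time step.  The default `EKE` indicator
  averages total KE; an anomaly variant (subtract the per-cell period mean
  current before squaring) is available via `anomaly=True` because the
  choice of convention is genuinely open — both contracts are tested.
* Coastal protection scores are weighted arithmetic means of min–max
  normalised attributes (capacity: geomorphology, slope, emerged and
  submerged habitat protection; exposure: wave height, storm surge, tidal
  range, relative sea-level rise; demand: residents, artificial surface,
  cultural sites), with `CPsup = CPcap × (1 − CPexp)`.  The exact
  aggregation of the source geographic model is not published at this
  level of detail; the forms chosen here are the simplest ones that are
  monotone in the directions the indicator definitions require, and all
  weights are configurable.  Slope is scored *directly* (flatter coast →
  less protective).  Normalisation pools the three assessment years so
  inter-year trends survive; per-year normalisation is a flag.  A constant
  attribute normalises to 0.5 (midpoint) rather than NaN.
* Habitat suitability is a hard conjunction of closed intervals (SST,
  front index, depth).  The real niche models behind the indicator use
  richer statistics; the conjunction preserves their "met all the
  environmental requirements" semantics and gives an exact brute-force
  oracle.  Frequency = 100 × favourable days / assessed days; missing days
  leave the denominator.
* `ROS class = 3·(level − 1) + zone` with RPI tertile levels (low/medium/
  high) and accessibility zones (remote/proximal/high-access from distances
  to roads and residential areas).  This enumeration is fixed by two
  printed anchors — (medium, proximal) → 5 and a maximum of 9 — and is
  config-overridable since the full published legend is not available.
  Tertile boundary values fall in the lower class.
* Trends: `r = (v₃ − v₁)/|v₁|`; |r| < τ is stable.  τ defaults to 0.05,
  recreation uses 0.01 (sub-1% changes in recreation capacity are treated
  as stable).  The middle period is reported but does not affect the
  symbol.  Indicators sharing a cascade level combine by majority, ties →
  undefined.  A zero baseline falls back to absolute change with a
  warning.  A (service, basin) cell is flagged as a sustainability concern
  when capacity decreases while flow or benefit increases.

## Periods and regions

Decadal model windows are concretised as 1960–1969, 1980–1989, 2000–2009;
coastal protection and recreation use the years 1990/2000/2010; habitat
maps use 2003–05 / 2006–09 / 2010–12.  The recruit-biomass survey series
ends in 2011, so `HKBMI` uses 2003–05 / 2006–08 / 2009–11.

The grid is regular lon/lat with an explicit per-cell area (no spherical
geometry), and the sub-basins are stylised: two longitude splits plus a
rectangular Adriatic carve-out that takes precedence over its longitude
band.  Aggregation is an area-weighted time-mean over unmasked basin
cells; it is linear, and basin aggregates weighted by basin area
reassemble the global aggregate to floating-point accuracy.

## The synthetic scenario generator

Each generator draws from an independent stream of the scenario seed, so a
`ScenarioConfig` determines every output byte-for-byte.  `trend_spec`
injects a relative change between the first and last window (the middle
window sits halfway); noise is unit-mean lognormal for positive quantities
and additive Gaussian for signed ones.  Specifics worth knowing:

* The `eke` trend scales current *speed* by √(1+t) so the kinetic-energy
  indicator changes by exactly 1+t.
* Catch is bounded by `max_exploitation × biomass` in every record, and
  all groups share the `catch` trend, so the catch composition — and hence
  TLC — stays exactly stable unless perturbed by noise.
* Habitat layers encode two species in one SST field through disjoint
  envelopes; per-cell designed favourability probabilities (0.15–0.35 per
  species) are scaled by the `bft_hab`/`hk_hab` trends.  At zero noise the
  favourable-day count is deterministic (rounded to whole days, the only
  place where zero-noise recovery is exact only to within half a day per
  cell); with noise each day is drawn independently.
* Coastal geomorphology and slope are static physiography; habitat scores
  carry the `cp_capacity` trend, oceanographic forcing `cp_exposure`, and
  socio-economic attributes `cp_demand`.  Residents and cultural sites are
  continuous expected counts so injected demographic trends propagate
  exactly.
* Trawl hauls follow the `hk_bmi` trend; the Eastern basin optionally gets
  fewer than five hauls per window, which flags its index unreliable and
  classifies its trend as undefined — by design, not noise.

Default trends are the study conditions: biomass −30%, catch +30%, TLC 0,
kinetic energy +30%, PPR +30%, Sed +10%, coastal capacity −30%, exposure
0, demand +30%, tuna habitat 0, hake habitat −30%, recruit biomass −44%
(the reported mean decline), recreation −0.5% (below the 1% stability
threshold).  These are per-variable scalars applied basin-wide; the
per-basin heterogeneity of the real assessment (e.g. Adriatic sediment
burial rising while other basins fall) is not emulated.

What the generators do **not** reproduce: real bathymetry and coastlines,
river forcing, seasonal cycles, spatial autocorrelation beyond a smoothed
random pattern, inter-indicator correlations, or observation error
structure of trawl surveys.  Passing tests therefore demonstrate that the
indicator pipeline is correct and calibrated — not that the emulated
fields resemble any real basin.

## Verification studies

* **Oracle equivalence** — habitat frequency against a brute-force per-day
  count on 50 random 20×20×60-day scenarios; TLC against explicit-loop
  weighted means on 100 random catch tables.
* **Parameter recovery** — on a reduced grid (8×18 cells, 40 days per
  habitat window, 20 hauls per basin), the 13 indicators with a generator
  dial are injected with ±30%/0% trends.  At zero noise the classified
  symbol matrix equals the injected one exactly; at 5% noise the cell
  agreement over 100 replicate seeds stays above 95% (measured ≈ 99%).
  `CPsup` and `ROS` are derived indicators without a dial of their own and
  are not part of the count.
* **Invariant suites** — score boundedness under 1000 random draws, supply
  monotonicity, envelope anti-monotonicity, trend antisymmetry (reflecting
  the endpoint across the baseline flips the symbol), and the partition/
  reassembly identity at 1e-10 relative tolerance.

Problem sizes (default scenario: 16×36 grid, monthly fields over three
decades, 60 days per habitat window, 12 LAUs, ~38 coastal units) were
chosen so the full pipeline runs in a few seconds while every basin keeps
enough cells for stable statistics.

## Known limitations

* No significance testing of trends (endpoint classification only).
* Recreation ROS is categorical and computed at LAU level; under noise a
  basin-mean class can flicker across the 1% threshold, mirroring the
  scale-sensitivity of the categorical indicator.
* Exposure (`CPexp`) is emitted as a diagnostic column, not an indicator
  row, since it is both a standalone descriptor and an input to supply.
* Monetary valuation, recreation demand, tourism, and carbon
  sequestration/climate regulation are out of scope.
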