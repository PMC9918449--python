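# Methods

This note documents the models in `barleywl`, the choices made where the
design was open, and what the synthetic-data conditions do and do not
establish about real cropping systems.

## Scope and philosophy

`barleywl` is a desk-scale analysis package, not a full farming-systems
model. The waterlogging stress physiology is represented explicitly and
carefully; everything around it (phenology, water balance, growth) is the
simplest defensible process model that exercises that physiology: daily
time step, bucket hydrology, radiation-use-efficiency growth, no nitrogen
cycling (all runs assume non-limiting N so that waterlogging effects are
not confounded), no pests or diseases, and no crop-failure mortality —
intolerant genotypes persist through extended waterlogging with reduced
function rather than dying, consistent with experimental observations of
barley surviving two months of saturation.

## Waterlogging stress functions

**Driver.** `rtfr`, the fraction of the root zone lying in saturated soil
layers, with partial-layer proration. A layer counts as saturated when its
water content reaches `DUL + 0.97·(SAT − DUL)` (the 0.97 band avoids a
floating-point knife edge at exact saturation; configurable via
`StressParams.saturation_fraction`) or when it lies below the water table.
The photosynthesis and phenology pathways are driven by one and the same
`rtfr`; their separately named drivers have identical definitions.

**Indices.** Piecewise-linear in `rtfr`, threshold 0.8:

- `oxdef_photo(rtfr)` = 1 below 0.8, linear to 0 at 1.0;
- `oxdef_pheno(rtfr)` = 1 below 0.8, linear to 0.8 at 1.0.

**Stage modifier** `y_oxdef_lim_pheno(stage)` anchors: 0.65 at stage 4.0 →
0.95 at stage 5.5; 1.0 at stage 6 → 1.5 at stage 10. Measured anchors
start at stage 4.0 and stop at 5.5/6–10; we extend 0.65 flat over stages
[1, 4), close the (5.5, 6) gap with a linear ramp 0.95 → 1.0, and hold 1.5
over (10, 11]. Both extensions preserve continuity at the anchor points
without inventing new extrema and are exposed in `StressParams`. A
stage-dependence hook for the photosynthesis index exists
(`photo_stage_anchors`) but defaults to identity: no published values are
available for it.

**Three-stage response.** A saturation spell (consecutive days with
`rtfr ≥ 0.8`; the counter resets when the driver drops below threshold)
passes through: (1) a lag of `lag_days` (default 3) with no effect — water
supply is unconstrained and soil strength is low; (2) full stress while
oxygen-dependent metabolism is impaired, the index equal to
`oxdef_photo(rtfr)`; (3) adaptation after `lag_days + adapt_days` (default
3 + 10), where the effective multiplier becomes
`max(oxdef_photo(rtfr), floor)` with `floor` the genotype's adapted
photosynthesis level (1 = fully tolerant). No durations are published for
the stages; the defaults make a two-week event span all three, and both
are genotype-overridable.

The **phenology pathway passes through the same three stages**: no effect
during the lag, full effect during stage two, and after adaptation the
residual effect scales with the genotype's unrecovered fraction
`(1 − floor)`. This is a design choice (the available measurements do not
separate the pathways' time courses): adaptation that restores
photosynthetic rates to pre-waterlogging levels is taken to restore normal
development as well. Without this coupling a fully tolerant genotype would
keep accruing phenological delay — and, with unimpaired photosynthesis
over a lengthened season, could *out-yield* its own no-waterlogging run,
which would make the yield-penalty metric negative on stressed seasons.

**Effective thermal-time multiplier on a stressed day.** The stage
modifier sets the full-saturation endpoint and the phenology index sets
how far toward it the day moves: with severity
`s = (1 − oxdef_pheno)/(1 − 0.8)` (0 at the threshold, 1 at saturation),
the multiplier is `1 − (1 − m)·s` before flowering (delay only, applied
when `m < 1`) and `1 + (m − 1)·s` after it (truncation only, `m > 1`).
This form is continuous in `rtfr` at the stress threshold and guarantees
the directional invariants: stressed flowering is never earlier, stressed
grain fill is never longer.

## Simulator

**Phenology.** Eleven stages / ten phases driven by daily thermal time
from a three-point cardinal response on the daily mean temperature (base
0, optimum 26, maximum 34 °C for barley). Phase targets are fixed,
mid-season-barley values except `tt_end_of_juvenile`, which is the
genotype parameter (400 °Cd spring; 400–750 winter). Vernalisation
(`vern_sens`, 0–5) and photoperiod (`photop_sens`, 0–5) multiply thermal
time between emergence and floral initiation:
`f_vern = 1 − 0.0054545·vern_sens·(50 − V)` with V the accumulated vernal
days (cool-day increments up to 1/day, saturating at 50), and
`f_photo = 1 − 0.002·photop_sens·(20 − daylength)²` with civil-twilight
day length from latitude and day of year; the smaller factor applies.
Stage codes are continuous within phases by fractional thermal-time
progress so the modifier anchors (4.0, 5.5, 6, 10) are addressable.

**Water balance.** Daily tipping bucket. Rain above an infiltration
capacity (default 80 mm/day) runs off; water above a layer's drained upper
limit cascades down at up to the layer's saturated conductivity; water that
cannot drain backs up to saturation and then to surface runoff; layers at
or below a static water table are boundary layers held at saturation
(drainage reaching them leaves the accounted store). Potential ET follows
an equilibrium-evaporation form, `1.1·radn·(2.04e-4 − 1.83e-4·albedo)·
(0.6·maxt + 0.4·mint + 29)`; actual ET extracts from the rooted zone (top
150 mm bare-soil before that) in proportion to plant-available water.
Mass balance closes identically each day; the tests assert ≤ 1e-6 mm over
1000 fuzzed days.

**Roots.** Descend 30 mm/day from sowing depth until the start of grain
fill, halted while `rtfr ≥ 0.8` (impeded respiration), and bounded by the
water table and by the first drainage-impeding layer (saturated
conductivity < 10 mm/day): dense clay subsoils both perch water and stop
root exploration, which is what makes duplex soils waterlogging-prone.
Topsoil in the archetypes is discretised into 50 mm layers so that a
draining perched zone desaturates gradually from the surface instead of
flipping a whole thick layer's saturation flag in one day.

**Growth and yield.** Daily biomass = radiation × stage-driven canopy
cover × RUE (1.2 g/MJ) × CO₂ factor × effective photosynthesis
multiplier. The CO₂ factor is a rectangular hyperbola normalised to 1 at
350 ppm with half-saturation 175 ppm (≈ 1.2 at 700 ppm). Yield = biomass
at maturity × potential harvest index (0.48) × mean effective
photosynthesis multiplier over stages 5–7. The reproductive-window
discount encodes the tight coupling of cereal yield to kernel number set
around flowering without an explicit kernel model; it is a deliberate
simplification relative to source–sink crop models. There is no soil-water
deficit effect on growth: the package studies excess water, and drought
response is out of scope.

## Synthetic weather and soils

The weather generator emulates the statistical features the analysis
needs, not any particular site record: two-state Markov rainfall
occurrence (wet→wet persistence produces multi-day wet spells, the driver
of soil saturation), gamma wet-day amounts with the scale set so
`365·P(wet)·shape·scale` equals the target mean annual rainfall and a
sinusoidal seasonal modulation, sinusoidal temperature and radiation
cycles with AR(1) residuals, and fixed wet-day depressions of temperature
(2 °C) and radiation (4 MJ m⁻²) so that rainy days are cooler and dimmer.
Hemisphere is carried by the latitude sign (photoperiod) and the seasonal
phase parameters; a leap day reuses the seasonal values of day 365.

What it does **not** emulate: inter-annual modes (ENSO-like persistence),
extreme-event clustering beyond Markov persistence, cross-correlated
multi-site fields, or observed spell-length distributions. Passing tests
establish that the stress machinery responds correctly to saturation
events of realistic length and seasonal placement — not that penalty
magnitudes transfer to any real site.

Future climates use the monthly delta-change method (additive temperature
offsets, multiplicative rain/radiation factors). Atmospheric CO₂ follows
an empirical SSP585 regression curve over 1900–2100, implemented verbatim
in its published form; because one term of that printed expression is
typographically suspect (a split exponent on the quartic term), the curve
is treated as opaque and a year→ppm table override is provided for
sensitivity work. Under the adopted reading the curve yields ≈ 389 ppm in
2015, ≈ 480 ppm in 2040 and ≈ 773 ppm in 2080, and is increasing over the
projection horizons.

Soil archetypes (`freely_drained`, `duplex_waterlogging_prone`,
`shallow_water_table`) are 6–8-layer templates with seeded multiplicative
jitter preserving `LL < DUL < SAT`. The duplex archetype's clay subsoil
(k_sat ≤ 1 mm/day below 300 mm) is the canonical perched-watertable
setting; the shallow-water-table archetype holds layers below 600 mm
saturated permanently.

## Stress typology

Each completed season is condensed to six phase means of the daily
photosynthesis stress index. The bins are defined on the decimal
(Zadoks-like) growth-stage scale — JV1 [10, 21), JV2 [21, 32), FIN
[32, 65), FL [65, 71), GF1 [71, 80), GF2 [80, 87) — reached from the
continuous 1–11 stage code by a fixed piecewise-linear anchor map
(emergence → 10, end of juvenile → 21, floral initiation → 32, flowering →
65, start of grain fill → 71, end of grain fill → 87). The conventional label
set duplicates "FIN" for both [32, 65) and [65, 71); the second interval
is renamed FL here to keep labels unique. Bins the crop never entered are marked
missing and such (incomplete) seasons are excluded from clustering rather
than zero-filled, to avoid conflating crop failure with a stress pattern.
Cumulated waterlogged-day counts per bin are emitted as companion output;
the phase *means* are the clustering features because the patterns of
interest are stress trajectories.

Clustering is k-means (k = 4 by default) via scikit-learn's Lloyd
algorithm with k-means++ seeding, best of `n_restarts`, seeded and
deterministic; variance explained = 1 − WSS/TSS. Tests pin the partition
to an exhaustive minimum-WSS oracle on 10 points and require ≥ 95%
recovery of four planted archetypes over 400 noisy synthetic seasons.
Clusters are labelled per maturity class (fitted separately for spring and
winter material): ordered by ascending total stress `Σ(1 − centroid)`,
ties broken earlier-onset-first, prefixed SW/WW, with a verbal descriptor
from the earliest phase whose centroid element falls below 0.95
(juvenile bins → early-onset, FIN → mid-season, FL/GF → late-onset).
The 0.95 onset threshold and the ordering rule are package conventions
making the verbal pattern labels computable; both are configurable.

## Factorial pipeline

Every design cell (site × genotype × sowing × scenario × realisation ×
year) is simulated with annual resets at sowing: soil water initialised to
the lower limit plus 15 mm plant-available water filled top-down, 180
plants/m², 20 mm depth, 200 mm rows, no N limitation. Three runs share
identical weather: waterlogging mode on the cell's soil, default mode
(stress functions pinned to 1) for the yield penalty, and waterlogging
mode on a freely drained control soil — the simulation analogue of a
physically drained control plot — for the yield-loss metric. Projection
spread across a GCM ensemble is represented by independent stochastic
weather realisations (default 27) with seeds derived from the master seed
via `SeedSequence`; the whole pipeline is reproducible from that seed.
Growing-season rainfall for the tolerance-benefit percentile split is
accumulated from sowing to maturity of the cell's default-mode run.

Frequency shifts of stress patterns between climate periods are tested by
one-way ANOVA with realisations as replicates followed by pairwise LSD at
α = 0.05 and standard descending-mean letter assignment; a pattern with
zero variance in every period is flagged skipped. Both mean and median
penalties are reported.

## Problem sizes

The shipped miniature study (2 sites × 2 genotypes × 2 sowings × 2
scenarios) is run in the tests at 2–3 realisations × 3–5 years — a few
hundred season simulations — which is ample to exercise every code path
and the directional contrasts (waterlogging-prone vs drained site, winter
vs spring genotype at class-appropriate sowing dates, wet-year vs
dry-year tolerance benefit). Directional contrasts are the intended use
of the synthetic conditions; absolute penalty percentages at the shipped
sites are properties of those archetype conditions only.

## Known limitations

- Bucket hydrology has no upward flow, no Richards-equation dynamics, and
  a static water table; lateral and groundwater processes are absent.
- Yield formation is harvest-index based; no tillering, kernel number or
  grain-weight components, so compensation mechanisms are not represented.
- The phenology stress pathway's three-stage gating (and its scaling by
  genotype tolerance) is a package design choice, stated above, not an
  experimentally pinned time course.
- The stage modifier below stage 4 and between 5.5 and 6 is an
  interpolation convention; measurements only anchor 4.0–5.5 and 6–10.
- No waterlogging mortality: extreme seasons reduce yield but never kill
  the crop, which overstates yield under catastrophic saturation.
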