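# Methods

This note documents the models implemented in `propagule`, the choices made
where the design was genuinely open, and what the synthetic generators do
and do not emulate.

## Spatial arena

The landscape is a pointy-top hexagonal lattice in odd-row offset layout:
columns `spacing` apart (default 10 m), rows `spacing·√3/2` apart, cell area
`(√3/2)·spacing²` = 86.60 m². Cell counts follow
`n_cols = ⌊width/spacing⌋`, `n_rows = ⌊height/(spacing·√3/2)⌋`, which at
15 km × 30 km yields 1500 × 3464 = 5,196,000 cells. Indices are 0-based
`(col, row)`; day indices are 1-based with day 1 = 1 January of simulation
year 1 (a 365-day calendar, no leap days).

Habitat codes: ocean, road, human habitation, bushland/grassland, woodland,
ephemeral flowing water, non-flowing water, other. Derived layers are pure
functions of habitat: water = both water classes; rehydration sites =
terrestrial water margins plus human habitation; breeding margins =
terrestrial cells adjacent to water; foraging habitat = grassland plus human
habitation.

### Synthetic landscapes

Two styles caricature contrasting entry-point settings:

* **packed** — one contiguous disturbed cluster (human habitation disk, a
  permanent waterbody inside it, a grassland verge, one road) in a woodland
  matrix; default footprint 4 km².
* **fragmented** — six habitation patches and four pit lakes (fewer, larger
  patches on small grids, never below three disturbed components) totalling
  9.7 km² by default.

Footprints are capped at 25% of the arena so the generators scale down to
smoke-test grids; the entry point (site1/site2) is always a terrestrial cell
inside the disturbed area, and the packed cluster always contains a
permanent waterbody, so founders arrive within reach of water and breeding
habitat. What these generators do **not** emulate: coastline/ocean, real
road networks, hydrological routing of ephemeral streams, or the actual
geography of any field site — conclusions from them concern the packed vs
fragmented contrast, not any real landscape.

### Rainfall

A tropical savannah wet–dry regime: the wet season is the calendar block
November–April (a config switch to a cumulative-rainfall trigger exists but
the calendar rule is the default). Daily rain is Bernoulli × Gamma(shape 2)
with season-specific parameters, defaults `p_wet = 0.55, mean 12 mm` and
`p_dry = 0.05, mean 2 mm` — chosen once as a caricature of a wet–dry
tropical regime (~1200 mm/yr, almost all in the wet season). The simulator
uses only (a) the wet/dry label and (b) whether rain fell on the day, so
the amount distribution matters little beyond its positive skew.

## Individual-based model

Terrestrial toads are individuals (struct-of-arrays); aquatic stages are
per-clutch cohorts, which makes clutches of ~10⁴ eggs cheap. The daily phase
order is fixed: environment update → aquatic development → behaviour choice
→ movement → spawning → hydration → mortality → ageing/growth. Reproduction
must see post-movement positions; mortality runs late so a same-day spawner
can die without losing her clutch.

Printed life-history values used directly: hatching at 3 days,
metamorphosis at 34–55 days (uniform per clutch), mean maturation 243 days,
fecundity 7675–14,288 eggs linear in female SVL, dehydration at 10% /
death at 40% body-weight loss, introduction SVL ~ Normal(90, 10) truncated
to [70, 110] mm, 50:50 sex ratio, ≤ 1000 m daily movement.

Quantities the source system cites but does not print are set here as
documented assumptions (all config-overridable):

| parameter | default | rationale |
|---|---|---|
| daily water loss | 0.10 of body weight/day | 4 dry days without water kill; forces dry-season water fidelity |
| extreme-dehydration threshold | 0.25 loss | midpoint of the 0.10–0.40 band; at this state only rehydration is attempted |
| perception range | 200 m | order of magnitude of amphibian wayfinding to water/chorus cues |
| movement kernels | exponential; wet 120 m (persistent heading, sd 0.6 rad), dry 25 m (random heading), directed commutes 300 m | wet-season steps longer and straighter; dry-season movement short and local |
| road preference | weight 3 among candidate headings | qualitative "prefers roads" |
| daily mortality | egg 0.05, tadpole 0.02, metamorph 0.01, juvenile 0.005, adult 0.001 | placeholder ladder honouring "eggs highest" |
| egg cannibalism | 0.5/day extra egg removal when tadpoles share the cell | strong larval interference |
| tadpole carrying capacity | 500 per water cell | density-dependence closure (below) |
| breeding propensity | 0.8/day for eligible wet-season adults | explosive breeding onset |
| inactivity | 0.2 wet / 0.5 dry | higher dry-season sheltering |

**Growth and maturation.** SVL follows discrete von Bertalanffy
`svl += k(L∞ − svl)` with `L∞ = 120 mm`, metamorphs at 25 mm, juvenile
threshold 40 mm, adult threshold 70 mm. The base `k` solves
`ln((L∞−25)/(L∞−70))/k = 243` days; individual rates are lognormal
(sd 0.2), so realised mean maturation is ≈ 248 days, within the
calibration band asserted by the tests (±15% of 243).

**Density dependence.** Fecundity of 10⁴ eggs per clutch with fixed daily
mortalities would grow without bound, so the larval stage closes the loop:
tadpoles impose an extra removal on co-located eggs, spawning females avoid
tadpole-rich ponds, and each water cell carries at most 500 tadpoles
(excess culled proportionally). The capacity stands in for the cannibalism,
chemical suppression and resource competition concentrated in natal ponds;
it bounds recruitment per pond per cohort without affecting small
populations.

**Hydration.** On wet-season or rainy days all toads rehydrate ambiently;
otherwise toads on rehydration sites reset to fully hydrated and everyone
else loses the daily fraction. Desiccated toads die deterministically at
the end of the day.

**Mate finding (the Allee mechanism).** A breeding female spawns only if a
breeding adult male is within perception range after movement; otherwise
the attempt fails that day. Females spawn at most once per season
(flags reset at the 1 November wet-season onset); males breed repeatedly.

**Conservation ledger.** Every step reconciles each compartment (eggs,
tadpoles, metamorphs, juveniles, adults) against its inflows and outflows;
any leak raises immediately when validation is on, and the test suite runs
full replicates with validation enabled.

## Scenarios

PS is **per introduction event** (so PN events introduce PS·PN toads); a
`split_total` interpretation is available behind a switch. Later event days
are uniform in (first day, 730] — their spacing is otherwise unspecified.
Each landscape style carries its own entry point (packed ↔ site1,
fragmented ↔ site2) so landscape effects are attributable; runs last 3
years from first introduction or until extinction. Replicate generators
derive from `SeedSequence(base, combo, replicate)` — batches are exactly
reproducible and replicates independent.

The Latin hypercube draws one point per stratum per dimension
(scipy's sampler) before discretisation onto the integer ranges; maximin
optimisation keeps the best of 10 same-seeded candidate designs by minimum
pairwise distance, so it can only improve on the unoptimised design.

## Statistical layer

Binomial GLMs (logit link) are maximum likelihood via IRLS (statsmodels),
with treatment contrasts (reference PN = 1, SE = site1). Degenerate inputs —
single-class outcome, non-convergence, or separation (detected as Wald SEs
above 50, where the observed information has collapsed) — yield a flagged
model with coefficients withheld rather than an exception.

The dynamic series uses a 90-day window advanced 1 day over the 730-day
intro span: windows k = 1..365, window k covering [k, k+89], centre k+44
mapped to day of year modulo 365 — the only construction giving both 365
models and full day-of-year coverage. Windows with fewer than 30 rows
(configurable) or one class are carried with a degenerate flag. Intervals
are Wald on the link scale mapped through the inverse logit (closed-form
testable; matches ribbon-plot practice); profile likelihood is not
implemented. The CI-overlap rule flags two estimates as approximately
significantly different at p ≈ 0.05 when their 95% intervals overlap by
less than half the shorter proximal arm, with the exact half-arm case
reported as "borderline".

Evaluation: McFadden's R² = 1 − ℓ/ℓ₀; stratified seeded 10-fold CV with
threshold 0.5 for class metrics (both choices ours — the original analysis
does not specify stratification or threshold); AUC by the rank
(Mann–Whitney) formulation with ties counted half, cross-checked in tests
against trapezoidal ROC integration; deviance ANOVA with χ² primary and F
reported alongside; binned residuals over ⌊√n⌋ near-equal bins with ±2·SE
bands; Tukey HSD applied by default to replicate-level outcomes grouped by
SE × PN (the grouping is our choice; the source is silent).

## Synthetic outcome tables

`synthdata` samples predictors with the design's marginals and draws
outcomes from a logistic model with an optional sinusoidal intercept term
`A·cos(2π(d − φ)/365)` — seasonality enters through the intercept only, the
simplest structure consistent with time-varying establishment curves (an
interaction with PS is deliberately out of scope). These tables share the
real pipeline's schema but have i.i.d. rows: they cannot emulate
within-replicate trajectory correlation, so tests passing on them validate
the statistical machinery, not the simulator.

## Problem sizes and numerical choices

The test suite and acceptance script use desk-scale arenas chosen as the
smallest that preserve the mechanisms: a 2 km × 2 km packed arena (46,000
cells) for the headline establishment rate (30 replicates, 3 years), a
1 km × 1 km arena for the PS-monotonicity check (60 replicates per PS
level, 2-year runs — establishment outcomes are decided well within two
years of a pre-breeding-season arrival), and n = 18,000 outcome tables
(matching the full study design's row count) for the statistical layer.
The full 15 km × 30 km arena is exercised for geometry and landscape-area
checks only.

Ties in pond choice break by (tadpole count, distance, cell index);
movement snapping uses nearest-centre with a 3-row candidate search;
displacement draws are capped at `max_move − spacing` so the realised
centre-to-centre displacement can never exceed 1000 m after snapping.
Empty populations are a fixed point of the daily step.

## Known limitations

* No energetics, toxins, predators or management actions; foraging is
  always assumed sufficient.
* Tadpoles stay in their natal cell; shoreline foraging is abstracted away.
* The mortality ladder and water-loss magnitudes are placeholders with the
  right ordering, not field-calibrated rates; absolute establishment
  probabilities therefore depend on them, while the qualitative contrasts
  (PS dominance, packed > fragmented at small PS, pre-breeding-season
  advantage) are robust across the ranges we explored.
* Desk-scale arenas compress dispersal distances relative to a real
  15 km × 30 km landscape; between-site contrasts at full scale would need
  full-scale runs.
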