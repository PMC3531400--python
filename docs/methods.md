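# Methods

## Scope and structure

The package implements a deterministic, bottom-up costing pipeline for
scaling up adolescent (10–19) health services in 74 low- and middle-income
countries over 2011–2015:

1. **Registry** (`registry`) — the 74-country table (WHO region, adolescent
   population, HIV prevalence by sex, sexual-activity rates by sex and age
   band, model flags) and the 19-intervention catalogue (need rules,
   coverage ranges, delivery-point shares, package membership), plus the 20
   AFHS quality characteristics.
2. **Need** (`need`) — population projection and population-in-need rules.
3. **Coverage** (`coverage`) — linear baseline→target trajectories and the
   incremental coverage costed each year.
4. **Costing** (`costing`) — ingredients cost-per-case, intervention
   scale-up costs, and programme-activity costs, emitted as an additive
   tidy cost cube.
5. **Scenarios & reporting** (`scenario`) — incremental and from-zero runs,
   the current-spending subtraction, aggregations and per-head metrics.
6. **Synthetic data** (`synth`) — seeded generation of every configuration
   input the engine loads, and a hand-computable toy worked example.

All monetary flows are constant 2008 US$: no discounting and no inflation
adjustment. The analysis takes a provider perspective; patient time and
demand-side costs are out of scope, as is any epidemiological feedback of
scale-up on disease rates (risk is held constant over the 5-year horizon,
so need moves only with population growth).

## Model assumptions and conventions

* **Population projection.** Geometric growth at a constant per-country
  rate: `N(y) = N(2010) · (1+g)^(y−2010)`. No back-projection.
* **Sex/age splits.** The registry reports only 10–19 totals; the default
  split is 50/50 by sex and 50/50 between the 10–14 and 15–19 bands,
  overridable per call. Splits are reconciled by the largest-remainder rule
  for whole-person inputs; fractional populations are split proportionally
  with the residual assigned to the last slice so totals are conserved
  exactly.
* **Need bases.** `all_adolescents` / `condition_share` use the (sex-filtered)
  10–19 population; `female_adolescents` the female half;
  `sexually_active` weights each sex × band slice by its band-specific
  sexual-activity rate; `hiv_positive` weights each sex by its HIV
  prevalence. The configured need share must lie inside the catalogue's
  published range — violations are hard errors, not warnings. Countries
  where a legally required precondition fails (abortion legality, harm
  reduction) contribute zero need for the affected interventions.
  Maternity need is a direct share of female adolescents; no fertility-rate
  sub-model is attempted. The HIV testing and counseling basis defaults to
  `sexually_active`, and the HIV care/ART rows to `hiv_positive` with the
  printed ranges as share bounds; both are configuration, not code.
* **Trajectory anchor.** Coverage equals the baseline at 2010 and the
  target at 2015, so 2011 already carries one fifth of the gap and the five
  costed years sum to 3/5 of (gap × 5). The anchor year is a configuration
  switch (`settings.yaml: anchor_year`) because anchoring at 2011 (first
  costed year at baseline) is equally defensible; 2010 is the default.
* **Clamping.** Baselines at or above the target (e.g. childbirth care
  reported at 98.8% against a 95% target) yield zero increment in every
  year; dis-investment is out of scope.
* **Exclusions.** Six countries (Botswana, DPR Korea, São Tomé and
  Príncipe, Solomon Islands, Turkmenistan, Uzbekistan) are excluded from
  the maternity-care sub-model; Somalia is excluded from programme-activity
  costing. Excluded cells emit no records rather than zero records.
* **Programme activities.** Each activity is a component list
  (item, quantity, unit price) with a scaling driver: `per_country_year`
  (constant), `per_district`, `per_facility` (fixed driver counts from
  `drivers.csv`), or `per_population` (quantity per 1,000 adolescents,
  IEC only — the only programme component that grows with population).
* **Current spending.** The from-zero cube minus the incremental cube,
  cell-wise (provably non-negative), annualized as total/5. The divisor is
  configurable (`annualization_years`).

## Key parameters

| Parameter | Units | Default | Notes |
|---|---|---|---|
| target coverage | fraction | 0.95 (0.50 for OST) | universal-access convention |
| model years | calendar | 2011–2015 | 5 costed years |
| anchor year | calendar | 2010 | coverage = baseline here |
| sex / band splits | fraction | 0.5 each | registry has 10–19 totals only |
| annualization divisor | years | 5 | current-spending summary |
| unit-cost anchors | US$/contact | hospital 15, primary 4, community 1.5 | illustrative |
| price dispersion | CV | 0.3 | log-normal, mean-1 factors |
| growth-rate range | fraction/yr | 0.005–0.03 | synthetic draws |

The registry's `total_pop_2010` and `pop_growth_rate` columns are not part
of the published country table; the packaged fixture carries documented
placeholders (adolescents ≈ 22% of total population, growth 1.5%/yr) and
the synthetic generator draws its own values. Income group (35 low / 39
middle) and the legality flags are configuration columns, defaulting to a
documented assignment and to `true` respectively.

## What the synthetic generator emulates — and what it does not

`generate_config` stands in for the unpublished ingredient lists and the
external service-price and drug-price databases. It reproduces their
*structure*: per-country service unit costs by delivery level (log-normally
dispersed around ordered anchors, hospital > primary > community), one
global price per commodity item, baselines and need shares inside the
published catalogue ranges, and facility/district counts proportional to
population. It makes no claim to reproduce their *values*: absolute dollar
outputs of the model therefore scale with the illustrative anchors and
should be read as demonstrating mechanics, not as policy estimates.
Consequently the tests and the acceptance script validate structural
fidelity and engine properties (oracle equivalence against a naive
summation, conservation under every aggregation, price homogeneity,
population scaling laws, trajectory closed forms, determinism, the
hand-computed worked example) rather than published dollar totals, which
would require the original price inputs. Passing tests show the arithmetic
and bookkeeping are right; they cannot show the price level is right.

## Numerical choices

* Fractional persons and dollars are carried as floats end to end; rounding
  happens only in report formatting. Conservation checks compare at 1e-9
  relative (engine vs oracle, toy vs closed form) and 1e-6 relative
  (aggregation partitions).
* `coverage_at` returns the target *exactly* at the end year (no
  interpolation drift).
* Largest-remainder reconciliation breaks ties by largest fractional part;
  its integer path triggers only for whole-person totals.
* Cube records are sorted on (country, item, kind, year, category) with a
  stable mergesort so identical configurations produce byte-identical CSVs.
* Configuration loading is all-or-nothing: any schema, integrity or
  validation error aborts with no partial output. Imputation of missing
  registry fields averages over *observed* values only (population-weighted,
  regional first, global fallback), which makes it idempotent and keeps
  imputed values inside the observed envelope.

## Problem sizes

The full model is 74 countries × 19 interventions × 5 years plus 5
programme activities per country-year (≈ 15,600 cube cells; a scenario run
takes a few seconds). The test suite exercises the full registry for
structural checks and 5–10-country synthetic configurations for engine
properties; the oracle-equivalence check runs both on a 5 × 3 × 5 subset and
on all 19 interventions. The acceptance script runs the full 74-country
model twice (incremental and from-zero).

## Known limitations

* The ingredient catalogue is illustrative; results are price-table-relative.
* Coverage trajectories are linear by construction; no S-shaped adoption.
* The sex/age split default (50/50/50/50) ignores real cohort structure.
* Income-group membership and legality flags are configuration assignments,
  not derived data.
* Two rows of the printed intervention catalogue carry the same label for
  HIV care; they are disambiguated as `8a` (care/support/OI treatment) and
  `8b` (ART provision). The OI-care row prints no delivery-point shares;
  the packaged catalogue assigns 20% hospital / 80% primary as a documented
  placeholder.
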