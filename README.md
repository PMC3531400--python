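# afhs-cost

A bottom-up, ingredients-based costing model for scaling up
**adolescent-friendly health services (AFHS)** in 74 low- and middle-income
countries over 2011–2015. The package estimates the incremental financial
resources ("the price tag") required to raise coverage of a standard package
of adolescent health interventions — contraception, maternity care, STI
management, HIV testing and counseling, safe abortion care, harm reduction,
HIV care and treatment, and care of injuries from intimate partner violence —
from current levels to universal-access targets, plus the programme-activity
spending (management, training, supervision, IEC, infrastructure) needed to
make services adolescent-friendly.

It is written for health economists and programme planners who need a
transparent, fully configurable and testable implementation of this class of
"global price tag" model.

## The model

For each country *c*, intervention *i* and year *y* ∈ {2011, …, 2015}:

```
cost(c,i,y) = PIN(c,i,y) × Δcov(c,i,y) × CPC(c,i)
```

* **Population in need** `PIN(c,i,y) = E(c,i,y) × s(c,i)`, where the eligible
  population *E* is the 10–19 population projected with constant geometric
  growth (epidemiology is held constant over the horizon), filtered by sex
  and weighted by band-specific sexual-activity rates or sex-specific HIV
  prevalence according to the intervention's need basis, and *s* is a
  per-country need share constrained to the catalogue's published range.
* **Incremental coverage** `Δcov(c,i,y) = max(0, cov(c,i,y) − b(c,i))`, with
  coverage rising linearly from the 2010 baseline *b* to the target (95%,
  or 50% for opioid substitution therapy) in 2015. Baselines above the
  target are clamped to zero increment.
* **Cost per case** `CPC = Σ quantity × price` over ingredient lines:
  commodity lines (drugs, lab tests, medical supplies) at global prices, and
  service-delivery lines (visits/contacts) priced per country and delivery
  level, weighted by the intervention's fixed hospital/primary/community
  delivery shares.

Programme activities are costed per country-year, per district or per
facility from component lists; only IEC scales with the adolescent
population. Six countries are excluded from the maternity-care sub-model and
Somalia from programme-activity costing. Results form an additive **cost
cube** (country × item × year × cost category, constant 2008 US$) that can
be aggregated by year, WHO region, intervention group, cost category or
income group, and expressed per adolescent and per capita.

Running the model a second time from 0% starting coverage and subtracting
the incremental run yields an estimate of **current spending** on the
service package (reported as total difference / 5 years).

The detailed ingredient quantities and unit prices used in the original
exercise live in external databases and are not published; the package ships
an explicitly illustrative ingredient catalogue and a synthetic-data module
that generates complete, internally consistent configurations (prices,
baselines, need shares, drivers, demographics) from a seed.

## Worked example

The packaged toy configuration (2 countries, 2 interventions, 3 programme
activities) is small enough to check by hand or in a spreadsheet:

```python
from pathlib import Path
import afhs_cost as ac

cfg, expected = ac.make_toy_worked_example(Path("toy"))
inc = ac.run_scenario(cfg, "incremental")
fz = ac.run_scenario(cfg, "from_zero")

print(ac.per_head_metrics(inc.cube, cfg).to_string(index=False))
print(ac.aggregate(inc.cube, ["cost_category"], cfg).to_string(index=False))
spend = ac.current_spending(inc, fz)
print("current spending / year:", ac.annualized_total(spend))
```

prints

```
 year     total_usd  per_adolescent_usd  per_capita_usd
 2011 234972.000000            0.778053        0.166647
 2012 326318.880000            1.073276        0.229770
 2013 419081.846400            1.369008        0.292940
 2014 513303.203904            1.665254        0.356160
 2015 609026.382970            1.962018        0.419428
   cost_category       amount  share_pct
     commodities 3.321688e+05  15.797234
       programme 7.280812e+05  34.625977
service_delivery 1.042452e+06  49.576789
current spending / year: 129585.19903296
```

Reading the 2011 row: scaling both toy services one fifth of the way from
their baselines towards 95% coverage, plus the programme activities, costs
US$ 234,972 — US$ 0.78 per adolescent and US$ 0.17 per capita across the two
toy countries. The engine cube equals the committed closed-form cube to
1e-9 (`tests/test_synth.py`).

The same pipeline is available from the shell:

```sh
afhs-cost synth --seed 5 --out cfg        # synthetic 74-country configuration
afhs-cost run --config cfg --mode both --out out
afhs-cost report --cube out/cube_incremental.csv --config cfg \
    --by intervention_group --per-head
```

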