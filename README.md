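# farmburden

Estimating the direct economic burden of unintentional injury on
Australian farms: on-farm fatality costing with the human-capital
approach, workers' compensation claims aggregation, and the statistical
disclosure-control conventions (small-cell suppression, complementary
masking, multiple-based rounding) under which such surveillance results
are published.

The case-level sources this kind of analysis runs on — coronial fatality
records and the national compensation claims data set — are
access-restricted, so the package ships a synthetic-registry generator
whose marginal structure matches the published summary tables for
2013–2023 (≈748 fatalities, ≈5,000 claims/year). Every downstream stage
is therefore fully testable without restricted data. It is intended for
injury epidemiologists and health economists who need a reproducible,
configurable version of this costing pipeline.

## The model

Each fatality is valued in base-year (2023) dollars as

```
cost = PV(future earnings) + PV(household production)
     + friction + fixed direct costs + compensation·1[work-related]
```

where, for a decedent of age *a*, sex *s*, occupation-matched annual
earnings *w* and discount rate *r*,

```
PV(earnings)  = Σ_{t=1..H}  w · FTE(a+t) · (1+r)^(−t),   H = ⌈e(a,s)⌉
PV(household) = Σ_{t: 16 ≤ a+t ≤ E_s}  v_h · (1+r)^(−t)
friction      = 0.25 · w
```

with *e(a,s)* the remaining life expectancy from the life table, the
retirement trajectory FTE = 0.9 to age 71 declining linearly to 0.5 at
75 and 0 from 76, household production *v_h* accruing from age 16 to
*E_s* = 76 (men) / 82 (women), and nominal amounts CPI-indexed to 2023.
Claims are aggregated by severity (minor = 0–4 days lost, serious = 5+
days), reporting period (2013–14 to 2016–17 vs 2017–18 to 2021–22),
agency of injury, and year, with annual means, integer percent shares
and pooled medians. An under-coverage uplift (×1.4 by default, since
workers' compensation covers only ~58% of the farm workforce) scales
annual claim costs to a workforce-wide figure.

Published cross-tabs are masked before release: counts of 1–4 become
`np`, a complementary cell (or, where necessary, a line total) becomes
`+` so that no suppressed value is recoverable by subtraction — backed
on small tables by an exact enumeration audit — and visible values are
rounded to a configured multiple at render time only.

## Worked example

```
$ farmburden demo --seed 1 --out demo_report
```

generates both registries at publication scale (748 fatalities, 44,780
claims over nine financial years), values every case, and writes the six
summary tables plus `case_costs.csv`, `run.log` and a `report.json`
manifest. The log for seed 1 reads:

```
INFO seed=1 config_hash=db32a18abd1539b8 version=0.1.0
INFO simulated 748 fatality cases
INFO simulated 44780 claims
INFO cohort fatality cost: $1575726478 total, $143247862/year over 11 years
```

i.e. with the packaged placeholder parameters the synthetic cohort costs
≈$1.58B over 11 years (≈$143M/year); the published analysis, with its
restricted inputs, reports ≈$1.8B (≈$164M/year). The rendered agent
cross-tab shows the masking conventions in action:

```
category,non_work,work,unknown,Total
farm_vehicles/quad,26,86,0,112
...
farm_structures/water_tank,5,7,0,12
farm_structures/other_shed,0,np,0,+
```

(the `other_shed` work-related count was 1–4 so it is suppressed, and
because nothing else in that row can absorb a complementary mask, the
row total is withheld instead). The serious-claim medians table lands on
the published calibration targets — pooled median 6.3 weeks and ≈$11,970
against the published $11,750:

```
$ farmburden verify
[PASS] work_related_share_pct: expected 73, computed 73
...
12/12 checks passed
```

`verify` replays every piece of arithmetic connecting the published
summary values: the 73%/94%/52% shares, all eight divide-and-round
age-band averages, the severity and agency annual means under nearest-5
rounding, the weeks/cost table sums, the annualised $164M and the
coverage-scaled $265M/year.

## Acceptance script

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs the full pipeline from scratch at the given seed (simulate →
cost → tabulate → mask → render) and the twelve-check verifier, failing
on any error; the JSON output is written on success.

## Layout

- `farmburden.synthetic` / `farmburden.registry` — registry generation and CSV persistence
- `farmburden.costing` / `farmburden.params` — the human-capital valuation engine and its configuration
- `farmburden.disclosure` — suppression, complementary masking, rounding, rendering
- `farmburden.tabulate` — the six summary-table builders
- `farmburden.verify` / `farmburden.pipeline` / `farmburden.cli` — the arithmetic verifier and orchestration

See `docs/methods.md` for the modelling assumptions, parameter defaults
and known limitations.
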