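# Methods

This note records the modelling assumptions, parameter defaults and
numerical choices behind the package, and what its synthetic data do and
do not establish.

## Fatality costing (human-capital approach)

A premature death is valued as the discounted stream of the decedent's
forgone market earnings and non-market household production, plus
one-off direct costs. Pain, suffering and grief are deliberately outside
the method, as is any willingness-to-pay valuation; estimates are
therefore conservative.

**Earnings.** Annual gross earnings are matched to the recorded
occupation code by longest prefix against the earnings schedule, falling
back to `default_earnings` ($65,000). The stream runs over the remaining
life expectancy at death (horizon = rounded-up expectancy; the
fractional final year is dropped), scaled by an age-dependent FTE
trajectory: 0.9 FTE from labour-force entry (16) to age 71, declining to
0.5 by 75 and 0 from 76. Between the stated anchors (0.9 at 71, 0.5 at
75, 0 at 76) we interpolate linearly — so 0.8/0.7/0.6/0.5 at ages
72–75 — with a step-function alternative available via
`fte_interpolation`. Children below entry age earn nothing now but still
accrue future earnings from entry age onward, which is why the youngest
age band carries substantial costs. Earnings are flat in real terms (no
wage-growth term).

**Household production.** A flat annual value (`hp_annual_value`,
default $25,000/year) accrues for every future year in which the
decedent would have been between 16 and the sex-specific end age — 76
for men, 82 for women, inclusive — discounted like earnings. The same
value applies at every age and to both sexes; only the window differs.

**Friction.** Employer disruption in the year of death is 25% of one
annual salary (`friction_fraction`).

**Fixed direct costs and compensation.** Funeral, coronial,
investigation and emergency-response components, plus a lump-sum
compensation payout applied only to work-related deaths. Their
magnitudes are not published; the shipped defaults (totalling $50,000
fixed, $600,000 compensation) are clearly-labelled placeholders in
plausible Australian ranges, all flowing from configuration.

**Discounting and indexation.** The discount rate is configurable
(default 3%/year, the conventional choice in human-capital costing; 0%
and 5% are the usual sensitivity bounds, and the zero-rate limit is
checked in closed form by the tests). Parameter amounts are treated as
nominal in the year of death and re-expressed in 2023 dollars with an
approximate Australian all-groups CPI series.

**Life table.** The official period life tables are licensed outputs we
do not redistribute. The packaged default is a *synthetic* Gompertz
life table (force of mortality A·e^(0.095·age)) calibrated to life
expectancies at birth of 77.8 (male) and 82.8 (female); any real life
table can be supplied through the parameter file.

**Annualisation and coverage.** Cohort totals are divided by the number
of observation years (11 for fatalities) and rounded at report time.
Annual claim costs can be scaled for the ~42% of the farm workforce not
covered by workers' compensation; the default convention is the
multiplicative ×(1 + 0.4) uplift used in the published arithmetic
(190 → 265 under nearest-5 rounding). The stricter alternative — divide
by the covered fraction, an uplift of 1/0.58 − 1 ≈ 0.724 — is available
via `coverage_factor_from_fraction`.

## Claims model

Claims carry a financial-year label (opaque ordered category; no date
arithmetic), a severity derived from days lost (serious = 5+ days,
i.e. ≥ 5/7 calendar-week equivalents), four category axes (agency,
nature, mechanism, bodily location), weeks lost and cost. Reporting
periods are 2013–14 to 2016–17 (four years) and 2017–18 to 2021–22
(five, the last provisional); cost and time data cover eight years.
Annual means are computed from unrounded totals and rounded once at
render — the published tables' own means show they were computed before
rounding, which is why printed sub-totals can disagree with their cells
by up to one rounding unit (and, in one row of the published agency
table, are internally inconsistent; that row is documented, not
reproduced). Pooled medians are medians of the pooled claim-level
values, not means of yearly medians.

## Synthetic registries: the stated world

The generator emulates the published margins, nothing more:

- fatality work status 544:203:1 (work / non-work / unknown), agent
  totals exactly as published for all 33 agent categories, age bands
  87/61/68/72/99/125/236, 94% male among work-related cases (the
  non-work sex mix, 80% male, is a documented default — the source is
  silent);
- claim volumes at the published annual means (5,045/year then
  4,920/year), serious shares 0.540/0.585 by period, agency shares from
  the published period totals, and soft narrative targets for nature
  (top three ≈75%), mechanism (top three ≈75%) and bodily location
  (upper limbs ≈38%, top four >90%);
- serious-claim weeks lost: lognormal truncated below the severity
  threshold, σ = 1.6, location calibrated numerically (Brent's method on
  the truncated-median equation) so the truncated median equals the
  published 6.3 weeks; minor-claim weeks uniform on [0, 5/7);
- cost = base × weeks^1.0 × lognormal(0, 0.94) noise, base set so the
  serious median is $11,750. The two dispersions were chosen once so
  that annual weeks (~60k) and annual costs (~$190M across ~5,000
  claims) sit near the published scale and serious claims carry ~95% of
  cost; the convolution of the (slightly skewed) truncated weeks
  distribution with the noise shifts the realised cost median a few
  percent above the target, which the ±15% test band accommodates.

Axes are sampled independently (sex conditionally on work status), ages
are uniform within bands (the open band truncated at 95), and years are
uniform — no secular trends, no agent–age correlation, no jurisdictional
structure. A green pipeline test therefore establishes the correctness
of the aggregation, costing and masking arithmetic, not epidemiological
realism, and the synthetic cohort's dollar totals depend on the
placeholder parameters above, so they are near, not equal to, the
published $1.78B.

## Disclosure control

Threshold suppression marks counts of 1–4 as `np`; zeros stay visible
(the published tables print them). Complementary masking applies a
declared rule — the source does not state its own, and several schemes
are consistent with the published `+` placements: in any row or column
whose only masked cell is an `np` and whose total is visible, mask the
smallest visible cell with count ≥ 5 (ties broken by category order,
minimising information loss), repeating to a fixpoint; where no cell can
absorb the mask, the line total itself is withheld, as the published
agent table does for its sparsest row. Because line-local rules cannot
defeat joint row+column+grand-total inference in general (a row of
suppressed cells whose visible total forces every cell, say), an exact
recoverability audit — depth-first enumeration of all integer
completions consistent with the visible cells and totals, with
column-capacity pruning and a node budget — runs on small tables and
masks further cells or totals until no suppressed cell is uniquely
determined. The audit is off by default for the full-size agent
cross-tab, where the budget would bite; the heuristic alone applies
there.

Rounding is to the nearest configured multiple (counts and annual means
to 5, monetary averages to 5,000, narrative grand totals to 5,000,000 —
all inferred from the printed values and configurable), with ties
rounded away from zero. The source itself rounds ties inconsistently
(147.5 → 145 in one row, 1107.5 → 1110 in another), so tie cells are
excluded from the arithmetic checks. True totals are kept internally;
masking and rounding are applied only at render.

## Numerical choices and degenerate inputs

- `percent_share` uses exact rational arithmetic (no float round-trip)
  with half-up rounding.
- Empty age bands report an absent average, never zero; years with no
  serious claims yield no median row.
- Registry parsing fails on the first invalid row, naming the 1-based
  line number and the offending value; severity must be consistent with
  weeks lost.
- Generation and file output are fully deterministic given the seed; the
  claims stream uses seed + 1 so the two registries are independent.

## Known limitations

- Earnings, household-production value, fixed direct costs and the
  compensation payout are placeholders; absolute dollar outputs are
  illustrative until real parameter tables are supplied.
- The complementary-masking rule is a declared convention, not a
  reconstruction of the source's; the exact audit guarantees
  non-recoverability only where it runs (small tables).
- No rate denominators (per-worker or per-hour rates), no inferential
  statistics or trend tests, no record linkage, and no modelling of the
  costs the human-capital method excludes by construction.
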