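# Methods

## Model

`oralforce` implements a needs-based workforce planning simulation for oral
health care: a deterministic comparison, per calendar year of a planning
horizon, between the full-time-equivalent (FTE) supply of dentists and the
FTE requirement implied by population need. "Need" is operationalised as
survey-observed service utilisation — per-capita annual dental visits by
visit type — held constant per stratum over the horizon and scaled by
demographic projections.

### Supply

The stock of registered practitioners follows an annual recursion: the
stock at the end of year *t−1* plus inflows (foreign-trained entrants,
returning domestic qualifiers, returns from absence), plus the new graduate
cohort, minus outflows (emigration, absence, retirement/death). "Stock at
the end of year *t*" and "stock at the start of year *t+1*" are the same
number; no intra-year timing is modelled and the stock is a single
aggregate (not age-structured). Headcounts are floats throughout; rounding
to whole practitioners happens only in the reporting layer.

Graduates from the cohort entering in year *y* arrive at the end of year
*y + course_length* (default 5). Under a constant pipeline the projection
adds the same cohort size every year:
`intake × (1 − nonprogression_y2) × (1 − attrition) × domestic_share`.

Flow assumptions are given per year; years without an explicit entry reuse
the last specified earlier year (carry-forward), the minimal assumption
when future flows are "based on" observed ones. A horizon year earlier than
every specified flow year is a configuration error; an entirely empty flow
schedule means zero flows. If outflows would drive the stock negative it is
floored at zero with a logged warning — conservation is deliberately broken
at the floor and the round-trip property holds only when no flooring
triggers.

FTE supply = stock × participation rate × activity rate. The activity rate
for a share *s* of part-timers working fraction *f* of full-time hours is
`(1 − s) + s·f`; defaults are participation 0.95 and s = 0.30, f = 0.50
(activity 0.85).

**Register diffing.** Flows can be estimated from two consecutive register
snapshots (columns: registrant id, date registered, year qualified,
qualification origin). Entries only in the later snapshot are inflows:
foreign-qualified → foreign-trained; domestically qualified with
qualification year strictly after the earlier snapshot year → new-graduate
inflow (the generator plants graduates qualified in the later year, so any
reasonable cut-off recovers them); otherwise → returning domestic. Entries
only in the earlier snapshot are outflows; their subtype is not
identifiable from the register, so they are reported as one unclassified
count, with an optional heuristic counting those qualified ≥ 41 years
before the later snapshot (hence aged ≥ ~65) as presumed retirements.
Conservation `n_later = n_earlier + inflows − outflows` holds by set
arithmetic.

### Need

Survey microdata are stratified by sex × age band (15–44, 45–64, 65–74,
75+; bands inclusive at the upper edges, partitioning ages 15 and over),
optionally refined by oral-health status (natural-teeth category ×
food/pain problem). Respondents under 15 and records missing core fields
are dropped with logged counts; there is no imputation.

Each respondent contributes an annual visit count: 0 if they did not visit
a dentist in 12 months, otherwise the count their ordinal frequency
category maps to. The survey does not define that mapping, so it is an
explicit parameter (default once → 1, twice → 2, three-or-more → 3.5, a
conventional midpoint-style top-code) echoed into all output metadata —
results are directly proportional to it within each category.

Per stratum, the total per-capita rate is the (optionally weighted) mean of
respondent visit counts. The survey records only the *most recent* visit's
type, so the stratum-level distribution of last-visit type among visitors
is applied to all of the stratum's visits; the three type-specific rates
sum to the total exactly. Estimation is unweighted by default (weighted by
flag), invariant to record order and to uniform weight rescaling. Strata
with no respondents are flagged undefined (NaN), never silently zeroed; the
caller pools or zero-fills explicitly (`NeedRates.zero_filled()`).
Health-status cells are computed on request, but the requirement
calculation aggregates over health status within sex × age band, because
population projections carry no tooth-count dimension and health status is
held constant over the horizon anyway.

Uncertainty: a percentile bootstrap resamples whole respondent records with
replacement within each stratum (strata are design cells, so their sizes
stay fixed), re-running the estimator per resample. It is implemented with
vectorised positional resampling per stratum — algebraically identical to
resampling DataFrame rows, verified in tests — and is deterministic per
seed. A simulation study in the test suite shows nominal 95% intervals
covering generator truth ≥ 90% of the time at n = 2000, B = 500.

### Requirement

For year *t*: visits(stratum, type) = persons(stratum, *t*) × rate(stratum,
type); minutes = Σ visits × minutes-per-visit (defaults 20 check-up, 30
routine, 40 emergency); FTE requirement = minutes / annual capacity.
Capacity = weeks × hours/week × clinical fraction × adult-care share × 60
(defaults 45 × 39 × 0.9 × 1.0 = 94 770 min ≈ 1579.5 h, reported as 1580 h).
Time spent on patients outside the modelled 15+ population (children) is
handled as the capacity multiplier `adult_care_share` rather than by
subtracting child visits — the survey covers adults only, so child visits
are unobservable, while a time share is a defensible practitioner-level
assumption; `adult_care_share = 0.8` multiplies the requirement by exactly
1.25. Population years between provided table years are linearly
interpolated per stratum; extrapolating beyond the table is an error.

The requirement is linear in population and in each per-capita rate,
monotone in service times, additive across strata and inversely
proportional to capacity; the test suite asserts these identities.

### Projection and scenarios

A run composes the components per year and reports stock, FTE supply, FTE
requirement, and their ratio computed from unrounded FTEs (rounding only at
display: whole FTEs, ratio to one decimal, ties away from zero — this
avoids compounding printed-rounding artefacts). The ratio is NaN, flagged
rather than zeroed, in any year with zero requirement.

Scenarios are named partial overrides addressed by dotted paths
(`service_times.minutes_emergency`, `capacity.adult_care_share`,
`flows.<year>.<component>`); unknown paths are rejected by name, and the
baseline object is never mutated, so re-running the baseline after any
scenarios is bit-for-bit identical. `reference_scenarios()` provides the
three standard sensitivity analyses: longer chair times (30/40/60 min), a
20% child-care time share (capacity × 0.8), and both combined.

## Synthetic data

The generator emulates the three external inputs with known ground truth:
survey microdata (stratum membership multinomial in base-population shares;
visiting Bernoulli per stratum; frequency and last-visit type categorical
per stratum; ages uniform within band; health-status variables drawn
independently of service use), population tables (per-stratum compound
growth), and register snapshot pairs with planted inflow/outflow counts. A
single integer seed drives independent derived streams per artefact, so
regenerating one dataset never perturbs another; generators are pure
functions of (truth, size, seed).

Default truth (synthetic, chosen once for plausible magnitudes — no claim
of matching any real country): eight sex × age-band strata; visit
participation 0.42–0.68, higher for women and the middle-aged; a
check-up-heavy visit-type mix shifting toward routine/emergency care with
age; frequency mix 0.48/0.34/0.18 over once/twice/three-or-more; adult
population ≈ 3.8 M with growth 0.2%/yr (15–44) to 1.1%/yr (65+); planted
register flows (35 graduates, 40 foreign, 10 returning, 60 outflows) sized
for a register of ~3000.

What passing tests on these data do and do not show: they verify the
estimator's statistical correctness (consistency, unbiasedness within
Monte-Carlo error, bootstrap coverage) and the pipeline's arithmetic
end-to-end, under clean independent sampling. They do not exercise complex
survey designs (multistage PSUs, post-stratification weights), item
non-response, respondent misreporting, or morbidity trends — so agreement
here does not certify estimates from a real survey export, only that the
machinery computes what it claims.

## Numerical and design choices

- All internal arithmetic in float64, no intermediate rounding; type-split
  rates sum to totals to 1e-9, stock-flow conservation asserted to 1e-9.
- Reporting rounds half away from zero (printed-figure convention).
- Empty survey strata: flagged undefined; downstream use of an undefined
  rate for a populated stratum is an error, not a silent zero.
- Bootstrap with B = 1 degenerates to a point interval by design.
- The frequency mapping default (3.5 for "three or more") is a top-code
  choice; absolute requirement levels scale with it, which is why it is a
  first-class config field recorded in output metadata.
- Config defaults equal the reference baseline (service times 20/30/40 min,
  45 wk × 39 h × 0.9 clinical, participation 0.95, part-time 0.30 at 0.50,
  horizon 2017–2050, initial stock 3053), so an empty config is a valid
  baseline run.
- Test problem sizes: survey recovery at n = 50 000; bootstrap coverage at
  100 replicates × n = 2000 × B = 500; the end-to-end expectation check at
  12 replicates × n = 8000 — sizes at which Monte-Carlo error is small
  relative to the tested effects while the full suite stays fast.

## Limitations

- Need is proxied by observed utilisation from a cross-sectional survey;
  unmet need and cosmetic demand are out of scope.
- Health status per stratum is held constant over the horizon, which likely
  overstates future requirement as oral health improves.
- The stock is a single aggregate: no age structure, so retirement waves
  are visible only through the flow assumptions.
- All care is attributed to dentists; skill-mix substitution (hygienists,
  therapists) is not modelled.
- Outflow subtypes from register diffs beyond the retirement heuristic
  require auxiliary data the register does not carry.
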