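# Methods

## Model overview

`caresim` is a discrete-time stochastic microsimulation. A base population of
individual records (one row per person: sex, age in months, education,
occupation, smoking, BMI class, physical activity, eight chronic diseases,
vision and hearing impairment, MMSE/cognition, physical dependency, residence,
sampling weight) is advanced in monthly steps from January 2014 to December
2042. Within a month, each *stochastic* characteristic — everything except
age, sex, education and occupation, which never transition — is updated in a
fixed order; then mortality is applied; then survivors age one month. A
characteristic changes state when its monthly transition probability strictly
exceeds a Uniform(0,1) draw.

Key structural assumptions, all standard for this model class:

* **Stationary transition models.** The per-characteristic logits estimated
  from a single two-wave panel apply unchanged over the whole horizon. Cohort
  effects enter only through the risk-factor profiles that younger entrants
  carry with them as they age into 65+.
* **One severity step per month.** Ordered characteristics (BMI class,
  activity, vision, hearing, cognition, physical dependency) move to an
  adjacent level only; the monthly clock still allows rapid multi-step
  progression within a year. Worsening is offered before recovery within a
  month, and at most one move per characteristic per month is applied.
* **Recovery** is modelled to the next less severe category for low, medium
  and high physical dependency, mild and moderate cognitive impairment,
  depression, and vision and hearing impairment. Severe cognitive impairment
  and the seven other chronic diseases are absorbing.
* **Cognition is kept out of the dependency state.** Physical dependency is
  simulated without cognitive impairment; the reported interval of need is
  `max(physical, high if cognition is severe else independent)`, applied at
  snapshot time. This avoids double-counting cognition, which is both a
  dependency criterion and a transition covariate.
* **Dementia is allocated, not simulated.** Dementia status is drawn per
  output-year snapshot from a probability table indexed by age group, MMSE
  category and residence, and is excluded from every transition model. No
  other field is touched by the allocation.
* **No new entrants.** A 35+ base in 2014 fully covers the 65+ population to
  2042 (someone 65 in 2035 was 44 in 2014); migration is out of scope.
* **Care-home residence is fixed** over the simulation; no residence
  transition model is estimated.

## Interval of need

Dependency is graded by the frequency of care required: high (24-hour care),
medium (help at regular times daily), low (help less than daily), independent
(free from care). Two item dialects are implemented: a *full* dialect with
proxy-interview items and an MMSE rule (score 0–9 alone implies high
dependency) and a *brief* self-report dialect. Rules are evaluated high →
medium → low, first match wins; incontinence contributes only through the
conjunction "incontinent **and** needs help putting on shoes and socks" (or,
in the full dialect, with proxy-reported dressing help), never alone. An
individual is classifiable at level L whenever an L-rule fires even if other
items are missing; *independent* additionally requires every dialect item
observed, otherwise the record is unclassifiable rather than independent.
MMSE bands are severe 0–9, moderate 10–20, mild 21–26, normal 27–30.

## Transition estimation

For each registered transition (38 in the default registry) a weighted
logistic regression of "state changed to the target level at follow-up" on
baseline covariates is fitted to the pooled panel with statsmodels GLM.
Age (years − 65), its square (/100) and sex enter every model; physical
dependency models add disease count, any cognitive impairment and low
education; cardiometabolic incidence models add smoking, obesity and low
activity. Study weights are normalised to mean one — making fits invariant
to uniform weight rescaling — and treated as probability weights: point
estimates from the weighted score, standard errors from the HC1 sandwich
(per-observation scores carry the weight). Individuals lost to follow-up are
excluded from fits; attrition in the generator is missing-at-random given age
and sex, both of which are always covariates. Transitions with fewer than 50
at-risk individuals, zero events, or separation-degenerate estimates raise
(or, in the fit-everything driver, are skipped with a warning and treated by
the engine as structural zeros — recovery from severe sensory loss is the
typical casualty at small panel sizes). A characteristic with *no* model at
all is a configuration error.

**Probability rescaling.** The estimation window (2 years) and simulation
step (1 month) are bridged under a constant-hazard assumption:
`p_month = 1 − (1 − p_biennial)^(1/24)`, so 24 independent monthly draws
recompose the biennial probability exactly; annual survival becomes monthly
as `s^(1/12)`. Whether an embedded multi-state (matrix) conversion would be
preferable is an open question; the root form is the standard scalar choice
and is exact for the two-state case.

## Synthetic data generator

The generator stands in for three pooled longitudinal studies, a national
population margin, a projection lifetable and a dementia prevalence table.
Everything is parameterised by a single serialisable `GroundTruthParams`
object written beside each dataset, enabling exact parameter-recovery tests.

* **Studies.** Three extracts with entry ages 35+, 50+ and 65+ and default
  sizes 16 000 / 5 200 / 3 200, with lognormal study weights — a desk-scale
  stand-in for a pooled national panel, roughly 1:1.7 of the real studies
  such a model would pool. Baseline characteristics follow logistic age-sex
  gradients chosen to resemble an English mid-2010s adult population
  (hypertension and arthritis common and steeply age-graded, depression
  commoner in women, sensory/cognitive impairment and dependency rising
  sharply after 75, care-home residence concentrated in the very old with
  high dependency or severe cognitive impairment). Follow-up states are drawn
  from the ground-truth 2-year logits evaluated on the baseline frame — the
  exact estimand of the transition fits. Attrition defaults to 10%,
  missing-at-random given age and sex.
* **Base population.** Study baselines are pooled and raked by iterative
  proportional fitting (tolerance 1e-10, 100-sweep cap) to age-band × sex
  margins — a full cross converges in one sweep; separate age and sex margins
  are also supported. Weights are then cloned to unit records with
  round-half-to-even, and a simple random sample (default 1% of ~3 million
  represented, i.e. ~30 000 records) forms the base population; the implied
  scale factor back to population units is recorded in the generate manifest.
* **Lifetable.** Gompertz–Makeham hazard `c + a·e^{b(x−35)}` with sex-specific
  level (defaults `a` = 8.5e-4 men / 5.5e-4 women, slope 0.093, background
  3e-4), integrated exactly to annual survival for ages 35–105. Defaults give
  period LE at 65 of ≈18.3 y (men) and ≈21.9 y (women). The table is static:
  no mortality improvement over calendar time is generated, so simulated
  period LE is flat across output years and health-expectancy *changes*
  reflect prevalence dynamics only.
* **Dementia table.** Allocation probabilities by age group (35–64, 65–74,
  75–84, 85+) × cognition band × residence, monotone in age and severity,
  shifted up one logit unit in care homes.

**What passing tests do and do not show.** The generator produces marginally
realistic, internally consistent data with known truth; it does not emulate
item-level questionnaires, study-specific measurement error, informative
attrition, residence dynamics, calendar trends in incidence, or the full
covariance structure of real cohorts. Green oracle and recovery tests
demonstrate that the machinery (classification, estimation, rescaling,
simulation, reporting) is correct — not that its outputs forecast any real
population.

## Numerical choices

* **Randomness** is counter-based: each (run, month, stream) triple seeds its
  own Philox generator (stream = one transition model, mortality, or the
  dementia draw), with uniforms indexed by individual position. Results are
  byte-identical for a master seed and independent of iteration order over
  individuals. Uniform draws are made for the whole population each stream,
  so masks never shift the stream alignment.
* **Update order** within a month: behaviours → diseases → sensory →
  cognition → physical dependency → mortality, with within-month updates
  visible downstream (dependency is downstream of its risk factors). The
  order is configurable; mortality-before-or-after-updates is not empirically
  identified at the monthly step.
* **Snapshots** are taken after the June step of each output year (a mid-year
  population); engine tests that reconcile with whole-year event counts use
  December. When a cognition band changes in the engine, the MMSE score is
  set deterministically to the band's top value to keep snapshots internally
  consistent.
* **Sullivan's method** uses single-year-of-age prevalence from the same
  year's snapshot (period expectancies), smoothed by a centred 5-year moving
  average when a cell holds fewer than 30 alive individuals; ages with no
  observations inherit the nearest observed age's distribution. Person-years
  use the midpoint rule `L_x = (l_x + l_{x+1})/2` with terminal open interval
  `L_ω = l_ω / μ_ω`. State years sum to total LE by construction (tested to
  1e-9).
* **Report rounding** is half-away-from-zero to one decimal, matching the
  usual printed-table style; ages beyond the lifetable use its terminal row.
* **Problem sizes.** Defaults (24 400 panel rows, 30 000 base records, ten
  runs) are a desk-scale configuration that runs the full pipeline in minutes
  on one CPU; tests use smaller cohorts (≈4 000–10 000) sized so that
  three-Monte-Carlo-standard-error oracle bands remain tight.

## Limitations

* Transition stationarity and a static lifetable mean simulated trends mix
  genuine dynamics with relaxation from the synthetic baseline cross-section
  toward the transition models' implied equilibrium; real-data deployments
  should recalibrate both.
* Recovery-direction models for the same characteristic are fitted marginally
  (worsening offered first in the generator), introducing a bias of order
  `p_up · p_down` in recovery logits — negligible at the default rates.
* The engine holds residence fixed and injects no new entrants; scenarios
  (changed incidence, improving mortality) require editing the model set or
  lifetable by hand.
* Survey-weighted fits use an HC1 sandwich, not full design-based variance
  (no strata/PSU structure is generated).
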