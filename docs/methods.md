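# Methods

`t2dsim` is an individual-level state-transition (microsimulation) model for
the cost-utility analysis of a targeted polygenic-risk-score (PRS) screening
strategy against usual risk-factor screening for type 2 diabetes (T2D)
prevention. This note documents the model, its assumptions, the defaults,
and what the synthetic inputs do and do not show.

## The decision problem

Adults whose 10-year T2D risk, estimated from age, sex and the FINDRISC
questionnaire score, falls in the *high* band (10–20%) are the target
population. Under **usual care** nobody in this band crosses the ≥ 20%
intervention threshold, so nobody is intervened on. Under the **PRS
strategy** every member of the band receives a PRS test (50 € by default);
the risk re-estimated with the PRS reclassifies a fraction of them to the
very-high band (≥ 20%), and those individuals receive a lifestyle
intervention (incidence hazard ratio 0.74), of whom 30% also receive
medical therapy (combined hazard ratio 0.51). Intervention effects last 15
years from screening; full adherence is assumed.

## State-transition model

Four mutually exclusive states: Healthy, T2D, T2D with complications,
Death (absorbing). Annual cycles; each individual is simulated until death
or age 100. Transitions:

- **Healthy → T2D**: annual conditional probability `1 − S(t+1)/S(t)` from a
  Weibull accelerated-failure-time (AFT) incidence model with the AFT
  parameterization `S(t|x) = exp(−(t/λ(x))^k)`, `λ(x) = exp(β₀ + xβ)`,
  shape `k = 1/scale`. Baseline covariates are held fixed while `t`
  advances (an extrapolation of the baseline risk equation; a covariate-
  updating variant was considered and rejected as it has no fitted basis).
- **T2D → T2D with complications**: the same machinery with the clock reset
  at diagnosis (time measured from T2D onset).
- **→ Death**: sex- and age-specific life-table probabilities, adjusted in
  the T2D state by sex-specific hazard ratios (women 2.47, men 1.93) and in
  the complications state by 2.36. The complications hazard ratio is
  interpreted as relative to the general population (it replaces, not
  stacks on, the T2D ratio); `MortalityAdjustment(complication_hr_on_top=True)`
  switches to the stacking reading.

Within a cycle, death is drawn first; survivors face at most one
progression event. Costs and utilities accrue by the post-transition state;
a death cycle accrues nothing beyond the cycle-1 screening charges. No
half-cycle correction is applied — individual-level annual accounting is
used as-is. Hazard-ratio adjustments of annual probabilities assume a
constant hazard within the cycle: `p ↦ 1 − (1−p)^HR`, which composes
exactly across multiplied hazard ratios.

The engine's production path is vectorized across individuals year by
year; a per-person reference implementation exists and the two agree on
shared uniform streams to below 1e-9 per person (summation order only).
Both arms of a comparison consume the same uniform streams (common random
numbers), which makes the null case exact — with a zero PRS coefficient and
a free test, the arms produce identical aggregates — and sharply reduces
Monte-Carlo noise on increments.

## Disease truth vs. screening models

Disease onset in *both* arms is driven by the PRS-informed incidence model
(the "truth"), so genetically higher-risk individuals truly progress
faster. The arms differ only in the information used for assignment: the
usual arm screens on the PRS-free risk, the PRS arm on the PRS-informed
risk. The PRS-free screening model is the truth model with the PRS term
dropped, which coincides with the truth at the population mean because the
PRS is standardized to mean 0.

## Economics

Costs (2021 €, societal perspective excluding direct non-medical costs):
T2D accrues primary care (562 €/yr men, 542 €/yr women), T2D medication
(584 €/yr), secondary care (3 315 €/yr), and productivity losses
(7 632 €/yr while the current age is under 65, both diseased states);
complications add 4 401 €/yr. One-off charges at screening: PRS test 50 €
(PRS arm, every band member), lifestyle course 650 €, and the first year of
medical therapy (1 965 €/yr). The duration of medical-therapy costing is
not well determined by the sources; the default is one year (matching the
one-year weight-loss window of the underlying trials) and is configurable
(`InterventionPolicy.medical_therapy_years`) — results are sensitive to
this choice. The lifestyle cost is treated as one-off for the same reason.

Utilities are EQ-5D-3L population baselines by sex and age band
(30–44/45–54/55–64/65+, resolved from the *current* simulated age each
cycle), with additive disutilities 0.041 (T2D) and 0.119 (complications),
floored at zero; `UtilityParameters(additive_complications=False)` switches
the complications decrement to replace rather than add. Discounting is 3%
per year for costs and QALYs from the second year onward (cycle 1
undiscounted).

## Probabilistic sensitivity analysis

Every uncertain parameter is sampled independently per draw (no correlation
structure is available): hazard ratios from lognormals moment-matched on
the natural scale (`σ² = ln(1+(SE/m)²)`, `μ = ln m − σ²/2`; the published
SEs for two hazard-ratio rows cannot be reconciled with their CIs under
either a natural- or log-scale rule, so the natural-scale SE rule is
applied uniformly and both numbers are retained in the parameter file);
costs from gammas by moment matching (`shape = (m/SE)²`, `rate = m/SE²`);
utilities and disutilities from betas using the published shape terms where
printed, otherwise method of moments (`ν = m(1−m)/SE² − 1`). Parameters
without a CI carry ±25% bounds and the `SE = (upper−lower)/3.92` rule.
Fixed rows (medical-therapy cost, test price) pass through.

Each draw simulates a fresh cohort with both arms under common random
numbers and averages individual-level noise within the draw before any
decision statistic. Defaults follow the study design — 1 000 draws ×
10 000 individuals per arm — and are configurable; tests and the shipped
smoke scale use 100 × 1 000, which runs in seconds and leaves the decision
statistics' qualitative behaviour unchanged.

Decision statistics: dominance is checked before any ICER is formed; the
CEAC is the per-WTP fraction of draws in which the PRS arm has the higher
net monetary benefit (exact ties count one half, so the null case yields
0.5); EVPI is the mean best-strategy NMB minus the best mean NMB; the
cost-neutral test price is `base price − ΔC`, exact because every PRS-arm
member is tested exactly once at an undiscounted year-1 charge, floored at
zero. The WTP grid defaults to 0–100 000 € in 2 500 € steps.

## Synthetic inputs

The registry data behind the original risk equations is restricted, so all
inputs that would come from it are synthetic and labelled as such:

- **Cohort generator** (`synthetic_population`): ages from a truncated
  normal (mean 61.5, SD 11, range 30–79), 63.9% male, BMI ~ N(28.5, 4.5²)
  clipped to [16, 60], waist tracking BMI with sex offsets, blood-pressure
  medication logistic in age, high-glucose history 12%, physical activity
  55%, daily vegetables 50%, family history none/second/first-degree at
  50/27/23%. The FINDRISC score is computed from the published 8-item
  instrument table (max 26 points), packaged as an overridable constant.
  The PRS is drawn normal and then sample-standardized, so the analysis
  cohort has mean 0 and SD 1 exactly.
- **Incidence coefficients** (`defaults`): stipulated synthetic Weibull AFT
  coefficients (shape 1.6; log-λ coefficients −0.015·age, −0.15·male,
  −0.09·FINDRISC, −0.30·PRS). The intercept (6.26) was calibrated once so
  that ≈ 10.5% of generated adults fall in the 10–20% risk band, matching
  the target-population share the screening design defines, and then
  frozen. These are configuration data, not estimates about any real
  population.
- **Life table**: Gompertz–Makeham hazard `μ(a) = 3·10⁻⁴ + A·e^{0.1a}`
  with `A` = 1.2·10⁻⁵ (women) / 1.8·10⁻⁵ (men), giving remaining life
  expectancies at 60 of ≈ 25.6 and ≈ 22.2 years — in the range of a
  contemporary high-income population. CSV load/save is provided for
  substituting a real national table.
- **Complication onset**: intercept 3.1, −0.10·male, shape 1.3 — a median
  time from diagnosis to first major complication of roughly 17 years.

Because these inputs are synthetic, passing tests demonstrate the
*machinery* — state-machine soundness, exact accounting identities,
parameter recovery of the fitting layer, direction and internal consistency
of the strategy comparison — not the published point estimates. The
headline published numbers (−253 € and +0.022 QALYs per person, 12.4-point
reclassification, 63.0% CEAC and 243 € EVPI at WTP 0) depend on the
unpublished fitted coefficients and restricted registry data and are out of
reach by construction; the suite instead pins the identities that must hold
regardless of inputs (null-PRS equivalence, one-for-one test-price
linearity, telescoping survival reconstruction, hazard-ratio composition,
non-negative EVPI) and verifies that under the shipped synthetic inputs the
PRS strategy is directionally favourable (more QALYs, fewer T2D years, and
typically dominant) across paired replicates.

## Model fitting

`fit_aft` fits right-censored parametric AFT regressions: Weibull,
log-normal and log-logistic via `lifelines`; the exponential family via a
Poisson GLM with log-time offset (`statsmodels`), whose solution is the
exact exponential-survival MLE. `compare_families` tabulates
`AIC = 2k − 2lnL` and `BIC = k·ln n − 2lnL` and selects the lowest AIC
(ties by BIC), propagating per-family failures into the table without
aborting the comparison. Parameter recovery is tested by simulating from a
known model with 10-year censoring and refitting (each coefficient within
3 estimated SEs at n = 50 000).

## Numerical conventions and edge cases

- Half-open risk bands: exactly 0.20 is very-high; exactly 0.10 is high.
- `annual_event_prob` raises if `S(t)` underflows to zero (degenerate).
- Rounding for table comparisons uses round-half-away-from-zero, matching
  the printed tables (e.g. 812.5 → 813).
- Beta method-of-moments rejects `SE² ≥ m(1−m)`; lognormal/gamma rules are
  exact round-trips by construction and tested to 1e-9.
- Sampled intervention hazard ratios are capped at 1.0 (an intervention is
  never allowed to cause harm through a sampling fluctuation; the 0.74 row's
  CI crosses 1, so uncapped draws would occasionally do so).
- Simulation reproducibility: a single master seed drives a
  `SeedSequence` tree (parameter draws, cohort generation, uniform streams
  are separated), and identical configurations are byte-identical on disk.

## Known limitations

- All PSA parameters are sampled independently; real cost and utility
  parameters are correlated in unknown ways.
- The synthetic cohort has no covariate correlation beyond waist–BMI and
  age–medication; FINDRISC item prevalences are stipulated.
- Interventions act only through the incidence hazard ratio; no effect
  heterogeneity by PRS, no behavioural response to risk disclosure, no
  medication adverse effects.
- A single complication state aggregates heterogeneous micro- and
  macro-vascular outcomes with one cost and one disutility.
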