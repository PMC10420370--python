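# Methods

## Problem and model chain

The package estimates how a front-of-package nutrition labeling (FoPNL) policy
would change sugary-beverage energy intake in Brazilian adults (20–59 y) over
five years, and propagates that change through body weight to obesity and
excess-weight prevalence and to direct public-health costs. The causal chain
is deliberately simple and fully explicit:

    survey intake  →  secular trend  →  policy multiplier  →  ΔEI per person
      →  first-order weight dynamics  →  BMI classification
      →  national prevalence difference  →  averted cases  →  discounted cost

Each arrow is one module with a narrow contract, so any stage can be replaced
(e.g. a full compartmental weight model) without touching the others.

## Survey processing

A respondent's daily soft-drink volume is reconstructed from two questions
(days per week; glasses/cans per day) as
`days/7 × glasses × serving_volume`. The frequency answers are mapped to
category midpoints (1–2 → 1.5, 3–4 → 3.5, 5–6 → 5.5, daily → 7 days/week);
the survey instrument does not define this mapping, so it is configurable.
The serving volume defaults to 300 mL — the mean of a 350 mL can and a 250 mL
glass, reflecting that the questionnaire does not distinguish vessel sizes.
Energy and sodium densities default to 42 kcal and 10 mg per 100 mL of
regular soft drink; the sodium default is anchored to published beverage
medians (≈10 mg/100 mL). Respondents reporting both regular and diet
consumption ("both") are treated as fully regular consumers — a conservative
inclusion; treating them as fractional consumers would require a split the
data do not provide.

Exclusions are applied in a fixed precedence order — age outside 20–59,
never/almost-never consumption, unknown quantity, diet-only, pregnancy,
BMI outside [15, 60] — and each excluded record is tallied once under the
first rule it violates, making the audit table deterministic. Boundary
conventions: ages 20 and 59 are kept; BMI exactly 15 or 60 is kept (only
*beyond* those values is extreme); BMI 30 and 25 are obese / excess weight
(inclusive cutoffs).

Weighted means use the sampling weights with the with-replacement
approximation `se² = Σw²(x−x̄)² / (Σw)²`; survey design variance and
regression variance are reported separately, never combined.

## Trend fitting and projection

Annual outcomes (consumer proportion; mean energy and sodium among consumers;
obesity and excess-weight prevalence among consumers) are computed per wave as
weighted means, then regressed on calendar year by OLS (statsmodels) using the
aggregated annual points — twelve of them for the 2007–2019 era, 2017 absent
because no wave was fielded; the label, never the position, is dropped.
Projections to 2020–2024 carry linear-predictor standard errors from the OLS
coefficient covariance. Projected proportions are clipped into [0, 1] with a
logged warning; the synthetic defaults never trigger the clip.

## Scenario composition

Policy effects are multiplicative on the projected year-specific intake:
energy multiplier `(1 + label)(1 + reform)`, sodium analogously. Built-in
fractions: labeling −9.9 % energy / −5.2 % sodium (post-implementation
purchase change observed in Chile) with reformulation −1.6 % energy /
+1.8 % sodium; sensitivity variants use −10.5 % / −5.5 % (Canadian
experimental-market estimate). The reformulation energy figure of −1.6 % is
used as published even though the same source's quoted medians
(30 → 28 kcal/100 mL) would imply roughly −6.7 %; the discrepancy is noted
here rather than resolved. The policy applies instantaneously at the start
year and is sustained — the underlying effect estimates are post-implementation
level changes with no ramp described.

Applying the multiplier to the *projected* year-specific intake (not a frozen
baseline) is the only composition under which the base trend change and the
scenario-1 change can both hold simultaneously at the horizon; with a
baseline soft-drink energy of ≈106 kcal/day and a trend of ≈−4 kcal/day/year
it yields the characteristic −20 / −28 / −29 kcal/day pattern for
base / s1 / s2 at year five.

Per-individual changes scale each respondent's own baseline intake so that
the cohort-weighted mean matches the scenario series:
`ΔEI_i(t) = energy_i × Δmean(t) / baseline_mean`. Heavier consumers therefore
absorb proportionally larger reductions, which is the natural reading of a
percentage purchase change.

## Body-weight dynamics

The full multi-compartment energy-balance literature model (fat/lean
partitioning, glycogen, adaptive thermogenesis) is reduced to its validated
first-order summary:

* equilibrium density **ρ = 23.9 kcal·day⁻¹ per kg** of eventual weight
  change (100 kJ/day per kg);
* time constant **τ = 1.44 y**, giving the canonical one-year half-time
  (half the eventual change after ~1 year, ~95 % after five).

Piecewise-constant yearly ΔEI is propagated in closed form
(`W ← W_eq + (W − W_eq)·e^(−Δt/τ)`), so the solver is exact for the input
class and trivially vectorises over 50 000-person cohorts. The sodium channel
adds an extracellular-fluid shift ΔECF = ΔNa / 3000 L per (mg/day), with a
~1-week time constant; at scenario-scale sodium deltas (≈1 mg/day) its
contribution is below 0.01 kg, which the test suite asserts. Age and sex are
carried for stratified reporting but do not modify the reduced dynamics — a
simplification relative to the full model, acceptable because the policy
deltas are small and the reduced summary reproduces the headline −1.1 kg at
−28 kcal/day within rounding. The parameter object allows swapping in a full
compartmental implementation without interface change.

## National impact and costs

Scenario prevalence at year *t* among consumers is the trend-projected base
prevalence plus the cohort-level difference the weight model produces between
scenario and base. Averted cases are
`(prev_base − prev_scenario) × population × consumer_share`; percentage-point
changes divide by the total adult population (sex-specific denominators for
strata). Averted cases are accounted as the year-5 stock (difference in
prevalent cases at the horizon) by default, matching the "after five years"
framing; an annual-flow accounting is available via `cost_accounting="flow"`.

The per-capita direct obesity cost divides the 2018 public-system total for
ages 20–59 by the obese 20–59 population served by the public system (71.5 %
dependence share), updates 2018 → 2019 by a consumer-price factor (default
1.0431, configurable), and converts at 4.03 BRL/USD or PPP 2.281. Costs
accrue at year end and are discounted at 5 %/year to the 2019 base. Only the
all-ages 2018 total (R$ 1.42 billion) is widely printed; it ships as a
documented fallback and `per_capita_cost` logs a warning until the
age-restricted figure is supplied.

## Synthetic survey generator

The generator emulates the statistical structure the analysis assumes, not
the survey's sampling design:

* **BMI** is lognormal; at the reference year (μ, σ) are solved in closed
  form so the mean (26.5) and obesity share (21.5 %) hit their targets
  simultaneously (σ ≈ 0.178). In other years μ alone shifts to follow the
  configured prevalence drift (+0.7 pp/year by default, the secular rise).
* **Height** is normal given sex (common SD 0.07 m, male/female mean ratio
  1.07), scaled so E[height²] = mean_weight / mean_BMI; self-reported weight
  is then BMI × height², which pins the mean weight (75.4 kg) exactly in
  expectation. This differs from drawing weight lognormally first: inverting
  weight = BMI × height² guarantees the three anthropometric targets jointly
  instead of approximately.
* **Consumption frequency** is categorical over the four consumer categories
  with probabilities exponentially tilted (one-dimensional root-find) so the
  implied mean volume — through the same conversion the intake module applies
  — equals the year's target (251.5 mL/day at reference, drifting
  −9.5 mL/day/year, equivalent to the observed ≈−4 kcal/day/year). Glasses
  per day are truncated-geometric on 1–6.
* **Filter triggers**: 5 % of records violate exactly one exclusion rule
  (never/almost-never, diet-only, pregnancy, extreme BMI, unknown quantity,
  cycled evenly) so the filters are always exercised.
* **Sampling weights** are lognormal(0, 0.5) — taken as given, with no
  attempt to reproduce a telephone-frame post-stratification procedure.
* An optional Gaussian-copula correlation couples the BMI and frequency
  draws (default 0; the survey does not identify this joint structure). The
  copula leaves both marginals — and hence all calibration targets — intact.

What passing tests on synthetic data do **not** show: the generator matches
marginal moments and linear drifts, not intra-household correlation, item
non-response patterns, digit preference in self-reports, or the true consumer
share of the population (the synthetic consumer share is ≈95 % by
construction, far above the real ≈25–30 %, so national case counts from
synthetic runs are illustrative only). Real-survey conclusions require the
real microdata through the same pipeline.

## Numerical choices and degenerate inputs

* Closed-form exponential propagation makes the weight model deterministic
  and step-size-free; `step_days` only sets trajectory output resolution.
* Frequency-tilt root-finding uses Brent's method on θ ∈ [−10, 10]; targets
  implying fewer than 1.5 or more than 7 consumption days/week are rejected
  with a message naming the infeasible value.
* All randomness flows from one integer seed; per-year waves use independent
  `default_rng([seed, year])` substreams, so identical (config, seed) runs
  are byte-identical and waves are independent across years.
* Degenerate inputs fail loudly: all-zero weights, fewer than three trend
  points, misaligned year sets, non-finite intake series, non-positive
  anthropometrics, unknown scenario names.

## Problem sizes

The shipped test suite generates waves of 1 500–50 000 records; the full
five-scenario pipeline at 50 000 records per wave (12 waves) runs in well
under a minute on one core, and the desk-scale weight-model example in
milliseconds.

## Known limitations

Only regular soft drinks are modelled (no fruit drinks or other sugary
beverages); saturated-fat and sugar channels beyond energy are ignored;
physical activity is constant; no price, advertising or substitution
responses beyond what the net percentage effects embed; the cost side covers
direct public-system costs only, with a prevalence-based (not incidence-based)
case count.
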