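# fopnlsim

Counterfactual simulation of **front-of-package nutrition labeling (FoPNL)**
effects on sugary-beverage intake, body weight, obesity prevalence and direct
public-health costs in Brazilian adults aged 20–59.

The package is aimed at nutrition-policy modellers and health economists. It
chains five stages into a reproducible pipeline:

1. **Survey processing** — VIGITEL-style telephone-survey records (year, sex,
   age, self-reported weight/height, soft-drink frequency and quantity answers,
   beverage type, sampling weight) are filtered with the study's
   inclusion/exclusion rules and converted to daily intake:
   `volume = days_per_week/7 × glasses × serving_volume`, with energy and
   sodium by density scaling (defaults 42 kcal and 10 mg per 100 mL).
2. **Trend projection** — survey-weighted annual means (2007–2019, no 2017
   wave) are fitted by OLS on calendar year and projected to 2020–2024.
3. **Scenario composition** — policy effects enter as multiplicative changes
   to projected intake, `(1 + label)(1 + reform)` per channel. Built-ins:
   `s1` (labeling: −9.9 % energy, −5.2 % sodium), `s2` (s1 + reformulation:
   −1.6 % energy, +1.8 % sodium), and sensitivity variants `s3`/`s4`
   (−10.5 % / −5.5 % labeling).
4. **Body-weight dynamics** — each individual's sustained intake change ΔEI
   (kcal/day) moves weight toward an equilibrium change ΔBW<sub>∞</sub> = ΔEI/ρ
   (ρ = 23.9 kcal·day⁻¹·kg⁻¹, i.e. 100 kJ/day per kg) with first-order time
   constant τ = 1.44 y; a fast extracellular-fluid channel carries the sodium
   effect. BMI ≥ 30 classifies obesity, BMI ≥ 25 excess body weight.
5. **National impact** — cohort prevalence differences are scaled to the adult
   consumer population, converted to averted cases and percentage-point
   changes, and priced at the per-capita direct obesity cost of the public
   health system (71.5 % public dependence, 2019 BRL, USD at 4.03, PPP at
   2.281), discounted at 5 %/year to 2019.

A **seeded synthetic survey generator** reproduces the statistical structure
the analysis assumes — 2019 consumer marginals (251.5 mL/day intake, 75.4 kg,
BMI 26.5, 21.5 % obesity, 54.3 % male) plus linear annual drifts — so the
whole chain runs and is testable without any data download.

## Worked example

```python
import numpy as np
from fopnlsim import simulate_weight

height = np.sqrt(75.4 / 26.5)            # baseline mean weight and BMI
traj = simulate_weight(75.4, height, 36, "male",
                       delta_ei=np.full(5, -28.0),   # sustained kcal/day
                       delta_na=np.zeros(5))
print(f"{traj.weight_change:+.2f} kg -> final BMI {traj.final_bmi:.2f}")
```

prints

```
-1.14 kg -> final BMI 26.10
```

— a sustained 28 kcal/day reduction (the labeling-scenario mean) takes an
average adult about half-way to its −1.17 kg equilibrium in the first year and
to −1.1 kg after five, lowering mean BMI from 26.5 to 26.1. The scripts in
`examples/` walk through each capability (generator calibration, scenario
composition, weight trajectories, the full pipeline) and print the numbers
they compute.

A full run from the shell:

```bash
fopnl-simulate --scenario all --seed 1 --output results/run1
```

writes an exclusion audit, trend and projection tables, per-scenario change
series, cohort summaries, a national impact table and a JSON manifest keyed by
the config hash and seed.

## Limitations

Only regular soft drinks are modelled; physical activity and other dietary
channels are held constant; the synthetic generator matches marginal moments
and linear drifts, not the full joint distribution of a real survey (see
`docs/methods.md`).
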