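"""End-to-end reproducible run: generate/read -> filter -> trend -> scenario ->
weight model -> national impact, with CSV outputs and a JSON manifest.

Every stage's row counts and the configuration hash land in the manifest, so a
run is fully identified by (config, seed). All randomness flows from the
single seed in the synthetic-survey config.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field

from .bodyweight import WeightModelParams, cohort_update
from .impact import (
    CostParams,
    ImpactResult,
    PopulationProjection,
    averted_cases,
    discounted_avoided_cost,
    per_capita_cost,
    prevalence_pp_change,
    read_population_csv,
    synthetic_population,
)
from .intake import ConversionParams, apply_filters, estimate_intake_wave
from .scenarios import (
    BUILTIN_SCENARIOS,
    build_change_series,
    get_scenario,
    individual_change_matrix,
    individual_sodium_matrix,
)
from .survey import read_wave
from .synth import SynthConfig, generate_waves
from .trends import build_annual_series, fit_trend, project

log = logging.getLogger(__name__)

HORIZON_YEARS = tuple(range(2020, 2025))
BASELINE_YEAR = 2019
#: Approximate male share of the adult population (used only by the synthetic
#: population split; a real projection supplies its own sex split).
_POP_MALE_SHARE = 0.49


class RunConfig(BaseModel):
    """Single-file configuration for a full pipeline run."""

    output_dir: str = "results"
    synth: SynthConfig = Field(default_factory=SynthConfig)
    input_waves: dict[int, str] = Field(default_factory=dict)
    conversion: ConversionParams = Field(default_factory=ConversionParams)
    weight_model: WeightModelParams = Field(default_factory=WeightModelParams)
    cost: CostParams = Field(default_factory=CostParams)
    scenario_names: list[str] = Field(
        default_factory=lambda: ["base", "s1", "s2", "s3", "s4"]
    )
    population_csv: str | None = None
    obese_count_2018: float | None = None
    cost_accounting: str = Field(default="stock", pattern="^(stock|flow)$")
    stratify_sex: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            payload = yaml.safe_load(fh) or {}
        return cls.model_validate(payload)


def _load_waves(config: RunConfig) -> dict[int, pd.DataFrame]:
    if config.input_waves:
        waves = {}
        for year, path in sorted(config.input_waves.items()):
            if not Path(path).exists():
                raise FileNotFoundError(f"input wave for {year} not found: {path}")
            waves[int(year)] = read_wave(path)
        return waves
    return generate_waves(config.synth)


def _population(config: RunConfig, consumer_share: dict[int, float]) -> PopulationProjection:
    years = sorted(consumer_share)
    if config.population_csv is not None:
        if not Path(config.population_csv).exists():
            raise FileNotFoundError(
                f"population projection CSV not found: {config.population_csv}"
            )
        return read_population_csv(config.population_csv, consumer_share)
    return synthetic_population(years, consumer_share)


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages and write outputs under ``config.output_dir``.

    Returns the run manifest (also written as ``manifest.json``).
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    scenario_specs = [get_scenario(name) for name in config.scenario_names]
    strata = ["all"] + (["male", "female"] if config.stratify_sex else [])

    # --- stage 1-2: waves and exclusion filters -----------------------------
    waves = _load_waves(config)
    audit_rows, kept_waves = [], {}
    for year, wave in sorted(waves.items()):
        kept, tally = apply_filters(wave)
        kept_waves[year] = kept
        audit_rows.append({"year": year, "records_in": len(wave), "kept": len(kept), **tally})
    audit = pd.DataFrame(audit_rows)
    audit.to_csv(out / "exclusions.csv", index=False)

    # --- stage 3: weighted annual series, trends and projections ------------
    outcomes = (
        "consumer_proportion",
        "mean_energy",
        "mean_sodium",
        "obesity_prevalence",
        "excess_weight_prevalence",
    )
    fits: dict[tuple[str, str], object] = {}
    projections: dict[tuple[str, str], object] = {}
    trend_rows, proj_rows = [], []
    proj_years = (BASELINE_YEAR, *HORIZON_YEARS)
    for stratum in strata:
        sex = None if stratum == "all" else stratum
        for outcome in outcomes:
            series = build_annual_series(waves, config.conversion, outcome, sex=sex)
            fit = fit_trend(series)
            proj = project(fit, proj_years)
            fits[stratum, outcome] = fit
            projections[stratum, outcome] = proj
            trend_rows.append(
                {
                    "stratum": stratum,
                    "outcome": outcome,
                    "slope": fit.slope,
                    "intercept": fit.intercept,
                    "slope_se": fit.slope_se,
                    "resid_var": fit.resid_var,
                }
            )
            for y, v, s in zip(proj.years, proj.values, proj.ses):
                proj_rows.append(
                    {"stratum": stratum, "outcome": outcome, "year": int(y),
                     "value": v, "se": s}
                )
    pd.DataFrame(trend_rows).to_csv(out / "trends.csv", index=False)
    pd.DataFrame(proj_rows).to_csv(out / "projections.csv", index=False)

    # --- stage 4: scenario change series ------------------------------------
    changes: dict[tuple[str, str], object] = {}
    change_rows = []
    for stratum in strata:
        e_proj = projections[stratum, "mean_energy"]
        s_proj = projections[stratum, "mean_sodium"]
        base_e = e_proj.value_at(BASELINE_YEAR)
        base_s = s_proj.value_at(BASELINE_YEAR)
        for spec in scenario_specs:
            cs = build_change_series(e_proj, s_proj, spec, base_e, base_s, BASELINE_YEAR)
            changes[stratum, spec.name] = cs
            for y, de, dn in zip(cs.years, cs.delta_energy, cs.delta_sodium):
                change_rows.append(
                    {"stratum": stratum, "scenario": spec.name, "year": int(y),
                     "delta_energy_kcal_day": de, "delta_sodium_mg_day": dn}
                )
    pd.DataFrame(change_rows).to_csv(out / "change_series.csv", index=False)

    # --- stage 5: per-individual weight trajectories ------------------------
    cohort_all = estimate_intake_wave(kept_waves[BASELINE_YEAR], config.conversion)
    cohort_rows = []
    yearly_prev: dict[tuple[str, str], pd.DataFrame] = {}
    for stratum in strata:
        cohort = cohort_all if stratum == "all" else cohort_all[cohort_all["sex"] == stratum]
        energies = cohort["energy"].to_numpy()
        sodiums = cohort["sodium"].to_numpy()
        for spec in scenario_specs:
            cs = changes[stratum, spec.name]
            active = cs.years >= spec.start_year
            horizon_cs = type(cs)(
                scenario=cs.scenario,
                baseline_year=cs.baseline_year,
                baseline_energy=cs.baseline_energy,
                baseline_sodium=cs.baseline_sodium,
                years=cs.years[active],
                delta_energy=cs.delta_energy[active],
                delta_sodium=cs.delta_sodium[active],
            )
            d_ei = individual_change_matrix(horizon_cs, energies)
            d_na = individual_sodium_matrix(horizon_cs, sodiums)
            _, yearly = cohort_update(cohort, d_ei, d_na, config.weight_model)
            yearly["year"] = horizon_cs.years
            yearly_prev[stratum, spec.name] = yearly
            for row in yearly.to_dict("records"):
                cohort_rows.append({"stratum": stratum, "scenario": spec.name, **row})
    pd.DataFrame(cohort_rows).to_csv(out / "cohort_summary.csv", index=False)

    # --- stage 6: national prevalences, averted cases, costs ----------------
    def national_prev(stratum: str, scenario: str, outcome: str) -> dict[int, float]:
        proj = projections[stratum, outcome]
        col = outcome  # cohort summaries use the same outcome names
        scen = yearly_prev[stratum, scenario].set_index("year")[col]
        base = yearly_prev[stratum, "base"].set_index("year")[col]
        return {
            int(y): float(np.clip(proj.value_at(int(y)) + scen[y] - base[y], 0.0, 1.0))
            for y in HORIZON_YEARS
        }

    share_all = {
        int(y): projections["all", "consumer_proportion"].value_at(int(y))
        for y in HORIZON_YEARS
    }
    population = _population(config, share_all)
    pop_2018 = synthetic_population([2018], {2018: 0.0}).total[0] \
        if config.population_csv is None else population.total[0]
    if config.obese_count_2018 is not None:
        obese_2018 = config.obese_count_2018
    else:
        prev_2018 = float(np.clip(fits["all", "obesity_prevalence"].predict([2018])[0], 0, 1))
        obese_2018 = pop_2018 * prev_2018
    pc_cost = per_capita_cost(config.cost, obese_2018)

    if "base" not in {s.name for s in scenario_specs}:
        raise ValueError("the scenario set must include 'base' as the comparison scenario")

    impact_rows = []
    results: dict[str, ImpactResult] = {}
    for spec in scenario_specs:
        base_ob = national_prev("all", "base", "obesity_prevalence")
        scen_ob = national_prev("all", spec.name, "obesity_prevalence")
        base_ex = national_prev("all", "base", "excess_weight_prevalence")
        scen_ex = national_prev("all", spec.name, "excess_weight_prevalence")
        cases_ob = averted_cases(base_ob, scen_ob, population)
        cases_ex = averted_cases(base_ex, scen_ex, population)
        horizon = max(HORIZON_YEARS)
        pop_h, _ = population.at(horizon)
        pp_ob = prevalence_pp_change(cases_ob[horizon], pop_h)
        pp_ex = prevalence_pp_change(cases_ex[horizon], pop_h)
        cost_cases = cases_ob if config.cost_accounting == "flow" else {horizon: cases_ob[horizon]}
        cost_usd = discounted_avoided_cost(cost_cases, pc_cost["usd"], config.cost)
        cost_ppp = discounted_avoided_cost(cost_cases, pc_cost["ppp"], config.cost)
        cost_brl = discounted_avoided_cost(cost_cases, pc_cost["brl"], config.cost)
        res = ImpactResult(
            scenario=spec.name,
            averted_obesity=cases_ob,
            averted_excess_weight=cases_ex,
            pp_change_obesity=pp_ob,
            pp_change_excess_weight=pp_ex,
            avoided_cost_usd=cost_usd,
            avoided_cost_ppp=cost_ppp,
            avoided_cost_brl=cost_brl,
        )
        results[spec.name] = res
        row = res.to_row()
        if config.stratify_sex:
            for sex in ("male", "female"):
                b = national_prev(sex, "base", "obesity_prevalence")
                s = national_prev(sex, spec.name, "obesity_prevalence")
                sex_share = _POP_MALE_SHARE if sex == "male" else 1.0 - _POP_MALE_SHARE
                sex_pop = PopulationProjection(
                    years=population.years,
                    total=population.total * sex_share,
                    consumer_share=population.consumer_share,
                )
                c = averted_cases(b, s, sex_pop)
                row[f"pp_change_obesity_{sex}"] = prevalence_pp_change(
                    c[horizon], pop_h * sex_share
                )
        impact_rows.append(row)
    impact_df = pd.DataFrame(impact_rows)
    impact_df.to_csv(out / "impact.csv", index=False)

    # --- manifest and plain-text summary ------------------------------------
    cfg_json = config.model_dump_json()
    manifest = {
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "seed": config.synth.seed,
        "scenarios": [s.name for s in scenario_specs],
        "waves": {
            str(y): {"records_in": int(len(waves[y])), "kept": int(len(kept_waves[y]))}
            for y in sorted(waves)
        },
        "per_capita_cost_usd": pc_cost["usd"],
        "outputs": [
            "exclusions.csv", "trends.csv", "projections.csv", "change_series.csv",
            "cohort_summary.csv", "impact.csv", "summary.txt",
        ],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))

    lines = ["Front-of-package labeling simulation — run summary", ""]
    for spec in scenario_specs:
        res = results[spec.name]
        cs = changes["all", spec.name]
        horizon = max(HORIZON_YEARS)
        de = float(cs.delta_energy[cs.years == horizon][0])
        lines.append(
            f"{spec.name}: mean energy change at {horizon} = {de:+.1f} kcal/day; "
            f"obesity pp change = {res.pp_change_obesity:+.3f}; "
            f"averted obesity cases ({horizon}) = {res.averted_obesity[horizon]:,.0f}; "
            f"avoided cost = US$ {res.avoided_cost_usd:,.0f}"
        )
    (out / "summary.txt").write_text("\n".join(lines) + "\n")
    return manifest
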