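"""Population extrapolation, averted cases and discounted avoided direct costs.

Cohort-level prevalence differences are scaled to the national adult (20-59 y)
population of sugary-beverage consumers, converted into averted obesity and
excess-weight cases, and the obesity cases priced at the per-capita direct
cost borne by the public health system (SUS), discounted to the base year.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

log = logging.getLogger(__name__)

#: Printed all-ages 2018 direct obesity cost (BRL), usable as a documented
#: fallback when the age-restricted (20-59) figure is not supplied.
ALL_AGES_COST_2018_BRL = 1.42e9


class CostParams(BaseModel):
    """Cost-of-illness parameters for the avoided-cost chain.

    ``total_cost_2018``: total direct obesity cost in BRL for adults 20-59 in
    2018 (if only the all-ages figure is available, pass it and a warning is
    logged by :func:`per_capita_cost`). ``public_share``: fraction of the
    population relying on the public health system. ``inflation_factor``:
    consumer-price update 2018 -> 2019. ``fx_rate``: BRL per USD (2019).
    ``ppp_factor``: purchasing-power-parity conversion (2019).
    ``discount_rate``: annual rate applied to 2020-2024 values, base 2019.
    """

    total_cost_2018: float = Field(default=ALL_AGES_COST_2018_BRL, gt=0)
    cost_is_all_ages: bool = True
    public_share: float = Field(default=0.715, gt=0, le=1)
    inflation_factor: float = Field(default=1.0431, gt=0)
    fx_rate: float = Field(default=4.03, gt=0)
    ppp_factor: float = Field(default=2.281, gt=0)
    discount_rate: float = Field(default=0.05, ge=0, le=1)
    base_year: int = 2019


@dataclass
class PopulationProjection:
    """Adults aged 20-59 by year, with the projected consumer share."""

    years: np.ndarray
    total: np.ndarray  # persons
    consumer_share: np.ndarray  # fraction in [0, 1]
    by_sex: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.total = np.asarray(self.total, dtype=float)
        self.consumer_share = np.asarray(self.consumer_share, dtype=float)
        if (self.total <= 0).any():
            raise ValueError("population counts must be positive")
        if ((self.consumer_share < 0) | (self.consumer_share > 1)).any():
            raise ValueError("consumer shares must lie in [0, 1]")

    def at(self, year: int) -> tuple[float, float]:
        idx = np.flatnonzero(self.years == year)
        if idx.size == 0:
            raise KeyError(f"year {year} not in population projection")
        i = idx[0]
        return float(self.total[i]), float(self.consumer_share[i])


def read_population_csv(path, consumer_share) -> PopulationProjection:
    """Read a two-column ``year,count`` CSV and attach projected consumer shares.

    ``consumer_share`` is either a scalar or a mapping year -> share.
    """
    df = pd.read_csv(path)
    if list(df.columns[:2]) != ["year", "count"]:
        raise ValueError(f"expected columns ['year', 'count'] in {path}, got {list(df.columns)}")
    years = df["year"].to_numpy(dtype=int)
    if np.isscalar(consumer_share):
        shares = np.full(len(years), float(consumer_share))
    else:
        shares = np.array([float(consumer_share[y]) for y in years])
    return PopulationProjection(years=years, total=df["count"].to_numpy(dtype=float),
                                consumer_share=shares)


def synthetic_population(years, consumer_share, base_count: float = 117.0e6,
                         growth: float = 0.6e6) -> PopulationProjection:
    """Synthetic stand-in for a national 20-59 population projection.

    A linear path from ``base_count`` persons in 2019 growing by ``growth``
    persons per year, in the order of magnitude of the Brazilian adult
    population. Synthetic: use a real statistical-institute projection for any
    substantive analysis.
    """
    years = np.asarray(years, dtype=int)
    total = base_count + growth * (years - 2019)
    if np.isscalar(consumer_share):
        shares = np.full(len(years), float(consumer_share))
    else:
        shares = np.array([float(consumer_share[y]) for y in years])
    return PopulationProjection(years=years, total=total, consumer_share=shares)


def averted_cases(
    base_prev: dict[int, float],
    scenario_prev: dict[int, float],
    population: PopulationProjection,
) -> dict[int, float]:
    """Cases averted per year among national consumers.

    ``cases(t) = (prev_base(t) - prev_scenario(t)) * population(t) * share(t)``.
    Negative differences (a scenario worse than base) are allowed but logged.
    """
    if set(base_prev) != set(scenario_prev):
        raise ValueError(
            f"prevalence series are misaligned: base years {sorted(base_prev)} vs "
            f"scenario years {sorted(scenario_prev)}"
        )
    out: dict[int, float] = {}
    for year in sorted(base_prev):
        total, share = population.at(year)
        diff = base_prev[year] - scenario_prev[year]
        if diff < 0:
            log.warning("scenario prevalence exceeds base in %d (diff %.3g)", year, diff)
        out[year] = diff * total * share
    return out


def prevalence_pp_change(cases: float, total_population: float) -> float:
    """Averted cases expressed as a percentage-point change in prevalence.

    Negative by convention when cases are averted: ``-100 * cases / population``.
    """
    if total_population <= 0:
        raise ValueError("total population must be positive")
    return -100.0 * cases / total_population


def per_capita_cost(params: CostParams, obese_count_2018: float) -> dict[str, float]:
    """Direct obesity cost per obese public-system patient per year.

    The 2018 total is divided by the obese 20-59 population served by the
    public system (``obese_count_2018 * public_share``), updated to 2019 by the
    inflation factor, and converted to USD (by the FX rate) and to
    PPP-adjusted dollars (by the PPP factor).
    """
    if obese_count_2018 <= 0:
        raise ValueError("obese count must be positive")
    if params.cost_is_all_ages:
        log.warning(
            "total_cost_2018 is the all-ages figure; the 20-59 restricted figure "
            "should be supplied for substantive use"
        )
    brl = params.total_cost_2018 / (obese_count_2018 * params.public_share)
    brl_2019 = brl * params.inflation_factor
    return {
        "brl": brl_2019,
        "usd": brl_2019 / params.fx_rate,
        "ppp": brl_2019 / params.ppp_factor,
    }


def discounted_avoided_cost(
    cases_by_year: dict[int, float],
    per_capita: float,
    params: CostParams,
) -> float:
    """Present value (at ``params.base_year``) of avoided per-case costs.

    ``sum_t cases(t) * per_capita * (1 + r)^-(t - base_year)``; costs accrue at
    year end. Years must fall in 2020-2024.
    """
    for year in cases_by_year:
        if not 2020 <= year <= 2024:
            raise ValueError(f"avoided costs are defined for 2020-2024, got year {year}")
    r = params.discount_rate
    return float(
        sum(
            cases * per_capita / (1.0 + r) ** (year - params.base_year)
            for year, cases in cases_by_year.items()
        )
    )


@dataclass
class ImpactResult:
    """Per-scenario national impact summary."""

    scenario: str
    averted_obesity: dict[int, float]
    averted_excess_weight: dict[int, float]
    pp_change_obesity: float
    pp_change_excess_weight: float
    avoided_cost_usd: float
    avoided_cost_ppp: float
    avoided_cost_brl: float

    def to_row(self) -> dict:
        horizon = max(self.averted_obesity) if self.averted_obesity else None
        return {
            "scenario": self.scenario,
            "horizon_year": horizon,
            "averted_obesity_cases": self.averted_obesity.get(horizon, 0.0),
            "averted_excess_weight_cases": self.averted_excess_weight.get(horizon, 0.0),
            "pp_change_obesity": self.pp_change_obesity,
            "pp_change_excess_weight": self.pp_change_excess_weight,
            "avoided_cost_usd": self.avoided_cost_usd,
            "avoided_cost_ppp": self.avoided_cost_ppp,
            "avoided_cost_brl": self.avoided_cost_brl,
        }
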