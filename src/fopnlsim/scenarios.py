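"""Counterfactual scenario composition.

A scenario layers multiplicative policy effects on the secular intake trend:

* a *labeling* effect — the net change in purchased beverage energy/sodium
  observed after a front-of-package labeling law takes effect, and
* a *reformulation* effect — the change in product composition induced by the
  same law.

The two channels compose multiplicatively, ``(1 + label) * (1 + reform)``, and
apply to the trend-projected year-specific intake from the policy start year
onward, sustained. The built-in scenarios are:

========  =======================  =========================
name      energy (label, reform)   sodium (label, reform)
========  =======================  =========================
base      0, 0                     0, 0
s1        -9.9%, 0                 -5.2%, 0
s2        -9.9%, -1.6%             -5.2%, +1.8%
s3        -10.5%, 0                -5.5%, 0
s4        -10.5%, -1.6%            -5.5%, +1.8%
========  =======================  =========================

s1/s2 use the post-implementation purchase change observed in Chile and the
Chilean reformulation estimate; s3/s4 are the sensitivity variants built on a
Canadian experimental-market labeling effect.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from pydantic import BaseModel, Field, model_validator

from .trends import AnnualSeries


class ScenarioSpec(BaseModel):
    """Named set of multiplicative energy/sodium changes layered on the trend."""

    name: str
    label_energy_change: float = Field(default=0.0, gt=-1.0, lt=1.0)
    label_sodium_change: float = Field(default=0.0, gt=-1.0, lt=1.0)
    reform_energy_change: float = Field(default=0.0, gt=-1.0, lt=1.0)
    reform_sodium_change: float = Field(default=0.0, gt=-1.0, lt=1.0)
    start_year: int = 2020

    @model_validator(mode="after")
    def _finite(self) -> "ScenarioSpec":
        if not self.name:
            raise ValueError("scenario name must be non-empty")
        return self


BUILTIN_SCENARIOS: dict[str, ScenarioSpec] = {
    "base": ScenarioSpec(name="base"),
    "s1": ScenarioSpec(name="s1", label_energy_change=-0.099, label_sodium_change=-0.052),
    "s2": ScenarioSpec(
        name="s2",
        label_energy_change=-0.099,
        label_sodium_change=-0.052,
        reform_energy_change=-0.016,
        reform_sodium_change=0.018,
    ),
    "s3": ScenarioSpec(name="s3", label_energy_change=-0.105, label_sodium_change=-0.055),
    "s4": ScenarioSpec(
        name="s4",
        label_energy_change=-0.105,
        label_sodium_change=-0.055,
        reform_energy_change=-0.016,
        reform_sodium_change=0.018,
    ),
}


def get_scenario(name: str) -> ScenarioSpec:
    try:
        return BUILTIN_SCENARIOS[name]
    except KeyError:
        raise KeyError(
            f"unknown scenario {name!r}; known scenarios: {sorted(BUILTIN_SCENARIOS)}"
        ) from None


def combined_multiplier(spec: ScenarioSpec) -> tuple[float, float]:
    """Multiplicative composition of labeling and reformulation per channel."""
    return (
        (1.0 + spec.label_energy_change) * (1.0 + spec.reform_energy_change),
        (1.0 + spec.label_sodium_change) * (1.0 + spec.reform_sodium_change),
    )


@dataclass
class ChangeSeries:
    """Yearly mean intake changes relative to the baseline year, one scenario.

    ``delta_energy`` is kcal/day and ``delta_sodium`` mg/day, both relative to
    the trend value at ``baseline_year`` (so the base scenario's change is the
    pure trend movement, and every scenario's change at the baseline year is 0).
    """

    scenario: str
    baseline_year: int
    baseline_energy: float
    baseline_sodium: float
    years: np.ndarray
    delta_energy: np.ndarray
    delta_sodium: np.ndarray

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.delta_energy = np.asarray(self.delta_energy, dtype=float)
        self.delta_sodium = np.asarray(self.delta_sodium, dtype=float)


def build_change_series(
    energy_projection: AnnualSeries,
    sodium_projection: AnnualSeries,
    spec: ScenarioSpec,
    baseline_energy: float,
    baseline_sodium: float,
    baseline_year: int = 2019,
) -> ChangeSeries:
    """Compose the trend projection with the scenario multipliers.

    For every projected year ``t``:
    ``delta_energy(t) = projected_energy(t) * m_e(t) - baseline_energy``, where
    the energy multiplier ``m_e`` is the scenario's combined multiplier from
    ``spec.start_year`` onward and 1 before; sodium analogously. The projection
    must cover ``start_year .. start_year + 4``.
    """
    horizon = set(range(spec.start_year, spec.start_year + 5))
    for name, proj in (("energy", energy_projection), ("sodium", sodium_projection)):
        missing = sorted(horizon - set(proj.years.tolist()))
        if missing:
            raise ValueError(f"{name} projection is missing years {missing}")
    if not np.array_equal(energy_projection.years, sodium_projection.years):
        raise ValueError("energy and sodium projections must cover identical years")

    m_energy, m_sodium = combined_multiplier(spec)
    years = energy_projection.years
    active = years >= spec.start_year
    me = np.where(active, m_energy, 1.0)
    ms = np.where(active, m_sodium, 1.0)
    return ChangeSeries(
        scenario=spec.name,
        baseline_year=baseline_year,
        baseline_energy=baseline_energy,
        baseline_sodium=baseline_sodium,
        years=years,
        delta_energy=energy_projection.values * me - baseline_energy,
        delta_sodium=sodium_projection.values * ms - baseline_sodium,
    )


def individual_change_matrix(change: ChangeSeries, energies: np.ndarray) -> np.ndarray:
    """Per-individual yearly energy changes implied by a mean change series.

    Each respondent's change is proportional to their own baseline intake and
    scaled so the cohort mean change matches the series:
    ``delta_i(t) = energy_i * delta_mean(t) / baseline_energy``. Returns an
    (n_individuals, n_years) array; a sodium analogue follows by passing
    sodium intakes against ``delta_sodium / baseline_sodium``.
    """
    if change.baseline_energy <= 0:
        raise ValueError("baseline mean energy must be positive")
    e = np.asarray(energies, dtype=float)
    return np.outer(e, change.delta_energy / change.baseline_energy)


def individual_sodium_matrix(change: ChangeSeries, sodiums: np.ndarray) -> np.ndarray:
    """Sodium analogue of :func:`individual_change_matrix` (mg/day)."""
    if change.baseline_sodium <= 0:
        raise ValueError("baseline mean sodium must be positive")
    s = np.asarray(sodiums, dtype=float)
    return np.outer(s, change.delta_sodium / change.baseline_sodium)
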