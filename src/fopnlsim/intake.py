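"""Inclusion/exclusion filters and conversion of survey answers to daily intake.

Only regular soft drinks count as sugary beverages here. A respondent's daily
volume is reconstructed from the two consumption questions (days per week and
glasses/cans per day) as

    volume = days_per_week[freq] / 7 * glasses_per_day * serving_volume

and energy / sodium follow by density scaling per 100 mL.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .survey import NON_CONSUMER_FREQS, SurveyRecord

#: Exclusion reasons in precedence order: each record is tallied once, under
#: the first rule it violates.
EXCLUSION_REASONS = (
    "age",
    "never_consumer",
    "unknown_quantity",
    "diet_only",
    "pregnancy",
    "extreme_bmi",
)

AGE_MIN, AGE_MAX = 20, 59
BMI_MIN, BMI_MAX = 15.0, 60.0


class ConversionParams(BaseModel):
    """Answer-to-volume conversion constants.

    ``days_per_week`` maps each consumer frequency category to a typical number
    of consumption days (defaults are category midpoints; the survey does not
    define them). ``serving_volume`` is the mL assumed per glass/can, defaulting
    to 300 mL — the average of a 350 mL can and a 250 mL glass. Densities are
    per 100 mL of regular soft drink.
    """

    days_per_week: dict[str, float] = Field(
        default_factory=lambda: {"1-2/wk": 1.5, "3-4/wk": 3.5, "5-6/wk": 5.5, "daily": 7.0}
    )
    serving_volume: float = Field(default=300.0, gt=0, description="mL per glass/can")
    energy_density: float = Field(default=42.0, ge=0, description="kcal/100 mL")
    sodium_density: float = Field(default=10.0, ge=0, description="mg/100 mL")

    @model_validator(mode="after")
    def _check_days(self) -> "ConversionParams":
        for cat, d in self.days_per_week.items():
            if not 0 <= d <= 7:
                raise ValueError(f"days_per_week[{cat!r}] must lie in [0, 7], got {d}")
        return self


@dataclass(frozen=True)
class IntakeEstimate:
    """Daily intake for one respondent: volume (mL), energy (kcal), sodium (mg)."""

    volume: float
    energy: float
    sodium: float


def apply_filters(wave: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply the study's inclusion/exclusion rules to a wave.

    Kept respondents are adults aged 20-59 who consume regular (or regular and
    diet) soft drinks at a known daily quantity, are not pregnant, and have a
    self-reported BMI within [15, 60] kg/m^2. Returns the kept sub-frame and a
    tally of removals keyed by :data:`EXCLUSION_REASONS`; each excluded record
    is counted once, under the first matching reason in that order.
    """
    required = {"age", "freq_category", "glasses_per_day", "beverage_type",
                "pregnant", "weight_sr", "height_sr"}
    missing = sorted(required - set(wave.columns))
    if missing:
        raise ValueError(f"wave is missing filter fields: {missing}")
    for col in required:
        isna = wave[col].isna()
        if col != "glasses_per_day" and isna.any():
            raise ValueError(
                f"record {int(isna.idxmax())}: missing value in field {col!r}"
            )

    bmi = wave["weight_sr"] / wave["height_sr"] ** 2
    rules = {
        "age": (wave["age"] < AGE_MIN) | (wave["age"] > AGE_MAX),
        "never_consumer": wave["freq_category"].isin(NON_CONSUMER_FREQS),
        "unknown_quantity": wave["glasses_per_day"].isna(),
        "diet_only": ~wave["beverage_type"].isin(["regular", "both"]),
        "pregnancy": wave["pregnant"],
        "extreme_bmi": (bmi < BMI_MIN) | (bmi > BMI_MAX),
    }
    reason = pd.Series("", index=wave.index, dtype=object)
    for name in EXCLUSION_REASONS:
        hit = np.asarray(rules[name]) & (reason == "")
        reason[hit] = name
    tally = {name: int((reason == name).sum()) for name in EXCLUSION_REASONS}
    kept = wave.loc[reason == ""].copy()
    return kept, tally


def estimate_intake(record: SurveyRecord, params: ConversionParams) -> IntakeEstimate:
    """Convert one kept respondent's answers into daily volume/energy/sodium."""
    if record.freq_category not in params.days_per_week:
        raise ValueError(
            f"freq_category {record.freq_category!r} has no days-per-week mapping; "
            "non-consumers must be removed by apply_filters first"
        )
    if record.glasses_per_day is None:
        raise ValueError("glasses_per_day unknown; record should have been filtered out")
    volume = (
        params.days_per_week[record.freq_category] / 7.0
        * record.glasses_per_day
        * params.serving_volume
    )
    return IntakeEstimate(
        volume=volume,
        energy=volume * params.energy_density / 100.0,
        sodium=volume * params.sodium_density / 100.0,
    )


def estimate_intake_wave(kept: pd.DataFrame, params: ConversionParams) -> pd.DataFrame:
    """Vectorised :func:`estimate_intake` over a filtered wave.

    Returns a copy of ``kept`` with ``volume`` (mL/day), ``energy`` (kcal/day)
    and ``sodium`` (mg/day) columns appended.
    """
    days = kept["freq_category"].map(params.days_per_week)
    if days.isna().any():
        bad = kept.loc[days.isna(), "freq_category"].iloc[0]
        raise ValueError(f"freq_category {bad!r} has no days-per-week mapping")
    out = kept.copy()
    out["volume"] = (
        days.astype(float) / 7.0
        * kept["glasses_per_day"].astype(float)
        * params.serving_volume
    )
    out["energy"] = out["volume"] * params.energy_density / 100.0
    out["sodium"] = out["volume"] * params.sodium_density / 100.0
    return out


def weighted_mean(values, weights) -> tuple[float, float, tuple[float, float]]:
    """Survey-weighted mean with an approximate 95% CI.

    The standard error uses the with-replacement approximation
    ``se^2 = sum(w_i^2 (x_i - mean)^2) / (sum w_i)^2`` and the CI is
    ``mean +/- 1.96 se``.
    """
    x = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if x.shape != w.shape:
        raise ValueError("values and weights must have equal length")
    if (w < 0).any():
        raise ValueError("weights must be >= 0")
    total = w.sum()
    if total == 0:
        raise ValueError("weights must not all be zero")
    mean = float((w * x).sum() / total)
    se = float(np.sqrt((w**2 * (x - mean) ** 2).sum()) / total)
    return mean, se, (mean - 1.96 * se, mean + 1.96 * se)
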