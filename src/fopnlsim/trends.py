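"""Survey-weighted annual series, linear trend fits and projections.

The study era covers the 2007-2019 survey waves with 2017 absent (no wave was
fielded that year); trends are ordinary least squares of the annual weighted
outcome on calendar year, fitted with statsmodels, and projected to 2020-2024
with linear-predictor confidence intervals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .intake import AGE_MAX, AGE_MIN, ConversionParams, apply_filters, estimate_intake_wave, weighted_mean

log = logging.getLogger(__name__)

EXCLUDED_YEAR = 2017  # no survey wave that year; dropped by label, never by position

#: Outcomes an annual series may carry. Proportions are in [0, 1].
OUTCOMES = (
    "consumer_proportion",
    "mean_volume",
    "mean_energy",
    "mean_sodium",
    "obesity_prevalence",
    "excess_weight_prevalence",
)
_PROPORTIONS = {"consumer_proportion", "obesity_prevalence", "excess_weight_prevalence"}


@dataclass
class AnnualSeries:
    """Yearly weighted outcome values with standard errors."""

    outcome: str
    years: np.ndarray
    values: np.ndarray
    ses: np.ndarray

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        self.ses = np.asarray(self.ses, dtype=float)
        if self.outcome not in OUTCOMES:
            raise ValueError(f"unknown outcome {self.outcome!r}; expected one of {OUTCOMES}")
        if not (np.diff(self.years) > 0).all():
            raise ValueError("years must be strictly increasing")
        if len(self.years) != len(self.values) or len(self.years) != len(self.ses):
            raise ValueError("years, values and ses must have equal length")
        if self.outcome in _PROPORTIONS and ((self.values < 0) | (self.values > 1)).any():
            raise ValueError(f"{self.outcome} values must lie in [0, 1]")

    def value_at(self, year: int) -> float:
        idx = np.flatnonzero(self.years == year)
        if idx.size == 0:
            raise KeyError(f"year {year} not present in series {self.outcome!r}")
        return float(self.values[idx[0]])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"year": self.years, "value": self.values, "se": self.ses})


@dataclass
class TrendFit:
    """OLS fit of an annual weighted outcome on calendar year."""

    outcome: str
    slope: float
    intercept: float
    slope_se: float
    resid_var: float
    cov: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        vals = [self.slope, self.intercept, self.slope_se, self.resid_var]
        if not np.isfinite(vals).all():
            raise ValueError("trend coefficients must be finite")
        if self.slope_se < 0:
            raise ValueError("slope SE must be >= 0")

    def predict(self, years) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(years, dtype=float)


def build_annual_series(
    waves: dict[int, pd.DataFrame],
    conversion: ConversionParams,
    outcome: str,
    sex: str | None = None,
) -> AnnualSeries:
    """Compute one weighted annual outcome series from raw survey waves.

    Intake means and the two prevalences are computed among kept (post-filter)
    soft-drink consumers; ``consumer_proportion`` is the weighted share of
    age-eligible (20-59 y) respondents who are kept. ``sex`` restricts to one
    stratum. The 2017 label is always dropped.
    """
    if outcome not in OUTCOMES:
        raise ValueError(f"unknown outcome {outcome!r}")
    years, values, ses = [], [], []
    for year in sorted(waves):
        if year == EXCLUDED_YEAR:
            continue
        wave = waves[year]
        if sex is not None:
            wave = wave[wave["sex"] == sex]
        kept, _ = apply_filters(wave)
        if outcome == "consumer_proportion":
            eligible = wave[(wave["age"] >= AGE_MIN) & (wave["age"] <= AGE_MAX)]
            is_kept = eligible.index.isin(kept.index).astype(float)
            mean, se, _ = weighted_mean(is_kept, eligible["sample_weight"])
        elif outcome in ("mean_volume", "mean_energy", "mean_sodium"):
            est = estimate_intake_wave(kept, conversion)
            col = outcome.removeprefix("mean_")
            mean, se, _ = weighted_mean(est[col], est["sample_weight"])
        else:
            bmi = kept["weight_sr"] / kept["height_sr"] ** 2
            cut = 30.0 if outcome == "obesity_prevalence" else 25.0
            mean, se, _ = weighted_mean((bmi >= cut).astype(float), kept["sample_weight"])
        years.append(year)
        values.append(mean)
        ses.append(se)
    return AnnualSeries(outcome, np.array(years), np.array(values), np.array(ses))


def fit_trend(series: AnnualSeries) -> TrendFit:
    """OLS of the annual weighted outcome on calendar year."""
    if len(series.years) < 3:
        raise ValueError(f"need at least 3 annual points, got {len(series.years)}")
    X = sm.add_constant(series.years.astype(float))
    res = sm.OLS(series.values, X).fit()
    return TrendFit(
        outcome=series.outcome,
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        slope_se=float(res.bse[1]),
        resid_var=float(res.mse_resid) if res.df_resid > 0 else 0.0,
        cov=np.asarray(res.cov_params()),
    )


def project(fit: TrendFit, years) -> AnnualSeries:
    """Project the fitted line to ``years`` with linear-predictor CIs.

    Projected proportions are clipped into [0, 1]; clipping is logged as a
    warning because it signals the linear trend has left the feasible range.
    """
    years = np.asarray(years, dtype=int)
    yhat = fit.predict(years)
    X = np.column_stack([np.ones(len(years)), years.astype(float)])
    se = np.sqrt(np.einsum("ij,jk,ik->i", X, fit.cov, X))
    if fit.outcome in _PROPORTIONS:
        clipped = np.clip(yhat, 0.0, 1.0)
        if (clipped != yhat).any():
            log.warning(
                "projection of %s clipped to [0, 1] in years %s",
                fit.outcome, years[clipped != yhat].tolist(),
            )
        yhat = clipped
    return AnnualSeries(fit.outcome, years, yhat, se)
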