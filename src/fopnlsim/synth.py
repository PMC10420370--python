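"""Seeded synthetic survey waves with the marginal structure the analysis assumes.

The generator emulates a VIGITEL-style adult (20-59 y) telephone-survey
subsample. Its defaults reproduce the 2019 consumer marginals used throughout
the analysis — mean soft-drink intake 251.5 mL/day, mean self-reported weight
75.4 kg, mean BMI 26.5 kg/m^2, obesity prevalence 21.5%, 54.3% male — and
linear annual drifts in intake (falling) and obesity prevalence (rising) for
earlier and later waves.

Calibration strategy
--------------------
* BMI is lognormal. At the reference year its (mu, sigma) are solved so the
  mean and the obesity share P(BMI >= 30) hit their targets simultaneously;
  in other years mu alone shifts to follow the prevalence drift.
* Height is normal given sex with a fixed male/female ratio; the common scale
  is solved so E[height^2] = mean_weight / mean_bmi, which makes the implied
  mean self-reported weight hit its target (weight = BMI * height^2).
* Consumption frequency is categorical over the consumer categories, with
  probabilities exponentially tilted so the implied mean daily volume —
  through the same answer-to-volume conversion the intake module applies —
  equals the year's target. Glasses per day are truncated-geometric on 1..6.
* A configurable slice of records (default 5%) is generated to trigger each
  exclusion rule (never/almost-never, diet-only, pregnancy, extreme BMI,
  unknown quantity), so downstream filters are always exercised.

An optional Gaussian-copula correlation links the BMI and frequency draws;
the survey itself does not identify this joint structure, so it defaults to 0.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator
from scipy.optimize import brentq
from scipy.stats import norm

from .intake import ConversionParams
from .survey import WAVE_COLUMNS, _coerce_wave

CONSUMER_FREQS = ("1-2/wk", "3-4/wk", "5-6/wk", "daily")
_TRIGGER_KINDS = ("never", "diet_only", "pregnant", "extreme_bmi", "unknown_quantity")

#: Untilted prior over the consumer frequency categories.
_BASE_FREQ_PROBS = np.array([0.35, 0.30, 0.10, 0.25])
#: Truncated-geometric success probability for glasses/cans per day.
_GLASSES_P = 0.5
_HEIGHT_SD = 0.07  # m, within sex
_HEIGHT_RATIO = 1.07  # male/female mean height ratio
_OBESITY_CUT = 30.0


class SynthConfig(BaseModel):
    """Targets and knobs for the synthetic survey generator.

    Marginal targets refer to the *kept* (post-filter) respondents of the
    reference year; drifts are per calendar year relative to that year.
    """

    n_records: int = Field(default=50_000, ge=1)
    years: tuple[int, ...] = Field(
        default=(2007, 2008, 2009, 2010, 2011, 2012, 2013, 2014, 2015, 2016, 2018, 2019)
    )
    reference_year: int = 2019
    mean_intake: float = Field(default=251.5, gt=0, description="mL/day among consumers")
    mean_weight: float = Field(default=75.4, gt=0, description="kg")
    mean_bmi: float = Field(default=26.5, gt=0, description="kg/m^2")
    obesity_prev: float = Field(default=0.215, ge=0.0, le=1.0)
    male_share: float = Field(default=0.543, ge=0.0, le=1.0)
    intake_drift: float = Field(default=-9.5, description="mL/day per calendar year")
    prevalence_drift: float = Field(default=0.007, description="obesity share per year")
    filter_fraction: float = Field(default=0.05, ge=0.0, le=0.5)
    both_type_share: float = Field(default=0.15, ge=0.0, le=1.0)
    intake_bmi_corr: float = Field(default=0.0, ge=-0.99, le=0.99)
    weight_sigma: float = Field(default=0.5, ge=0.0, description="lognormal sd of sampling weights")
    seed: int = 20_190_101
    conversion: ConversionParams = Field(default_factory=ConversionParams)

    @model_validator(mode="after")
    def _check(self) -> "SynthConfig":
        if not np.isfinite(self.intake_drift) or not np.isfinite(self.prevalence_drift):
            raise ValueError("intake_drift and prevalence_drift must be finite")
        if self.mean_bmi >= _OBESITY_CUT:
            raise ValueError("mean_bmi must lie below the obesity cutoff of 30 kg/m^2")
        if not 0.0 < self.obesity_prev < 0.5:
            raise ValueError("obesity_prev must lie in (0, 0.5)")
        _bmi_lognormal_params(self.mean_bmi, self.obesity_prev)  # raises if infeasible
        return self


def _bmi_lognormal_params(mean_bmi: float, obesity_prev: float) -> tuple[float, float]:
    """Solve lognormal (mu, sigma) so E[BMI] and P(BMI >= 30) match targets."""
    z = norm.ppf(1.0 - obesity_prev)
    disc = z**2 - 2.0 * np.log(_OBESITY_CUT / mean_bmi)
    if disc <= 0:
        raise ValueError(
            f"mean_bmi={mean_bmi} and obesity_prev={obesity_prev} are jointly infeasible "
            "for a lognormal BMI distribution"
        )
    sigma = z - np.sqrt(disc)
    if sigma <= 0:
        raise ValueError("obesity_prev target requires mean_bmi below the cutoff")
    mu = np.log(mean_bmi) - sigma**2 / 2.0
    return float(mu), float(sigma)


def _glasses_probs() -> np.ndarray:
    k = np.arange(1, 7)
    p = _GLASSES_P * (1 - _GLASSES_P) ** (k - 1)
    return p / p.sum()


def _freq_probs_for_volume(target_volume: float, conv: ConversionParams) -> np.ndarray:
    """Tilt the frequency prior so the implied mean daily volume hits the target."""
    days = np.array([conv.days_per_week[c] for c in CONSUMER_FREQS])
    mean_glasses = float(_glasses_probs() @ np.arange(1, 7))
    target_days = target_volume * 7.0 / (conv.serving_volume * mean_glasses)
    lo, hi = days.min(), days.max()
    if not lo < target_days < hi:
        raise ValueError(
            f"mean_intake target {target_volume:.1f} mL/day implies {target_days:.2f} "
            f"consumption days/week, outside the representable range ({lo}, {hi})"
        )

    def gap(theta: float) -> float:
        w = _BASE_FREQ_PROBS * np.exp(theta * days)
        w /= w.sum()
        return float(w @ days) - target_days

    theta = brentq(gap, -10.0, 10.0)
    w = _BASE_FREQ_PROBS * np.exp(theta * days)
    return w / w.sum()


def _categorical_ppf(u: np.ndarray, probs: np.ndarray) -> np.ndarray:
    return np.searchsorted(np.cumsum(probs), u, side="right").clip(0, len(probs) - 1)


def generate_wave(cfg: SynthConfig, year: int) -> pd.DataFrame:
    """Generate one synthetic survey wave for ``year``.

    Deterministic given ``cfg.seed`` and ``year``; waves for different years
    use independent substreams of the same seed.
    """
    rng = np.random.default_rng([cfg.seed, year])
    n = cfg.n_records
    conv = cfg.conversion

    prev = float(np.clip(
        cfg.obesity_prev + cfg.prevalence_drift * (year - cfg.reference_year), 1e-4, 0.4999
    ))
    _, sigma = _bmi_lognormal_params(cfg.mean_bmi, cfg.obesity_prev)
    mu = np.log(_OBESITY_CUT) - sigma * norm.ppf(1.0 - prev)

    target_volume = cfg.mean_intake + cfg.intake_drift * (year - cfg.reference_year)
    freq_probs = _freq_probs_for_volume(target_volume, conv)

    sex = np.where(rng.random(n) < cfg.male_share, "male", "female")
    age = rng.integers(20, 60, size=n)

    # Height: normal given sex, scaled so E[height^2] = mean_weight / mean_bmi.
    target_h2 = cfg.mean_weight / cfg.mean_bmi
    denom = cfg.male_share * _HEIGHT_RATIO**2 + (1.0 - cfg.male_share)
    mu_f = np.sqrt((target_h2 - _HEIGHT_SD**2) / denom)
    mu_h = np.where(sex == "male", _HEIGHT_RATIO * mu_f, mu_f)
    height = rng.normal(mu_h, _HEIGHT_SD)

    z_bmi = rng.standard_normal(n)
    bmi = np.exp(mu + sigma * z_bmi)

    rho = cfg.intake_bmi_corr
    z_freq = rho * z_bmi + np.sqrt(1.0 - rho**2) * rng.standard_normal(n)
    freq_idx = _categorical_ppf(norm.cdf(z_freq), freq_probs)
    freq = np.array(CONSUMER_FREQS)[freq_idx].astype(object)
    glasses = _categorical_ppf(rng.random(n), _glasses_probs()).astype(float) + 1.0

    beverage = np.where(rng.random(n) < cfg.both_type_share, "both", "regular").astype(object)
    pregnant = np.zeros(n, dtype=bool)

    # Filter-triggering slice: one exclusion rule per record, kinds cycled.
    n_trig = int(round(cfg.filter_fraction * n))
    kinds = np.array(_TRIGGER_KINDS)[np.arange(n_trig) % len(_TRIGGER_KINDS)]
    idx = np.arange(n_trig)
    for kind in _TRIGGER_KINDS:
        sel = idx[kinds == kind]
        if kind == "never":
            freq[sel] = np.where(rng.random(sel.size) < 0.5, "never", "almost-never")
            glasses[sel] = np.nan
            beverage[sel] = "none"
        elif kind == "diet_only":
            beverage[sel] = "diet"
        elif kind == "pregnant":
            sex[sel] = "female"
            pregnant[sel] = True
        elif kind == "extreme_bmi":
            lo = rng.random(sel.size) < 0.5
            bmi[sel] = np.where(lo, rng.uniform(10.0, 14.5, sel.size),
                                rng.uniform(61.0, 75.0, sel.size))
        elif kind == "unknown_quantity":
            glasses[sel] = np.nan

    weight = bmi * height**2
    sample_weight = rng.lognormal(mean=0.0, sigma=cfg.weight_sigma, size=n)

    wave = pd.DataFrame(
        {
            "year": np.full(n, year, dtype=np.int64),
            "sex": sex,
            "age": age.astype(np.int64),
            "weight_sr": np.round(weight, 6),
            "height_sr": np.round(height, 6),
            "freq_category": freq,
            "beverage_type": beverage,
            "glasses_per_day": pd.array(
                [None if np.isnan(g) else int(g) for g in glasses], dtype="Int64"
            ),
            "pregnant": pregnant,
            "sample_weight": np.round(sample_weight, 6),
        },
        columns=list(WAVE_COLUMNS),
    )
    return _coerce_wave(wave)


def generate_waves(cfg: SynthConfig) -> dict[int, pd.DataFrame]:
    """Generate all configured waves, keyed by year."""
    return {year: generate_wave(cfg, year) for year in cfg.years}
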