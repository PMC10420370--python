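import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from fopnlsim import ConversionParams, SurveyRecord, SynthConfig, generate_wave, records_to_wave

settings.register_profile(
    "suite", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def make_record(**overrides) -> SurveyRecord:
    """A kept-by-default consumer record; override fields to trigger filters."""
    base = dict(
        year=2019, sex="male", age=35, weight_sr=75.0, height_sr=1.70,
        freq_category="3-4/wk", beverage_type="regular", glasses_per_day=2,
        pregnant=False, sample_weight=1.0,
    )
    base.update(overrides)
    return SurveyRecord(**base)


@pytest.fixture(scope="session")
def conversion() -> ConversionParams:
    return ConversionParams()


@pytest.fixture(scope="session")
def small_cfg() -> SynthConfig:
    return SynthConfig(n_records=4000, seed=7)


@pytest.fixture(scope="session")
def small_wave(small_cfg) -> pd.DataFrame:
    return generate_wave(small_cfg, 2019)


@pytest.fixture
def toy_wave() -> pd.DataFrame:
    """100 records: 93 valid consumers plus 7 constructed single-rule violators."""
    records = [make_record(sample_weight=1.0 + 0.01 * i) for i in range(93)]
    records += [
        make_record(age=19),
        make_record(age=60),
        make_record(freq_category="never", beverage_type="none", glasses_per_day=None),
        make_record(glasses_per_day=None),
        make_record(beverage_type="diet"),
        make_record(sex="female", pregnant=True),
        make_record(weight_sr=61.0 * 1.7**2, height_sr=1.7),  # BMI 61
    ]
    return records_to_wave(records)
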