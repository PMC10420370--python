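"""Survey record schema and delimited-text I/O.

A survey *wave* is one year of VIGITEL-style telephone interviews. In memory a
wave is a :class:`pandas.DataFrame` with the columns of :data:`WAVE_COLUMNS`;
on disk it is a UTF-8 CSV with a header line, ``.`` decimal separator and that
same column order. :class:`SurveyRecord` is the single-respondent view, used
when constructing small cohorts by hand.

Missing ``glasses_per_day`` is encoded as an empty field. It means either
"question not asked" (never / almost-never consumers) or "respondent did not
know" (consumers); the exclusion filters in :mod:`fopnlsim.intake` distinguish
the two by frequency category.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path
from typing import Iterable

import pandas as pd

#: Allowed soft-drink frequency answers ("how many days a week...").
FREQ_CATEGORIES = ("1-2/wk", "3-4/wk", "5-6/wk", "daily", "almost-never", "never")
#: Frequency answers that mean the respondent is not a consumer.
NON_CONSUMER_FREQS = ("almost-never", "never")
#: Allowed beverage-type answers ("which type?").
BEVERAGE_TYPES = ("regular", "diet", "both", "none")
SEXES = ("male", "female")

#: Canonical wave column order (also the CSV column order).
WAVE_COLUMNS = (
    "year",
    "sex",
    "age",
    "weight_sr",
    "height_sr",
    "freq_category",
    "beverage_type",
    "glasses_per_day",
    "pregnant",
    "sample_weight",
)

_NUMERIC = {
    "year": "int64",
    "age": "int64",
    "weight_sr": "float64",
    "height_sr": "float64",
    "glasses_per_day": "Int64",  # nullable: empty = not asked / did not know
    "sample_weight": "float64",
}


@dataclass
class SurveyRecord:
    """One respondent: anthropometrics, beverage answers and sampling weight.

    ``weight_sr`` / ``height_sr`` are self-reported weight (kg) and height (m);
    ``sample_weight`` is the post-stratification expansion factor.
    """

    year: int
    sex: str
    age: int
    weight_sr: float
    height_sr: float
    freq_category: str
    beverage_type: str
    glasses_per_day: int | None
    pregnant: bool
    sample_weight: float

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if self.freq_category not in FREQ_CATEGORIES:
            raise ValueError(
                f"freq_category must be one of {FREQ_CATEGORIES}, got {self.freq_category!r}"
            )
        if self.beverage_type not in BEVERAGE_TYPES:
            raise ValueError(
                f"beverage_type must be one of {BEVERAGE_TYPES}, got {self.beverage_type!r}"
            )
        if self.age < 0:
            raise ValueError("age must be >= 0")
        if self.weight_sr <= 0 or self.height_sr <= 0:
            raise ValueError("self-reported weight and height must be positive")
        if self.sample_weight < 0:
            raise ValueError("sample_weight must be >= 0")

    @property
    def bmi(self) -> float:
        return self.weight_sr / self.height_sr**2


def records_to_wave(records: Iterable[SurveyRecord]) -> pd.DataFrame:
    """Assemble :class:`SurveyRecord` objects into a wave DataFrame."""
    names = [f.name for f in fields(SurveyRecord)]
    df = pd.DataFrame([{n: getattr(r, n) for n in names} for r in records], columns=list(WAVE_COLUMNS))
    return _coerce_wave(df)


def wave_to_records(wave: pd.DataFrame) -> list[SurveyRecord]:
    out = []
    for row in wave.itertuples(index=False):
        d = row._asdict()
        g = d["glasses_per_day"]
        d["glasses_per_day"] = None if pd.isna(g) else int(g)
        out.append(SurveyRecord(**d))
    return out


def _coerce_wave(df: pd.DataFrame) -> pd.DataFrame:
    for col, dtype in _NUMERIC.items():
        df[col] = df[col].astype(dtype)
    df["pregnant"] = df["pregnant"].astype(bool)
    for col in ("sex", "freq_category", "beverage_type"):
        df[col] = df[col].astype(str)
    return df


def write_wave(path: str | Path, wave: pd.DataFrame) -> None:
    """Write a wave as CSV (header line, documented column order, UTF-8)."""
    missing = [c for c in WAVE_COLUMNS if c not in wave.columns]
    if missing:
        raise ValueError(f"wave is missing columns: {missing}")
    wave.loc[:, list(WAVE_COLUMNS)].to_csv(path, index=False, encoding="utf-8")


def read_wave(path: str | Path) -> pd.DataFrame:
    """Read a wave CSV, validating every field.

    A malformed value raises :class:`ValueError` naming the (1-based, header
    included) line number and the offending column. A header-only file yields
    an empty wave.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8")
    got = tuple(df.columns)
    if got != WAVE_COLUMNS:
        raise ValueError(f"unexpected columns {got}; expected {WAVE_COLUMNS}")
    if df.empty:
        return _coerce_wave(pd.DataFrame(columns=list(WAVE_COLUMNS)))

    out = pd.DataFrame(index=df.index)
    for col, dtype in _NUMERIC.items():
        raw = df[col].str.strip()
        vals = pd.to_numeric(raw.replace("", pd.NA), errors="coerce")
        bad = vals.isna() & (raw != "")
        if col != "glasses_per_day":
            bad |= raw == ""
        if bad.any():
            i = int(bad.idxmax())
            raise ValueError(
                f"line {i + 2}, column {col!r}: cannot parse {df.loc[i, col]!r}"
            )
        out[col] = vals
    for col, allowed in (
        ("sex", SEXES),
        ("freq_category", FREQ_CATEGORIES),
        ("beverage_type", BEVERAGE_TYPES),
    ):
        bad = ~df[col].isin(allowed)
        if bad.any():
            i = int(bad.idxmax())
            raise ValueError(
                f"line {i + 2}, column {col!r}: invalid value {df.loc[i, col]!r}"
            )
        out[col] = df[col]
    bad = ~df["pregnant"].isin(["True", "False"])
    if bad.any():
        i = int(bad.idxmax())
        raise ValueError(
            f"line {i + 2}, column 'pregnant': invalid value {df.loc[i, 'pregnant']!r}"
        )
    out["pregnant"] = df["pregnant"] == "True"
    return _coerce_wave(out.loc[:, list(WAVE_COLUMNS)])
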