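"""Averted cases, percentage-point conversion, cost chain and discounting."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from fopnlsim import (
    CostParams,
    PopulationProjection,
    averted_cases,
    discounted_avoided_cost,
    per_capita_cost,
    prevalence_pp_change,
    synthetic_population,
)

YEARS = list(range(2020, 2025))


def flat_population(count=10_000_000, share=1.0):
    return PopulationProjection(
        years=np.array(YEARS),
        total=np.full(5, float(count)),
        consumer_share=np.full(5, float(share)),
    )


class TestAvertedCases:
    def test_identical_series_avert_nothing(self):
        prev = {y: 0.25 for y in YEARS}
        cases = averted_cases(prev, dict(prev), flat_population())
        assert all(v == 0.0 for v in cases.values())

    def test_half_point_on_ten_million(self):
        base = {2024: 0.255}
        scen = {2024: 0.250}
        cases = averted_cases(base, scen, flat_population())
        assert cases[2024] == pytest.approx(50_000.0)

    def test_consumer_share_scales_cases(self):
        base, scen = {2024: 0.26}, {2024: 0.25}
        full = averted_cases(base, scen, flat_population(share=1.0))[2024]
        half = averted_cases(base, scen, flat_population(share=0.5))[2024]
        assert half == pytest.approx(full / 2)

    def test_misaligned_years_rejected(self):
        with pytest.raises(ValueError, match="misaligned"):
            averted_cases({2024: 0.2}, {2023: 0.2}, flat_population())

    def test_negative_difference_allowed_but_logged(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="fopnlsim.impact"):
            cases = averted_cases({2024: 0.20}, {2024: 0.21}, flat_population())
        assert cases[2024] < 0
        assert any("exceeds base" in rec.message for rec in caplog.records)


class TestPPChange:
    def test_zero_cases_zero_pp(self):
        assert prevalence_pp_change(0.0, 1_000_000) == 0.0

    def test_320k_cases_over_100m_is_minus_032(self):
        assert prevalence_pp_change(320_000, 100_000_000) == pytest.approx(-0.32)

    def test_zero_population_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            prevalence_pp_change(1000, 0.0)


class TestPerCapitaCost:
    def test_trivial_ratio(self):
        params = CostParams(total_cost_2018=1000.0, cost_is_all_ages=False,
                            public_share=1.0, inflation_factor=1.0)
        assert per_capita_cost(params, 100.0)["brl"] == pytest.approx(10.0)

    def test_public_share_divides(self):
        params = CostParams(total_cost_2018=1000.0, cost_is_all_ages=False,
                            public_share=0.715, inflation_factor=1.0)
        assert per_capita_cost(params, 100.0)["brl"] == pytest.approx(1000.0 / 71.5)

    def test_usd_conversion_at_stated_fx(self):
        params = CostParams(total_cost_2018=4030.0, cost_is_all_ages=False,
                            public_share=1.0, inflation_factor=1.0, fx_rate=4.03)
        pc = per_capita_cost(params, 100.0)
        assert pc["brl"] == pytest.approx(40.30)
        assert pc["usd"] == pytest.approx(10.0)

    def test_currency_consistency(self):
        params = CostParams()
        pc = per_capita_cost(params, 1e7)
        assert pc["usd"] * params.fx_rate == pytest.approx(pc["brl"], rel=1e-12)
        assert pc["ppp"] * params.ppp_factor == pytest.approx(pc["brl"], rel=1e-12)

    def test_all_ages_fallback_warns(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="fopnlsim.impact"):
            per_capita_cost(CostParams(), 1e7)
        assert any("all-ages" in rec.message for rec in caplog.records)

    def test_zero_count_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            per_capita_cost(CostParams(), 0.0)


class TestDiscounting:
    def test_zero_rate_is_plain_sum(self):
        params = CostParams(discount_rate=0.0)
        cases = {y: 1000.0 for y in YEARS}
        assert discounted_avoided_cost(cases, 10.0, params) == pytest.approx(50_000.0)

    def test_one_year_at_five_percent(self):
        params = CostParams(discount_rate=0.05, base_year=2019)
        assert discounted_avoided_cost({2020: 10.0}, 10.0, params) == pytest.approx(100.0 / 1.05)

    @given(rate=st.floats(min_value=0.0, max_value=0.5))
    def test_discounted_never_exceeds_undiscounted(self, rate):
        params = CostParams(discount_rate=rate)
        cases = {y: 1000.0 for y in YEARS}
        disc = discounted_avoided_cost(cases, 10.0, params)
        plain = sum(cases.values()) * 10.0
        assert disc <= plain + 1e-9
        if rate == 0.0:
            assert disc == pytest.approx(plain)

    def test_out_of_window_year_rejected(self):
        with pytest.raises(ValueError, match="2020-2024"):
            discounted_avoided_cost({2019: 10.0}, 10.0, CostParams())


class TestPopulation:
    def test_synthetic_population_is_positive_and_bounded(self):
        pop = synthetic_population(YEARS, {y: 0.3 for y in YEARS})
        assert (pop.total > 0).all()
        assert ((pop.consumer_share >= 0) & (pop.consumer_share <= 1)).all()

    def test_read_population_csv(self, tmp_path):
        from fopnlsim.impact import read_population_csv

        path = tmp_path / "pop.csv"
        path.write_text("year,count\n2020,1000000\n2021,1010000\n")
        pop = read_population_csv(path, 0.25)
        assert pop.at(2021) == (1_010_000.0, 0.25)
        with pytest.raises(KeyError, match="2030"):
            pop.at(2030)
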