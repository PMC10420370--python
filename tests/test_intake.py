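"""Exclusion filters, answer-to-intake conversion and weighted means."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from fopnlsim import (
    ConversionParams,
    apply_filters,
    estimate_intake,
    estimate_intake_wave,
    records_to_wave,
    weighted_mean,
)

from conftest import make_record


class TestFilters:
    def test_constructed_violators_are_tallied(self, toy_wave):
        kept, tally = apply_filters(toy_wave)
        assert len(kept) == 93
        assert tally == {
            "age": 2,
            "never_consumer": 1,
            "unknown_quantity": 1,
            "diet_only": 1,
            "pregnancy": 1,
            "extreme_bmi": 1,
        }
        assert sum(tally.values()) == len(toy_wave) - len(kept)

    @pytest.mark.parametrize(
        "overrides, reason",
        [
            (dict(age=19), "age"),
            (dict(age=60), "age"),
            (dict(weight_sr=61.0 * 1.7**2, height_sr=1.7), "extreme_bmi"),
            (dict(weight_sr=14.9 * 1.7**2, height_sr=1.7), "extreme_bmi"),
            (dict(freq_category="almost-never", beverage_type="none",
                  glasses_per_day=None), "never_consumer"),
            (dict(beverage_type="diet"), "diet_only"),
        ],
    )
    def test_boundary_exclusions(self, overrides, reason):
        wave = records_to_wave([make_record(**overrides)])
        kept, tally = apply_filters(wave)
        assert len(kept) == 0
        assert tally[reason] == 1

    def test_boundaries_kept(self):
        keepers = [
            make_record(age=20),
            make_record(age=59),
            make_record(weight_sr=15.0 * 1.7**2, height_sr=1.7),  # BMI exactly 15
            make_record(weight_sr=60.0 * 1.7**2, height_sr=1.7),  # BMI exactly 60
            make_record(beverage_type="both"),
        ]
        kept, _ = apply_filters(records_to_wave(keepers))
        assert len(kept) == len(keepers)

    def test_precedence_first_matching_reason(self):
        # violates both age and pregnancy: counted once, under age
        wave = records_to_wave([make_record(sex="female", age=17, pregnant=True)])
        _, tally = apply_filters(wave)
        assert tally["age"] == 1 and tally["pregnancy"] == 0

    def test_idempotence(self, small_wave):
        kept1, _ = apply_filters(small_wave)
        kept2, tally2 = apply_filters(kept1)
        assert len(kept2) == len(kept1)
        assert all(v == 0 for v in tally2.values())

    def test_missing_field_named(self, toy_wave):
        with pytest.raises(ValueError, match="missing filter fields.*age"):
            apply_filters(toy_wave.drop(columns=["age"]))


class TestEstimate:
    def test_daily_one_glass(self, conversion):
        rec = make_record(freq_category="daily", glasses_per_day=1)
        est = estimate_intake(rec, conversion)
        assert est.volume == pytest.approx(300.0)
        assert est.energy == pytest.approx(126.0)  # 300 mL * 42 kcal/100 mL
        assert est.sodium == pytest.approx(30.0)

    def test_one_two_days_two_glasses(self, conversion):
        rec = make_record(freq_category="1-2/wk", glasses_per_day=2)
        est = estimate_intake(rec, conversion)
        assert est.volume == pytest.approx(1.5 / 7 * 2 * 300, abs=1e-9)
        assert est.volume == pytest.approx(128.5714, abs=1e-3)

    def test_non_consumer_rejected(self, conversion):
        rec = make_record(freq_category="never", beverage_type="none", glasses_per_day=None)
        with pytest.raises(ValueError, match="days-per-week"):
            estimate_intake(rec, conversion)
        rec = make_record(glasses_per_day=None)
        with pytest.raises(ValueError, match="filtered"):
            estimate_intake(rec, conversion)

    @given(scale=st.floats(min_value=0.1, max_value=10.0, allow_nan=False))
    def test_linearity_in_serving_volume(self, scale):
        base = ConversionParams()
        scaled = ConversionParams(serving_volume=base.serving_volume * scale)
        rec = make_record(freq_category="3-4/wk", glasses_per_day=3)
        a, b = estimate_intake(rec, base), estimate_intake(rec, scaled)
        assert b.volume == pytest.approx(a.volume * scale, rel=1e-12)
        assert b.energy == pytest.approx(a.energy * scale, rel=1e-12)
        assert b.sodium == pytest.approx(a.sodium * scale, rel=1e-12)

    def test_wave_estimation_matches_record_estimation(self, small_wave, conversion):
        kept, _ = apply_filters(small_wave)
        est = estimate_intake_wave(kept.head(50), conversion)
        from fopnlsim import wave_to_records

        for row, rec in zip(est.itertuples(), wave_to_records(kept.head(50))):
            single = estimate_intake(rec, conversion)
            assert row.volume == pytest.approx(single.volume)
            assert row.energy == pytest.approx(single.energy)


class TestWeightedMean:
    def test_equal_weights(self):
        mean, _, _ = weighted_mean([100.0, 300.0], [1.0, 1.0])
        assert mean == pytest.approx(200.0)

    def test_unequal_weights(self):
        mean, _, _ = weighted_mean([100.0, 300.0], [1.0, 3.0])
        assert mean == pytest.approx(250.0)

    def test_all_zero_weights_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            weighted_mean([1.0, 2.0], [0.0, 0.0])

    @given(
        st.lists(
            st.tuples(
                st.floats(min_value=-1e3, max_value=1e3),
                st.floats(min_value=0.01, max_value=50.0),
            ),
            min_size=1,
            max_size=40,
        )
    )
    def test_mean_within_range_and_ci_brackets_mean(self, pairs):
        values = [p[0] for p in pairs]
        weights = [p[1] for p in pairs]
        mean, se, (lo, hi) = weighted_mean(values, weights)
        assert min(values) - 1e-9 <= mean <= max(values) + 1e-9
        assert lo <= mean <= hi and se >= 0
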