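"""Energy-balance weight model: steady state, dynamics, classification, cohorts."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from fopnlsim import (
    WeightModelParams,
    classify_bmi,
    cohort_update,
    simulate_weight,
)
from fopnlsim.bodyweight import propagate_yearly

PARAMS = WeightModelParams()


def sustained(dei, years=5):
    return np.full(years, float(dei)), np.zeros(years)


class TestSimulateWeight:
    def test_zero_change_keeps_weight_constant(self):
        dei, dna = sustained(0.0)
        traj = simulate_weight(75.4, 1.687, 36, "male", dei, dna)
        assert np.allclose(traj.weight, 75.4)
        assert np.allclose(traj.bmi, 75.4 / 1.687**2)

    def test_steady_state_equals_dei_over_rho(self):
        """-100 kJ/day (-23.9 kcal/day) sustained forever converges to -1 kg."""
        dei, dna = sustained(-23.9, years=80)
        traj = simulate_weight(75.0, 1.70, 36, "male", dei, dna)
        assert traj.weight_change == pytest.approx(-1.0, abs=1e-9)

    def test_convergence_gap_below_1pct_at_5_tau(self):
        years = int(np.ceil(5 * PARAMS.tau))
        dei, dna = sustained(-28.0, years=years)
        traj = simulate_weight(75.4, 1.687, 36, "male", dei, dna)
        eq = -28.0 / PARAMS.rho
        at_5tau = np.interp(5 * PARAMS.tau, traj.times, traj.weight) - 75.4
        assert abs(at_5tau - eq) < 0.01 * abs(eq)

    @given(dei=st.floats(min_value=-500.0, max_value=-1.0))
    def test_energy_channel_linearity(self, dei):
        d1, dna = sustained(dei)
        d2, _ = sustained(2 * dei)
        t1 = simulate_weight(75.0, 1.70, 36, "male", d1, dna)
        t2 = simulate_weight(75.0, 1.70, 36, "male", d2, dna)
        assert np.allclose(t2.weight - 75.0, 2 * (t1.weight - 75.0), rtol=1e-10, atol=1e-12)

    def test_monotonicity_in_sustained_deficit(self):
        trajs = [
            simulate_weight(75.0, 1.70, 36, "male", *sustained(dei))
            for dei in (-10.0, -28.0, -50.0)
        ]
        for shallow, deep in zip(trajs, trajs[1:]):
            assert (deep.weight <= shallow.weight + 1e-12).all()

    def test_sodium_channel_negligible_at_study_scale(self):
        dei = np.zeros(5)
        dna = np.full(5, -1.3)  # mg/day, scenario-scale sodium delta
        traj = simulate_weight(75.0, 1.70, 36, "male", dei, dna)
        assert np.abs(traj.weight - 75.0).max() < 0.01

    def test_sodium_channel_fast_equilibration(self):
        dna = np.full(1, -3000.0)  # 1 L ECF shift at default concentration
        traj = simulate_weight(75.0, 1.70, 36, "male", np.zeros(1), dna)
        after_month = np.interp(1 / 12, traj.times, traj.weight) - 75.0
        assert after_month == pytest.approx(-1.0, abs=0.02)

    def test_invalid_inputs_rejected(self):
        dei, dna = sustained(-28.0)
        with pytest.raises(ValueError, match="initial_weight"):
            simulate_weight(-5.0, 1.70, 36, "male", dei, dna)
        with pytest.raises(ValueError, match="finite"):
            simulate_weight(75.0, 1.70, 36, "male", np.full(5, np.nan), dna)
        with pytest.raises(ValueError, match="equal-length"):
            simulate_weight(75.0, 1.70, 36, "male", dei, dna[:3])


class TestClassify:
    @pytest.mark.parametrize(
        "bmi, obese, excess",
        [(30.0, True, True), (26.5, False, True), (24.99, False, False),
         (25.0, False, True), (45.0, True, True)],
    )
    def test_cutoffs_inclusive(self, bmi, obese, excess):
        assert classify_bmi(bmi) == (obese, excess)

    def test_obese_implies_excess(self):
        for bmi in np.linspace(15, 60, 91):
            ob, ex = classify_bmi(float(bmi))
            assert not ob or ex

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            classify_bmi(0.0)


class TestCohort:
    @staticmethod
    def toy_cohort():
        return pd.DataFrame(
            {
                "weight_sr": [70.0, 90.0],
                "height_sr": [1.70, 1.80],
                "sample_weight": [1.0, 3.0],
            }
        )

    def test_zero_changes_keep_prevalence(self):
        cohort = self.toy_cohort()
        d = np.zeros((2, 5))
        _, yearly = cohort_update(cohort, d, d)
        base_bmi = cohort["weight_sr"] / cohort["height_sr"] ** 2
        expected_prev = float(
            (base_bmi >= 30).astype(float).mul(cohort["sample_weight"]).sum()
            / cohort["sample_weight"].sum()
        )
        assert np.allclose(yearly["obesity_prevalence"], expected_prev)
        assert np.allclose(yearly["mean_weight_change"], 0.0)

    def test_hand_computed_weighted_mean_change(self):
        """Two-record cohort against closed-form first-order arithmetic."""
        cohort = self.toy_cohort()
        dei = np.array([[-20.0] * 5, [-40.0] * 5])
        dna = np.zeros((2, 5))
        per_record, yearly = cohort_update(cohort, dei, dna)
        decay = np.exp(-5.0 / PARAMS.tau)
        expected = {dei_i: dei_i / PARAMS.rho * (1 - decay) for dei_i in (-20.0, -40.0)}
        assert per_record["final_weight"].iloc[0] == pytest.approx(70.0 + expected[-20.0])
        assert per_record["final_weight"].iloc[1] == pytest.approx(90.0 + expected[-40.0])
        hand_mean = (1.0 * expected[-20.0] + 3.0 * expected[-40.0]) / 4.0
        assert yearly["mean_weight_change"].iloc[-1] == pytest.approx(hand_mean)

    def test_propagate_matches_trajectory_at_year_ends(self):
        dei = np.array([[-28.0, -30.0, -32.0, -34.0, -36.0]])
        dna = np.zeros((1, 5))
        mat = propagate_yearly(dei, dna, PARAMS)
        traj = simulate_weight(75.4, 1.687, 36, "male", dei[0], dna[0])
        for t in range(5):
            at_year = np.interp(t + 1.0, traj.times, traj.weight) - 75.4
            assert mat[0, t] == pytest.approx(at_year, abs=1e-9)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="cohort of 2"):
            cohort_update(self.toy_cohort(), np.zeros((3, 5)), np.zeros((3, 5)))
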