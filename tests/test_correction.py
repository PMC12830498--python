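"""Decay factor, regression correction, loss adjustment, plan assembly."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from itemprecision import (
    ALL_DECILE_COEFFS,
    FOURTH_DECILE_COEFFS,
    ProportionSummary,
    apply_decay,
    calculate_correction,
    decay_factor,
    loss_adjust,
    regression_correction,
)

# Worked examples: the two applied-correction case studies — a 1-5
# concreteness rating pilot (n=29, prop var 0.14) and a response-latency
# pilot (n=33, prop var 0.0809) — at the four nominal target levels.
WORKED_ROWS = [
    (45, 29, 0.14, 80, 39.63),
    (45, 29, 0.14, 85, 39.29),
    (50, 29, 0.14, 90, 45.30),
    (55, 29, 0.14, 95, 51.21),
    (60, 33, 0.0809, 80, 54.08),
    (75, 33, 0.0809, 85, 68.12),
    (90, 33, 0.0809, 90, 80.87),
    (125, 33, 0.0809, 95, 107.09),
]


class TestDecayFactor:
    def test_zero_decay_at_minimum(self):
        assert decay_factor(20, 20) == 1.0

    @pytest.mark.parametrize(
        "n_pilot, min_sim, expected",
        [(100, 20, 0.5235), (40, 20, 0.8419)],
    )
    def test_hand_oracle_values(self, n_pilot, min_sim, expected):
        # direct arithmetic: 1 - sqrt((N-m)/N)^log2(N)
        direct = 1 - math.sqrt((n_pilot - min_sim) / n_pilot) ** math.log2(n_pilot)
        assert decay_factor(n_pilot, min_sim) == pytest.approx(direct, abs=1e-12)
        assert decay_factor(n_pilot, min_sim) == pytest.approx(expected, abs=5e-5)

    def test_strictly_decreasing_in_pilot_size(self):
        factors = [decay_factor(n, 20) for n in range(20, 400, 10)]
        assert all(a > b for a, b in zip(factors, factors[1:]))

    @given(n=st.integers(20, 5000), m=st.integers(2, 20))
    @settings(max_examples=100, deadline=None)
    def test_bounded_unit_interval(self, n, m):
        f = decay_factor(n, m)
        assert 0.0 < f <= 1.0
        assert (f == 1.0) == (n == m)

    def test_pilot_below_minimum_rejected(self):
        with pytest.raises(ValueError):
            decay_factor(10, 20)


class TestApplyDecay:
    def test_identity_at_no_decay(self):
        assert apply_decay(100, 20, 20) == 100

    def test_product_of_oracle_values(self):
        assert apply_decay(200, 100, 20) == pytest.approx(200 * 0.523490, abs=0.01)

    def test_monotone_in_pilot_size(self):
        assert apply_decay(150, 60, 20) > apply_decay(150, 90, 20)


class TestRegressionCorrection:
    @pytest.mark.parametrize("proj, pilot, pv, power, expected", WORKED_ROWS)
    def test_reproduces_worked_corrections(self, proj, pilot, pv, power, expected):
        got = regression_correction(proj, pilot, pv, power, FOURTH_DECILE_COEFFS)
        assert got == pytest.approx(expected, abs=0.1)

    def test_alternate_coefficient_set_differs(self):
        a = regression_correction(45, 29, 0.14, 80, FOURTH_DECILE_COEFFS)
        b = regression_correction(45, 29, 0.14, 80, ALL_DECILE_COEFFS)
        assert a != pytest.approx(b, abs=1.0)

    def test_zero_prop_var_rejected(self):
        with pytest.raises(ValueError, match="prop_var"):
            regression_correction(45, 29, 0.0, 80)

    def test_power_outside_percent_range_rejected(self):
        with pytest.raises(ValueError):
            regression_correction(45, 29, 0.14, 101)
        with pytest.raises(ValueError):
            regression_correction(45, 29, 0.14, 0)


class TestLossAdjust:
    def test_full_retention_is_ceiling(self):
        assert loss_adjust(39.63, 1.0) == 40

    @pytest.mark.parametrize(
        "n, retention, expected",
        [(50, 0.8, 63), (39.63, 0.93, 43)],
    )
    def test_hand_values(self, n, retention, expected):
        assert loss_adjust(n, retention) == expected

    def test_non_increasing_in_retention(self):
        values = [loss_adjust(80, r) for r in (0.5, 0.7, 0.9, 1.0)]
        assert all(a >= b for a, b in zip(values, values[1:]))

    def test_invalid_retention(self):
        with pytest.raises(ValueError):
            loss_adjust(50, 0.0)


class TestCalculateCorrection:
    summary = ProportionSummary.from_pairs(
        [(40, 0.70), (45, 0.82), (50, 0.91), (55, 0.951), (60, 0.97)]
    )

    def test_all_levels_reached_rows_consistent(self):
        plan = calculate_correction(
            self.summary, pilot_n=29, prop_var=0.14,
            power_levels=(80, 85, 90, 95), se_cutoff=0.18,
        )
        assert [r.level for r in plan.rows] == [80, 85, 90, 95]
        assert all(r.reached for r in plan.rows)
        # each row's correction equals a direct evaluation at achieved power
        for r in plan.rows:
            direct = regression_correction(
                r.projected_n, 29, 0.14, r.achieved_percent
            )
            assert r.corrected_n == pytest.approx(max(direct, 40.0))
        assert plan.minimum_n == plan.rows[0].final_n
        assert plan.maximum_n == plan.rows[-1].final_n
        assert plan.minimum_n <= plan.maximum_n

    def test_unreached_level_marked_and_excluded(self):
        summary = ProportionSummary.from_pairs([(20, 0.82), (25, 0.86)])
        plan = calculate_correction(
            summary, pilot_n=29, prop_var=0.14, power_levels=(80, 85, 90, 95)
        )
        reached = [r for r in plan.rows if r.reached]
        assert len(reached) == 2
        assert plan.rows[-1].projected_n is None
        assert plan.maximum_n == reached[-1].final_n

    def test_nominal_power_reproduces_worked_corrections(self):
        # feed curves whose first crossings are the worked projected sizes
        concrete = ProportionSummary.from_pairs(
            [(40, 0.79), (45, 0.87), (50, 0.92), (55, 0.96)]
        )
        plan = calculate_correction(
            concrete, pilot_n=29, prop_var=0.14,
            power_levels=(80, 85, 90, 95), use_achieved_power=False,
            grid_start=20,
        )
        expected = {80: 39.63, 85: 39.29, 90: 45.30, 95: 51.21}
        for r in plan.rows:
            assert r.corrected_n == pytest.approx(expected[r.level], abs=0.1)

    def test_sub_grid_correction_floored_with_warning(self):
        summary = ProportionSummary.from_pairs([(20, 0.99)])
        with pytest.warns(UserWarning, match="floor"):
            plan = calculate_correction(
                summary, pilot_n=200, prop_var=0.01, power_levels=(80,)
            )
        assert plan.rows[0].corrected_n == 20.0

    def test_retention_inflates_final_sizes(self):
        base = calculate_correction(
            self.summary, pilot_n=29, prop_var=0.14, power_levels=(80,)
        )
        lossy = calculate_correction(
            self.summary, pilot_n=29, prop_var=0.14, power_levels=(80,),
            retention=0.8,
        )
        assert lossy.rows[0].final_n >= base.rows[0].final_n
        assert lossy.rows[0].final_n == math.ceil(base.rows[0].corrected_n / 0.8)
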