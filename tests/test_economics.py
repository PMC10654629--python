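"""Discounting, accrual, ICER/INMB decision rules, donation schedules."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate

from escc_cea import (
    CostProfile,
    ModelSettings,
    UtilitySet,
    WeibullParams,
    accrue,
    build_trace,
    compare,
    discount_factor,
    donation_schedule_cost,
    mean_survival,
    weibull_survival,
)
from escc_cea.exceptions import ValidationError

WTP = 37_663.26


class TestDiscountFactor:
    def test_known_values(self):
        assert discount_factor(0, 0.05) == 1.0
        assert discount_factor(12, 0.05) == pytest.approx(1 / 1.05, rel=1e-12)
        assert discount_factor(120, 0.0) == 1.0

    def test_strictly_decreasing_for_positive_rate(self):
        d = discount_factor(np.arange(0, 121), 0.05)
        assert np.all(np.diff(d) < 0)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValidationError):
            discount_factor(1, -0.05)


class TestAccrue:
    def test_zero_costs_and_utilities(self, config):
        trace = build_trace(WeibullParams(0.0594, 1.275), WeibullParams(0.0119, 1.478), config.settings)
        cost, qalys = accrue(
            trace,
            CostProfile({"drug": 0.0}, 0.0),
            UtilitySet(0.0, 0.0),
            config.settings,
        )
        assert cost == 0.0
        assert qalys == 0.0

    def test_undiscounted_life_years_match_restricted_mean_survival(self):
        # utilities (1,1), no discounting: QALYs = mean time alive over horizon / 12
        os_params = WeibullParams(0.0119, 1.478)
        settings_ = ModelSettings(
            horizon_cycles=120, discount_rate_annual=0.0, half_cycle_correction=True
        )
        trace = build_trace(WeibullParams(0.0594, 1.275), os_params, settings_)
        _, qalys = accrue(trace, CostProfile({}, 0.0), UtilitySet(1.0, 1.0), settings_)
        rmst, _ = integrate.quad(lambda t: weibull_survival(os_params, t), 0, 120)
        assert qalys == pytest.approx(rmst / 12.0, rel=2e-3)  # trapezoid vs exact integral

    def test_horizon_mismatch_rejected(self, config):
        short = ModelSettings(horizon_cycles=12)
        trace = build_trace(WeibullParams(0.05, 1.2), WeibullParams(0.01, 1.4), short)
        with pytest.raises(ValidationError):
            accrue(trace, CostProfile({}, 0.0), config.utilities, config.settings)

    def test_long_horizon_life_months_approach_mean_survival(self):
        os_params = WeibullParams(0.0119, 1.478)
        settings_ = ModelSettings(horizon_cycles=600, discount_rate_annual=0.0)
        trace = build_trace(WeibullParams(0.0594, 1.275), os_params, settings_)
        _, qalys = accrue(trace, CostProfile({}, 0.0), UtilitySet(1.0, 1.0), settings_)
        assert qalys * 12 == pytest.approx(mean_survival(os_params), rel=1e-3)


class TestCompare:
    def test_printed_icer_reproduced_to_the_cent(self):
        res = compare((29_547.88, 0.16), (0.0, 0.0), WTP)
        assert round(res.icer, 2) == 184_674.25

    def test_printed_inmb_reproduced_to_the_cent(self):
        res = compare((37_118.97, 0.29), (0.0, 0.0), WTP)
        assert round(res.inmb, 2) == -26_196.62

    def test_zero_effect_difference(self):
        res = compare((100.0, 0.5), (50.0, 0.5), WTP)
        assert not res.icer_defined
        assert math.isnan(res.icer)
        assert res.inmb == pytest.approx(-50.0)

    def test_dominance_labels(self):
        assert compare((10.0, 2.0), (20.0, 1.0), WTP).dominance == "a_dominates"
        assert compare((20.0, 1.0), (10.0, 2.0), WTP).dominance == "b_dominates"
        assert compare((20.0, 2.0), (10.0, 1.0), WTP).dominance == ""

    @given(
        dc=st.floats(-1e5, 1e5),
        de=st.floats(1e-4, 2.0),
        wtp=st.floats(1e3, 3e5),
    )
    @settings(max_examples=200, deadline=None)
    def test_inmb_positive_iff_icer_below_wtp(self, dc, de, wtp):
        res = compare((dc, de), (0.0, 0.0), wtp)
        assert (res.inmb > 0) == (res.icer < wtp)


class TestDonationSchedule:
    def _icer(self, config, costs_a):
        from escc_cea.model import evaluate_arm
        from escc_cea.config import StrategyDefinition

        pop = config.populations["cps_ge1"]
        a = evaluate_arm(
            StrategyDefinition("a", costs_a, pop["intervention"]["pfs"], pop["intervention"]["os"]),
            config.utilities,
            config.settings,
        )
        b = evaluate_arm(config.strategy("cps_ge1", "comparator"), config.utilities, config.settings)
        return compare(a, b, WTP).icer

    def test_identity_schedule_matches_base(self, config):
        base = config.costs["intervention"]
        capped = donation_schedule_cost(base, lambda t: 1.0, cap_cycles=10_000)
        assert self._icer(config, capped) == pytest.approx(self._icer(config, base), rel=1e-12)

    def test_free_drug_removes_its_contribution(self, config):
        base = config.costs["intervention"]
        free = donation_schedule_cost(base, lambda t: 0.0, cap_cycles=0)
        no_drug = CostProfile(
            {k: (0.0 if k == "serplulimab" else v) for k, v in base.pfs_components.items()},
            base.pd_per_cycle,
        )
        assert self._icer(config, free) == pytest.approx(self._icer(config, no_drug), rel=1e-12)

    def test_pay_free_blocks_lower_icer(self, config):
        # pay 3 cycles / free 3 cycles / pay 3 / free until cap at 24 cycles
        base = config.costs["intervention"]

        def schedule(t):
            if t < 3 or 6 <= t < 9:
                return 1.0
            return 0.0

        donated = donation_schedule_cost(base, schedule, cap_cycles=24)
        assert self._icer(config, donated) < self._icer(config, base)

    def test_invalid_multiplier_rejected(self, config):
        with pytest.raises(ValidationError):
            donation_schedule_cost(config.costs["intervention"], lambda t: 1.5, cap_cycles=5)


class TestCostProfileValidation:
    def test_negative_component_rejected(self):
        with pytest.raises(ValidationError):
            CostProfile({"drug": -1.0}, 0.0)

    def test_utility_ordering_enforced(self):
        with pytest.raises(ValidationError):
            UtilitySet(u_pfs=0.4, u_pd=0.6)
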