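"""Weibull evaluation, transition probabilities, summary statistics, and MLE."""

import math

import numpy as np
import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as st
from scipy import integrate, optimize

from escc_cea import (
    PseudoIPD,
    WeibullParams,
    fit_weibull_mle,
    mean_survival,
    median_survival,
    transition_probability,
    weibull_survival,
)
from escc_cea.exceptions import FittingError, ValidationError

OS_COMBO = WeibullParams(0.0119, 1.478)

params_st = st.builds(
    WeibullParams,
    scale_lambda=st.floats(1e-3, 0.5),
    shape_gamma=st.floats(0.3, 3.0),
)


class TestWeibullSurvival:
    def test_starts_at_one_and_vanishes(self):
        assert weibull_survival(OS_COMBO, 0.0) == 1.0
        assert weibull_survival(WeibullParams(0.0594, 1.275), 1e6) == pytest.approx(0.0, abs=1e-12)

    def test_median_crossing_found_by_bisection(self):
        # independent root-find of S(t) = 1/2; trial-consistent (~15.3 mo reported OS median)
        t_half = optimize.brentq(lambda t: weibull_survival(OS_COMBO, t) - 0.5, 1.0, 100.0)
        assert t_half == pytest.approx(15.65, abs=0.05)
        assert weibull_survival(OS_COMBO, t_half) == pytest.approx(0.5, abs=1e-9)

    def test_negative_time_rejected(self):
        with pytest.raises(ValidationError):
            weibull_survival(OS_COMBO, -1.0)

    @given(params=params_st)
    @settings(max_examples=50, deadline=None)
    def test_non_increasing(self, params):
        t = np.linspace(0, 60, 121)
        s = weibull_survival(params, t)
        assert np.all(np.diff(s) <= 1e-15)
        assert np.all((s >= 0) & (s <= 1))


class TestTransitionProbability:
    def test_single_cycle_value(self):
        # 1 - S(1)/S(0) with S(1) = exp(-0.0119)
        assert transition_probability(OS_COMBO, 1, 1) == pytest.approx(
            1 - math.exp(-0.0119), rel=1e-12
        )

    def test_zero_length_interval(self):
        assert transition_probability(OS_COMBO, 5, 0) == 0.0

    def test_domain_error(self):
        with pytest.raises(ValidationError):
            transition_probability(OS_COMBO, 1, 2)

    def test_increasing_hazard_gives_increasing_exit_probability(self):
        p = WeibullParams(0.05, 1.4)
        vals = [transition_probability(p, t, 1) for t in range(1, 61)]
        assert all(b > a for a, b in zip(vals, vals[1:]))

    @given(params=params_st, t=st.integers(1, 120))
    @settings(max_examples=100, deadline=None)
    def test_consistent_with_survival_ratio(self, params, t):
        # 1 - P(t, 1) must equal S(t)/S(t-1) to machine precision
        s_prev = weibull_survival(params, float(t - 1))
        assume(s_prev > 1e-300)  # ratio well-defined only before underflow
        lhs = 1.0 - transition_probability(params, t, 1)
        rhs = weibull_survival(params, float(t)) / s_prev
        assert lhs == pytest.approx(rhs, rel=1e-12)


class TestSummaryStatistics:
    def test_median_closed_form_matches_bisection(self):
        med = median_survival(OS_COMBO)
        assert med == pytest.approx(15.65, abs=0.05)
        t_half = optimize.brentq(lambda t: weibull_survival(OS_COMBO, t) - 0.5, 1.0, 100.0)
        assert med == pytest.approx(t_half, rel=1e-9)

    def test_unit_median_exponential(self):
        assert median_survival(WeibullParams(math.log(2), 1.0)) == pytest.approx(1.0)

    def test_mean_matches_numerical_integration(self):
        mean = mean_survival(OS_COMBO)
        assert mean == pytest.approx(18.2, abs=0.1)
        numeric, _ = integrate.quad(lambda t: weibull_survival(OS_COMBO, t), 0, 1000)
        assert mean == pytest.approx(numeric, rel=1e-6)

    @given(
        params=st.builds(
            # clinically plausible region: the trapezoid grid resolves the curve
            WeibullParams,
            scale_lambda=st.floats(5e-3, 0.3),
            shape_gamma=st.floats(0.8, 3.0),
        )
    )
    @settings(max_examples=25, deadline=None)
    def test_mean_vs_trapezoid(self, params):
        # integrate out to where the cumulative hazard reaches ~30 (S < 1e-13)
        t_max = (30.0 / params.scale_lambda) ** (1.0 / params.shape_gamma)
        t = np.linspace(0, t_max, 400_001)
        trapz = np.trapezoid(weibull_survival(params, t), t)
        assert mean_survival(params) == pytest.approx(trapz, rel=1e-4)


def _simulate_ipd(lam, gam, n, seed, censor=None):
    rng = np.random.default_rng(seed)
    t = (-np.log(rng.uniform(size=n)) / lam) ** (1.0 / gam)
    if censor is None:
        e = np.ones(n, dtype=int)
    else:
        e = (t <= censor).astype(int)
        t = np.minimum(t, censor)
    return PseudoIPD(tuple(float(x) for x in t), tuple(int(x) for x in e))


class TestWeibullMLE:
    def test_parameter_recovery_uncensored(self):
        ipd = _simulate_ipd(0.06, 1.3, 2000, seed=11)
        fit = fit_weibull_mle(ipd)
        assert fit.params.scale_lambda == pytest.approx(0.06, abs=0.01)
        assert fit.params.shape_gamma == pytest.approx(1.3, abs=0.1)

    def test_recovery_under_administrative_censoring(self):
        ipd = _simulate_ipd(0.0119, 1.478, 2000, seed=5, censor=24.0)
        fit = fit_weibull_mle(ipd)
        assert abs(fit.params.scale_lambda - 0.0119) < 2 * fit.se_lambda
        assert abs(fit.params.shape_gamma - 1.478) < 2 * fit.se_gamma

    def test_fixed_shape_reduces_to_exponential_mle(self):
        ipd = PseudoIPD((2.0, 3.0, 7.0), (1, 1, 0))
        fit = fit_weibull_mle(ipd, fix_gamma=1.0)
        assert fit.params.scale_lambda == pytest.approx(2 / 12.0, rel=1e-12)

    def test_single_event_allowed_only_with_fixed_shape(self):
        ipd = PseudoIPD((4.0, 6.0), (1, 0))
        assert fit_weibull_mle(ipd, fix_gamma=1.0).params.scale_lambda == pytest.approx(0.1)
        with pytest.raises(FittingError):
            fit_weibull_mle(ipd)

    def test_all_censored_rejected(self):
        with pytest.raises(FittingError):
            fit_weibull_mle(PseudoIPD((1.0, 2.0, 3.0), (0, 0, 0)))

    def test_consistency_bias_shrinks_with_n(self):
        errs = {}
        for n in (200, 2000):
            lam_err = []
            gam_err = []
            for seed in range(5):
                fit = fit_weibull_mle(_simulate_ipd(0.06, 1.3, n, seed=100 + seed))
                lam_err.append(fit.params.scale_lambda - 0.06)
                gam_err.append(fit.params.shape_gamma - 1.3)
            errs[n] = (np.mean(np.abs(lam_err)), np.mean(np.abs(gam_err)))
        assert errs[2000][0] < errs[200][0]
        assert errs[2000][1] < errs[200][1]


class TestParamValidation:
    @pytest.mark.parametrize("lam,gam", [(-0.1, 1.0), (0.0, 1.0), (0.1, 0.0), (0.1, -2.0)])
    def test_positivity_enforced(self, lam, gam):
        with pytest.raises(ValidationError):
            WeibullParams(lam, gam)
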