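"""Unit and property tests for the two-point kinetics estimators."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stbrproc.kinetics import (FALLBACK_FLOOR, KineticsError, log_mean,
                               passage_kinetics, q_glc_batch, q_glc_perfusion,
                               q_lac_batch, q_lac_perfusion,
                               specific_growth_rate, yield_coefficient)
from stbrproc.process_data import (PassageRecord, PerfusionSchedule,
                                   PerfusionSegment, ProcessSample)

positive = st.floats(min_value=1e-6, max_value=1e12, allow_nan=False,
                     allow_infinity=False)


def sample(t, X=1e6, glc=10.0, lac=10.0):
    return ProcessSample(t=t, X=X, glc=glc, lac=lac)


class TestLogMean:
    @pytest.mark.parametrize("a,b,expected", [
        (2.0, 2.0, 2.0),                      # equal-endpoint limit
        (2e9, 1e9, 1e9 / math.log(2.0)),      # 1.442695e9
        (math.e, 1.0, math.e - 1.0),
    ])
    def test_closed_forms(self, a, b, expected):
        lm = log_mean(a, b)
        assert lm.value == pytest.approx(expected, rel=1e-12)
        assert not lm.fallback_used

    def test_zero_endpoint_uses_arithmetic_fallback(self):
        lm = log_mean(0.0, 5.0)
        assert lm.value == 2.5
        assert lm.fallback_used

    def test_both_nonpositive_is_domain_error(self):
        with pytest.raises(KineticsError):
            log_mean(0.0, 0.0)
        with pytest.raises(KineticsError):
            log_mean(-1.0, -2.0)

    @settings(max_examples=200, derandomize=True)
    @given(a=positive, b=positive)
    def test_between_endpoints_and_below_arithmetic_mean(self, a, b):
        lm = log_mean(a, b).value
        lo, hi = min(a, b), max(a, b)
        assert lo <= lm * (1 + 1e-12)
        assert lm <= hi * (1 + 1e-12)
        assert lm <= (a + b) / 2 * (1 + 1e-12)


class TestSpecificGrowthRate:
    def test_doubling_in_one_day_is_ln2(self):
        mu = specific_growth_rate(sample(0.0, X=5e5), sample(1.0, X=1e6))
        assert mu == pytest.approx(math.log(2.0), rel=1e-12)

    def test_constant_density_gives_zero(self):
        assert specific_growth_rate(sample(0.0, X=7e5), sample(2.0, X=7e5)) == 0.0

    def test_declining_density_is_negative(self):
        assert specific_growth_rate(sample(0.0, X=1e6), sample(1.0, X=5e5)) < 0

    @pytest.mark.parametrize("bad", [
        (sample(1.0), sample(0.5)),                    # reversed times
        (sample(0.0, X=1e6), sample(0.0, X=2e6)),      # zero interval
    ])
    def test_ordering_errors(self, bad):
        with pytest.raises(KineticsError):
            specific_growth_rate(*bad)

    @settings(max_examples=200, derandomize=True)
    @given(x0=positive, x1=positive,
           dt=st.floats(min_value=1e-3, max_value=10, allow_nan=False))
    def test_log_mean_form_equals_log_ratio_form(self, x0, x1, dt):
        """The defining form (ΔX/Δt)/X̄ is algebraically ln(X1/X0)/Δt."""
        mu = specific_growth_rate(sample(0.0, X=x0), sample(dt, X=x1))
        assert mu == pytest.approx(math.log(x1 / x0) / dt, rel=1e-12, abs=1e-12)


class TestConversionRates:
    def test_batch_glucose_example(self):
        q = q_glc_batch(sample(0.0, glc=17.0), sample(1.0, glc=10.0), 1e6)
        assert q == pytest.approx(7.0, rel=1e-12)

    def test_unchanged_concentrations_give_zero(self):
        assert q_glc_batch(sample(0.0), sample(1.0), 1e6) == 0.0
        assert q_lac_batch(sample(0.0), sample(1.0), 1e6) == 0.0

    def test_batch_lactate_example(self):
        q = q_lac_batch(sample(0.0, lac=0.0), sample(1.0, lac=20.0), 1e6)
        assert q == pytest.approx(20.0, rel=1e-12)

    def test_perfusion_glucose_steady_state(self):
        # constant 15 mM residual, 20 mM feed, D = 1/d: uptake balances supply
        q = q_glc_perfusion(sample(0.0, glc=15.0), sample(1.0, glc=15.0),
                            1e6, F=1.0, V=1.0, glc_feed=20.0)
        assert q == pytest.approx(5.0, rel=1e-12)

    def test_perfusion_lactate_steady_state(self):
        q = q_lac_perfusion(sample(0.0, lac=20.0), sample(1.0, lac=20.0),
                            1e6, F=1.0, V=1.0)
        assert q == pytest.approx(20.0, rel=1e-12)

    def test_nonpositive_xbar_is_domain_error(self):
        with pytest.raises(KineticsError):
            q_glc_batch(sample(0.0), sample(1.0), 0.0)

    @settings(max_examples=100, derandomize=True)
    @given(g0=positive, g1=positive, l0=positive, l1=positive, xbar=positive,
           feed=st.floats(min_value=0, max_value=100, allow_nan=False))
    def test_zero_flow_reduces_perfusion_to_batch(self, g0, g1, l0, l1, xbar, feed):
        s0 = ProcessSample(t=0.0, X=1e6, glc=g0, lac=l0)
        s1 = ProcessSample(t=1.0, X=1e6, glc=g1, lac=l1)
        assert q_glc_perfusion(s0, s1, xbar, 0.0, 1.0, feed) == \
            pytest.approx(q_glc_batch(s0, s1, xbar), rel=1e-12, abs=1e-15)
        assert q_lac_perfusion(s0, s1, xbar, 0.0, 1.0) == \
            pytest.approx(q_lac_batch(s0, s1, xbar), rel=1e-12, abs=1e-15)


class TestYieldCoefficient:
    @pytest.mark.parametrize("ql,qg,expected", [
        (21.0, 15.0, 1.4),
        (20.0, 5.0, 4.0),
        (-20.0, 10.0, 2.0),   # absolute value
    ])
    def test_values(self, ql, qg, expected):
        assert yield_coefficient(ql, qg) == pytest.approx(expected, rel=1e-12)

    def test_zero_consumption_is_undefined(self):
        with pytest.raises(KineticsError):
            yield_coefficient(10.0, 0.0)


def _daily_passage(schedule, n_days=4):
    samples = tuple(
        ProcessSample(t=float(d), X=5e5 * math.exp(0.5 * d),
                      glc=max(16.0 - d, 1.0), lac=5.0 + 4.0 * d)
        for d in range(n_days + 1))
    return PassageRecord(label="p1", volume=0.15, inoc_density=5e5,
                         duration=float(n_days), samples=samples,
                         schedule=schedule)


class TestPassageKinetics:
    def test_regime_assignment_with_perfusion_from_d1(self):
        sched = PerfusionSchedule((
            PerfusionSegment(1.0, 4.0, 0.5, "vvd", 20.0),))
        ks = passage_kinetics(_daily_passage(sched))
        assert [k.regime for k in ks] == ["batch"] + ["perfusion"] * 3

    def test_yield_is_ratio_of_reported_rates(self):
        sched = PerfusionSchedule((PerfusionSegment(1.0, 4.0, 0.5, "vvd", 20.0),))
        for k in passage_kinetics(_daily_passage(sched)):
            assert k.Y == pytest.approx(abs(k.q_lac / k.q_glc), rel=1e-12)

    def test_feed_change_inside_interval_is_rejected(self):
        sched = PerfusionSchedule((
            PerfusionSegment(1.0, 1.5, 0.5, "vvd", 20.0),
            PerfusionSegment(1.5, 4.0, 0.5, "vvd", 40.0),))
        with pytest.raises(KineticsError, match="align"):
            passage_kinetics(_daily_passage(sched))

    def test_time_weighted_mean_rate_over_partial_coverage(self):
        # active only in the second half of [1, 2]: mean F = rate/2
        sched = PerfusionSchedule((PerfusionSegment(1.5, 2.0, 1.0, "L_per_day", 20.0),))
        assert sched.mean_rate_L_per_day(1.0, 2.0, 0.15) == pytest.approx(0.5)

    def test_needs_two_samples(self):
        p = PassageRecord(label="solo", volume=0.15, inoc_density=5e5,
                          duration=1.0, samples=(sample(0.0),))
        with pytest.raises(KineticsError, match="solo"):
            passage_kinetics(p)


class TestBatchExactnessOracle:
    """Independent ODE oracle: under X = X0·e^{µt} and constant q, the
    two-point batch estimators are exact (the log-mean IS the time
    average), so they must recover the truth to integration precision."""

    def test_recovers_constant_rates_on_integrated_trajectory(self):
        from scipy.integrate import solve_ivp

        mu_true, qg_true, ql_true = 1.0, 14.0, 19.0
        x0, g0 = 5e5, 400.0

        def rhs(t, y):
            X, G, L = y
            return [mu_true * X, -qg_true * X * 1e-6, ql_true * X * 1e-6]

        sol = solve_ivp(rhs, (0.0, 4.0), [x0, g0, 0.0], rtol=1e-12,
                        atol=1e-9, dense_output=True, max_step=1e-3)
        days = [0.0, 1.0, 2.0, 3.0, 4.0]
        samples = [ProcessSample(t=t, X=float(sol.sol(t)[0]),
                                 glc=float(sol.sol(t)[1]),
                                 lac=float(sol.sol(t)[2])) for t in days]
        for s0, s1 in zip(samples, samples[1:]):
            xbar = log_mean(s1.X, s0.X)
            assert specific_growth_rate(s0, s1) == pytest.approx(mu_true, rel=1e-9)
            assert q_glc_batch(s0, s1, xbar) == pytest.approx(qg_true, rel=1e-6)
            assert q_lac_batch(s0, s1, xbar) == pytest.approx(ql_true, rel=1e-6)
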