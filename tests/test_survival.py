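"""Survival curves, per-cycle probabilities, KM estimation and MLE fitting."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ventcea import (FitError, SurvivalParams, SurvivalRecord,
                     cycle_death_probability, fit_parametric, km_estimate,
                     select_family, survival_at)
from ventcea.survival import log_likelihood
from ventcea.synthdata import SyntheticCohortSpec, simulate_survival


class TestSurvivalFunction:
    @pytest.mark.parametrize("params, t, expected", [
        (SurvivalParams.weibull(1.0, 10.0), 10.0, math.exp(-1)),
        (SurvivalParams.lognormal(math.log(33.8), 0.8), 33.8, 0.5),
        (SurvivalParams.weibull_from_median(25.8, 1.5), 25.8, 0.5),
        (SurvivalParams.weibull(1.5, 30.0), 0.0, 1.0),
        (SurvivalParams.lognormal(3.0, 0.5), 0.0, 1.0),
    ])
    def test_known_values(self, params, t, expected):
        assert survival_at(params, t) == pytest.approx(expected, abs=1e-12)

    def test_median_inversion_formula(self):
        params = SurvivalParams.weibull_from_median(25.8, 1.5)
        assert params.scale == pytest.approx(25.8 / math.log(2) ** (1 / 1.5))
        assert params.median == pytest.approx(25.8)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            survival_at(SurvivalParams.weibull(1.5, 30.0), -1.0)

    @given(shape=st.floats(0.3, 5.0), scale=st.floats(1.0, 100.0))
    def test_weibull_monotone_to_zero(self, shape, scale):
        params = SurvivalParams.weibull(shape, scale)
        t = np.linspace(0, 600, 200)
        s = survival_at(params, t)
        assert s[0] == 1.0
        assert np.all(np.diff(s) <= 1e-15)
        assert survival_at(params, 1e6) < 1e-6

    @given(mu=st.floats(1.0, 5.0), sigma=st.floats(0.1, 2.0))
    def test_lognormal_monotone_to_zero(self, mu, sigma):
        params = SurvivalParams.lognormal(mu, sigma)
        t = np.linspace(0, 600, 200)
        s = survival_at(params, t)
        assert s[0] == 1.0
        assert np.all(np.diff(s) <= 1e-15)

    def test_positivity_enforced(self):
        with pytest.raises(ValueError):
            SurvivalParams.weibull(-1.0, 10.0)
        with pytest.raises(ValueError):
            SurvivalParams.lognormal(3.0, 0.0)


class TestCycleDeathProbability:
    def test_exponential_is_memoryless(self):
        params = SurvivalParams.weibull(1.0, 20.0)
        expected = 1 - math.exp(-1 / 20.0)
        for t in (0, 5, 50, 300):
            assert cycle_death_probability(params, t) == pytest.approx(
                expected, rel=1e-12)

    def test_direct_evaluation(self):
        params = SurvivalParams.weibull(2.0, 50.0)
        assert cycle_death_probability(params, 0) == pytest.approx(
            1 - math.exp(-(1 / 50.0) ** 2), rel=1e-12)

    def test_flat_survival_gives_zero(self):
        assert cycle_death_probability(SurvivalParams.none(), 7) == 0.0

    def test_exhausted_survival_gives_one(self):
        params = SurvivalParams.weibull(4.0, 5.0)
        assert cycle_death_probability(params, 4000.0) == 1.0

    @pytest.mark.parametrize("params", [
        SurvivalParams.weibull_from_median(25.8, 1.5),
        SurvivalParams.lognormal_from_median(33.8, 0.8),
    ])
    def test_composition_reconstructs_survival(self, params):
        # prod_{t<T} (1 - p(t)) telescopes back to S(T)
        for horizon in (1, 12, 120):
            prod = 1.0
            for t in range(horizon):
                prod *= 1.0 - cycle_death_probability(params, t)
            assert prod == pytest.approx(survival_at(params, horizon),
                                         abs=1e-10)


class TestKaplanMeier:
    def test_uncensored_steps(self):
        records = [SurvivalRecord(t, 1) for t in (1.0, 2.0, 3.0)]
        km = km_estimate(records)
        assert km(0.5) == pytest.approx(1.0)
        assert km(1.0) == pytest.approx(2 / 3)
        assert km(2.0) == pytest.approx(1 / 3)
        assert km(3.0) == pytest.approx(0.0)

    def test_all_censored_flat_one(self):
        records = [SurvivalRecord(t, 0) for t in (1.0, 5.0, 9.0)]
        km = km_estimate(records)
        assert np.all(km(np.array([0.0, 4.0, 10.0])) == 1.0)

    def test_censoring_product_limit_by_hand(self):
        # deaths at 1 and 3, censoring at 2: S(1)=2/3, S(3)=(2/3)*(1-1/1)=0
        records = [SurvivalRecord(1.0, 1), SurvivalRecord(2.0, 0),
                   SurvivalRecord(3.0, 1)]
        km = km_estimate(records)
        assert km(1.0) == pytest.approx(2 / 3)
        assert km(3.0) == pytest.approx(0.0)

    def test_matches_empirical_survival_without_censoring(self):
        rng = np.random.default_rng(11)
        times = rng.weibull(1.3, 200) * 20
        records = [SurvivalRecord(float(t), 1) for t in times]
        km = km_estimate(records)
        for q in (5.0, 15.0, 30.0):
            assert km(q) == pytest.approx(np.mean(times > q), abs=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            km_estimate([])


class TestFitting:
    def test_weibull_parameter_recovery(self):
        true = SurvivalParams.weibull(1.5, 30.0)
        records = simulate_survival(
            SyntheticCohortSpec(n=1000, params=true, seed=42))
        fit = fit_parametric(records, "weibull")
        assert fit.params.shape == pytest.approx(1.5, rel=0.10)
        assert fit.params.scale == pytest.approx(30.0, rel=0.05)

    def test_lognormal_recovery_under_censoring(self):
        true = SurvivalParams.lognormal(3.2, 0.8)
        records = simulate_survival(
            SyntheticCohortSpec(n=1000, params=true, censor_rate=0.2, seed=7))
        fit = fit_parametric(records, "lognormal")
        assert fit.params.mu == pytest.approx(3.2, abs=0.1)

    def test_fitted_loglik_beats_truth(self):
        true = SurvivalParams.weibull(1.5, 30.0)
        records = simulate_survival(
            SyntheticCohortSpec(n=500, params=true, seed=5))
        fit = fit_parametric(records, "weibull")
        assert fit.log_likelihood >= log_likelihood(true, records) - 1e-6

    def test_degenerate_identical_times_fail_loudly(self):
        records = [SurvivalRecord(10.0, 1)] * 20
        with pytest.raises((FitError, ValueError)):
            fit_parametric(records, "weibull")

    def test_too_few_events_rejected(self):
        records = [SurvivalRecord(5.0, 1)] + [SurvivalRecord(9.0, 0)] * 10
        with pytest.raises(ValueError):
            fit_parametric(records, "weibull")


class TestFamilySelection:
    @pytest.mark.parametrize("true, expected", [
        (SurvivalParams.weibull(2.0, 30.0), "weibull"),
        (SurvivalParams.lognormal(3.4, 0.5), "lognormal"),
    ])
    def test_selects_generating_family(self, true, expected):
        records = simulate_survival(
            SyntheticCohortSpec(n=2000, params=true, seed=17))
        assert select_family(records).family == expected

    def test_minimal_sample_flagged_low_confidence(self):
        records = [SurvivalRecord(5.0, 1), SurvivalRecord(9.0, 1)]
        sel = select_family(records)
        assert sel.low_confidence
        assert sel.family in ("weibull", "lognormal")

    def test_requires_two_candidates(self):
        records = [SurvivalRecord(5.0, 1), SurvivalRecord(9.0, 1)]
        with pytest.raises(ValueError):
            select_family(records, candidates=["weibull"])
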