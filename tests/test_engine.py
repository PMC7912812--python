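"""Cohort engine: transition rows, propagation, accrual and conservation."""

import dataclasses
import math

import numpy as np
import pytest

from ventcea import (Arm, ConfigError, ModelSpec, NumericDomainError, State,
                     SurvivalParams, TransitionSplits, UtilityCurve,
                     baseline_cost_schedule, build_transition_row,
                     cumulative_outputs, run_cohort)


def flat_one_curve():
    # exactly 1.0 over the ages a 10-year horizon can reach
    return UtilityCurve((42.8, 119.0, 120.0), (1.0, 1.0, 0.0))


def zero_curve():
    return UtilityCurve((42.8, 120.0), (0.0, 0.0))


def single_state_spec(arm=Arm.HMV, horizon=120, p_death=0.0, rate=0.0):
    """NIV-only cohort: no exits, optional constant exponential hazard."""
    if p_death > 0:
        niv = SurvivalParams.weibull(1.0, -1.0 / math.log(1.0 - p_death))
    else:
        niv = SurvivalParams.none()
    return ModelSpec(
        arm=arm, niv_survival=niv, iv_survival=SurvivalParams.none(),
        initial_distribution={State.NIV: 1.0}, horizon_cycles=horizon,
        discount_rate_annual=rate,
        splits=dataclasses.replace(TransitionSplits(),
                                   niv_continue=1.0, niv_exit=0.0))


def costs_with(**over):
    zero = dict(niv_home_monthly=0.0, iv_home_monthly=0.0,
                hosp_nip_monthly=0.0, hosp_nvp_monthly=0.0,
                mv_facility_monthly=0.0, transfer_cost=0.0)
    zero.update(over)
    return baseline_cost_schedule().perturb(**zero)


class TestTransitionRow:
    def test_hospitalization_unconditional_split(self, baseline):
        row = build_transition_row(
            baseline.spec_hmv, State.HOSPITALIZATION, 5, 40).as_dict()
        assert row == {State.HOSPITALIZATION: pytest.approx(0.01),
                       State.IV: pytest.approx(0.95),
                       State.DEATH: pytest.approx(0.04)}

    def test_hazard_off_limit_facility_niv(self, baseline):
        spec = dataclasses.replace(baseline.spec_mv,
                                   niv_survival=SurvivalParams.none())
        row = build_transition_row(spec, State.NIV, 0, 0).as_dict()
        assert row[State.NIV] == pytest.approx(0.99812)
        assert row[State.IV] == pytest.approx(0.00188)
        assert row.get(State.DEATH, 0.0) == 0.0

    def test_residual_mass_split_with_forced_hazard(self, baseline):
        row = build_transition_row(baseline.spec_hmv, State.IV, 3, 10,
                                   death_probability=0.2).as_dict()
        assert row[State.IV] == pytest.approx(0.8 * 0.999)
        assert row[State.HOSPITALIZATION] == pytest.approx(0.8 * 0.001)
        assert row[State.DEATH] == pytest.approx(0.2)

    def test_row_sums_to_one(self, baseline):
        for state in (State.NIV, State.IV, State.HOSPITALIZATION):
            row = build_transition_row(baseline.spec_hmv, state, 4, 9)
            assert sum(p for _s, p in row.targets) == pytest.approx(1.0,
                                                                    abs=1e-12)

    def test_absorbing_and_foreign_states_rejected(self, baseline):
        with pytest.raises(ConfigError):
            build_transition_row(baseline.spec_hmv, State.DEATH, 0, 0)
        with pytest.raises(ConfigError):
            build_transition_row(baseline.spec_mv, State.HOSPITALIZATION, 0, 0)

    def test_pathological_hazard_rejected(self, baseline):
        with pytest.raises(NumericDomainError):
            build_transition_row(baseline.spec_hmv, State.NIV, 0, 0,
                                 death_probability=1.2)


class TestPropagation:
    def test_geometric_decay(self):
        spec = single_state_spec(horizon=40, p_death=0.1)
        trace = run_cohort(spec, costs_with(), zero_curve())
        for k in (0, 1, 5, 20, 40):
            assert trace.occupancy.loc[k, "NIV"] == pytest.approx(
                0.9 ** k, rel=1e-12)

    def test_mass_conservation_both_arms(self, baseline_traces):
        for trace in baseline_traces:
            sums = trace.occupancy.sum(axis=1).to_numpy()
            assert len(sums) == 121
            assert np.max(np.abs(sums - 1.0)) < 1e-10
            assert trace.occupancy.to_numpy().min() >= 0.0
            assert trace.occupancy.to_numpy().max() <= 1.0

    def test_death_monotone_and_accruals_nondecreasing(self, baseline_traces):
        for trace in baseline_traces:
            death = trace.occupancy["Death"].to_numpy()
            assert np.all(np.diff(death) >= -1e-15)
            assert np.all(trace.cycle_cost >= 0)
            assert np.all(trace.cycle_qaly >= 0)

    def test_hazard_off_death_free(self, baseline):
        # no parametric hazards and the hospital death mass redirected to IV
        splits = dataclasses.replace(
            TransitionSplits(), hosp_death=0.0, hosp_to_iv=0.99)
        spec = dataclasses.replace(
            baseline.spec_hmv, splits=splits,
            niv_survival=SurvivalParams.none(),
            iv_survival=SurvivalParams.none())
        trace = run_cohort(spec, baseline.costs, baseline.utilities)
        assert np.all(trace.occupancy["Death"].to_numpy() == 0.0)

    def test_hospitalization_only_in_home_arm(self, baseline_traces):
        hmv, mv = baseline_traces
        assert "Hospitalization" in hmv.occupancy.columns
        assert "Hospitalization" not in mv.occupancy.columns
        assert len(hmv.occupancy.columns) == 4
        assert len(mv.occupancy.columns) == 3


class TestAccrual:
    def test_zero_profiles_accrue_nothing(self):
        spec = single_state_spec(horizon=24, p_death=0.05)
        trace = run_cohort(spec, costs_with(), zero_curve())
        assert cumulative_outputs(trace) == (0.0, 0.0)

    def test_undiscounted_cost_toy(self):
        spec = single_state_spec(horizon=12)
        trace = run_cohort(spec, costs_with(niv_home_monthly=100.0),
                           flat_one_curve())
        assert trace.cumulative_cost == pytest.approx(1200.0)

    def test_ten_qaly_over_full_horizon(self):
        # utility 1.0 held for 120 undiscounted months is exactly 10 QALYs
        spec = single_state_spec(horizon=120)
        trace = run_cohort(spec, costs_with(), flat_one_curve())
        assert trace.cumulative_qaly == pytest.approx(10.0, abs=1e-12)

    def test_discount_neutrality_and_monotonicity(self):
        undisc = run_cohort(single_state_spec(horizon=60),
                            costs_with(niv_home_monthly=100.0),
                            flat_one_curve())
        assert undisc.cumulative_cost == pytest.approx(6000.0)
        prev_cost = math.inf
        for rate in (0.0, 0.03, 0.10):
            trace = run_cohort(single_state_spec(horizon=60, rate=rate),
                               costs_with(niv_home_monthly=100.0),
                               flat_one_curve())
            assert trace.cumulative_cost < prev_cost or rate == 0.0
            prev_cost = trace.cumulative_cost

    def test_transfer_charged_at_destination_cycle(self, baseline):
        # a cohort forced through hospitalization pays transport on arrival
        trace = run_cohort(baseline.spec_hmv, baseline.costs,
                           baseline.utilities)
        assert trace.transfer_fraction[0] == 0.0
        assert trace.transfer_fraction[1:].max() > 0.0

    def test_trace_export_shape(self, baseline_traces):
        hmv, _ = baseline_traces
        frame = hmv.to_frame()
        assert set(frame.columns) == {"cycle", "state", "time_in_state",
                                      "occupancy", "cycle_cost", "cycle_qaly"}
        assert frame["cycle"].max() == 120


class TestValidation:
    def test_bad_initial_distribution(self, baseline):
        with pytest.raises(ConfigError):
            dataclasses.replace(baseline.spec_hmv,
                                initial_distribution={State.NIV: 0.6})
        with pytest.raises(ConfigError):
            dataclasses.replace(
                baseline.spec_mv,
                initial_distribution={State.HOSPITALIZATION: 1.0})

    def test_bad_splits(self, baseline):
        with pytest.raises(ConfigError):
            dataclasses.replace(
                baseline.spec_hmv,
                splits=dataclasses.replace(TransitionSplits(),
                                           hosp_death=0.05))
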