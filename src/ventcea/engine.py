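"""Deterministic Markov cohort engine with time-in-state tracking.

Two arms are modelled over monthly cycles: home ventilation (four states --
non-invasive NIV, invasive IV, Hospitalization, Death) and facility
ventilation (three states -- NIV, IV, Death).  Death probabilities come from
parametric survival curves evaluated on a configurable clock: by default the
NIV (Weibull) clock runs from model entry and the IV (log-normal) clock from
invasive-ventilation initiation, paused while the patient is hospitalized,
because the source survival curves measure time from each modality's start.
The residual survival mass in each cycle is split by fixed conditional
transition probabilities.

Accrual is full-cycle in the state occupied at cycle start (no half-cycle
correction), discounted at (1+r)^(-t/12) for cycle t; transfer (transport)
costs are charged per transition into hospital and back, at the destination
cycle's discount factor; a month of utility u contributes u/12 QALY.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Mapping

import numpy as np
import pandas as pd

from .costs import CostSchedule
from .survival import SurvivalParams, cycle_death_probability
from .utilities import UtilityCurve, state_utility, utility_at

MONTHS_PER_YEAR = 12
_MASS_TOL = 1e-10


class ConfigError(ValueError):
    """Invalid model configuration."""


class NumericDomainError(ValueError):
    """A hazard or probability left [0, 1]."""


class Arm(str, Enum):
    HMV = "HMV"  # home mechanical ventilation
    MV = "MV"    # mechanical ventilation in a healthcare facility


class State(str, Enum):
    NIV = "NIV"
    IV = "IV"
    HOSPITALIZATION = "Hospitalization"
    DEATH = "Death"


ARM_STATES = {
    Arm.HMV: (State.NIV, State.IV, State.HOSPITALIZATION, State.DEATH),
    Arm.MV: (State.NIV, State.IV, State.DEATH),
}


@dataclass(frozen=True)
class TransitionSplits:
    """Fixed conditional splits of the residual (surviving) mass."""

    niv_continue: float = 0.99812
    niv_exit: float = 0.00188      # to Hospitalization (home) / IV (facility)
    iv_continue: float = 0.999     # home arm only; facility IV has no exit
    iv_to_hosp: float = 0.001
    hosp_stay: float = 0.01        # hospitalization has no parametric hazard
    hosp_to_iv: float = 0.95
    hosp_death: float = 0.04

    def validate(self) -> list[str]:
        findings = []
        for name, p in self.__dict__.items():
            if not (0.0 <= p <= 1.0):
                findings.append(f"splits.{name}: {p} outside [0, 1]")
        if abs(self.niv_continue + self.niv_exit - 1.0) > 1e-12:
            findings.append(
                f"splits.niv: sum {self.niv_continue + self.niv_exit!r} != 1")
        if abs(self.iv_continue + self.iv_to_hosp - 1.0) > 1e-12:
            findings.append(
                f"splits.iv: sum {self.iv_continue + self.iv_to_hosp!r} != 1")
        hosp = self.hosp_stay + self.hosp_to_iv + self.hosp_death
        if abs(hosp - 1.0) > 1e-12:
            findings.append(f"splits.hospitalization: sum {hosp!r} != 1")
        return findings


@dataclass(frozen=True)
class ModelSpec:
    """Full configuration of one arm's state-transition model."""

    arm: Arm
    niv_survival: SurvivalParams
    iv_survival: SurvivalParams
    initial_distribution: Mapping[State, float]
    horizon_cycles: int = 120
    cycle_length_months: int = 1
    discount_rate_annual: float = 0.03
    splits: TransitionSplits = field(default_factory=TransitionSplits)
    clock_mode: str = "state_entry"  # or "model_time"
    iv_clock_resumes_after_hospital: bool = True

    def __post_init__(self):
        object.__setattr__(self, "arm", Arm(self.arm))
        dist = {State(k): float(v) for k, v in self.initial_distribution.items()}
        object.__setattr__(self, "initial_distribution", dist)
        findings = self.validate()
        if findings:
            raise ConfigError("; ".join(findings))

    @property
    def states(self) -> tuple:
        return ARM_STATES[self.arm]

    def validate(self) -> list[str]:
        findings = []
        if self.horizon_cycles < 1:
            findings.append(f"horizon_cycles: {self.horizon_cycles} < 1")
        if self.cycle_length_months != 1:
            findings.append("cycle_length_months: only monthly cycles supported")
        if self.discount_rate_annual < 0:
            findings.append(
                f"discount_rate_annual: {self.discount_rate_annual} < 0")
        if self.clock_mode not in ("state_entry", "model_time"):
            findings.append(f"clock_mode: unknown mode {self.clock_mode!r}")
        allowed = set(ARM_STATES[Arm(self.arm)]) - {State.DEATH}
        dist = self.initial_distribution
        for state, p in dist.items():
            if state not in allowed:
                findings.append(
                    f"initial_distribution.{state.value}: not a live state "
                    f"of the {Arm(self.arm).value} arm")
            if p < 0:
                findings.append(
                    f"initial_distribution.{state.value}: {p} negative")
        total = sum(dist.values())
        if abs(total - 1.0) > 1e-12:
            findings.append(f"initial_distribution: sum {total!r} != 1")
        findings.extend(self.splits.validate())
        return findings


@dataclass(frozen=True)
class TransitionRow:
    """Outgoing probabilities of one (state, clocks) source."""

    source: State
    t_state: int
    t_model: int
    targets: tuple  # ((State, probability), ...)

    def probability(self, state: State) -> float:
        return sum(p for s, p in self.targets if s is state)

    def as_dict(self) -> dict:
        out: dict[State, float] = defaultdict(float)
        for s, p in self.targets:
            out[s] += p
        return dict(out)


def _death_probability(spec: ModelSpec, params: SurvivalParams,
                       t_state: int, t_model: int) -> float:
    clock = t_state if spec.clock_mode == "state_entry" else t_model
    return cycle_death_probability(params, clock)


def build_transition_row(spec: ModelSpec, state: State, t_state: int,
                         t_model: int,
                         death_probability: float | None = None) -> TransitionRow:
    """Transition probabilities out of `state` at the given clocks.

    The parametric death probability is taken first; the residual mass is
    split by the fixed conditional probabilities.  Hospitalization uses its
    unconditional three-way split with no parametric hazard.
    `death_probability` overrides the hazard (used by tests and sensitivity
    perturbations).
    """
    state = State(state)
    if t_state < 0 or t_model < 0:
        raise ValueError("clocks must be >= 0")
    if state not in spec.states or state is State.DEATH:
        raise ConfigError(
            f"no transition row for state {state.value!r} in arm "
            f"{spec.arm.value}")
    sp = spec.splits
    if state is State.HOSPITALIZATION:
        targets = ((State.HOSPITALIZATION, sp.hosp_stay),
                   (State.IV, sp.hosp_to_iv),
                   (State.DEATH, sp.hosp_death))
        return TransitionRow(state, t_state, t_model, targets)
    params = spec.niv_survival if state is State.NIV else spec.iv_survival
    p_death = (death_probability if death_probability is not None
               else _death_probability(spec, params, t_state, t_model))
    if not (0.0 <= p_death <= 1.0) or not np.isfinite(p_death):
        raise NumericDomainError(
            f"death probability {p_death!r} outside [0, 1] for "
            f"{state.value} at t_state={t_state}")
    live = 1.0 - p_death
    if state is State.NIV:
        exit_state = (State.HOSPITALIZATION if spec.arm is Arm.HMV
                      else State.IV)
        targets = ((State.NIV, live * sp.niv_continue),
                   (exit_state, live * sp.niv_exit),
                   (State.DEATH, p_death))
    else:  # IV
        if spec.arm is Arm.HMV:
            targets = ((State.IV, live * sp.iv_continue),
                       (State.HOSPITALIZATION, live * sp.iv_to_hosp),
                       (State.DEATH, p_death))
        else:
            targets = ((State.IV, live), (State.DEATH, p_death))
    return TransitionRow(state, t_state, t_model, targets)


@dataclass
class CohortTrace:
    """Per-cycle state occupancy and discounted accruals of one arm."""

    arm: Arm
    occupancy: pd.DataFrame        # index cycle 0..H, one column per state
    cycle_cost: np.ndarray         # discounted CZK accrued per cycle (len H+1)
    cycle_qaly: np.ndarray         # discounted QALY accrued per cycle
    transfer_fraction: np.ndarray  # cohort fraction charged a transfer
    detail: pd.DataFrame           # cycle, state, time_in_state, occupancy
    discount_rate_annual: float
    start_age: float

    @property
    def cumulative_cost(self) -> float:
        return float(self.cycle_cost.sum())

    @property
    def cumulative_qaly(self) -> float:
        return float(self.cycle_qaly.sum())

    def to_frame(self) -> pd.DataFrame:
        """Long export: cycle, state, time_in_state, occupancy plus the
        cycle-level discounted accruals repeated per cycle."""
        df = self.detail.copy()
        df["cycle_cost"] = self.cycle_cost[df["cycle"].to_numpy()]
        df["cycle_qaly"] = self.cycle_qaly[df["cycle"].to_numpy()]
        return df


def _discount_factors(rate: float, horizon: int) -> np.ndarray:
    return (1.0 + rate) ** (-(np.arange(horizon + 1)) / MONTHS_PER_YEAR)


def run_cohort(spec: ModelSpec, costs: CostSchedule,
               utilities: UtilityCurve) -> CohortTrace:
    """Propagate the cohort over the horizon, accruing cost and QALYs.

    Time-in-state bookkeeping: NIV's clock coincides with model time (the
    state is only entered at cycle 0); IV mass is bucketed by months of
    invasive ventilation; hospitalization mass is bucketed by (paused IV
    clock, months in current episode, prior-episode flag), the last driving
    the intensive-care/ventilation-care billing switch.
    """
    H = spec.horizon_cycles
    arm = spec.arm
    disc = _discount_factors(spec.discount_rate_annual, H)
    sp = spec.splits

    niv = spec.initial_distribution.get(State.NIV, 0.0)
    # IV mass bucketed by (months on invasive ventilation, prior-episode
    # flag); hospitalization mass by (paused IV clock, months in current
    # episode, prior-episode flag).
    iv = np.zeros((H + 1, 2))
    iv[0, 0] = spec.initial_distribution.get(State.IV, 0.0)
    hosp = np.zeros((H + 1, H + 1, 2))
    hosp[0, 0, 0] = spec.initial_distribution.get(State.HOSPITALIZATION, 0.0)
    dead = 0.0

    # per-clock death probabilities (state_entry indexes by clock c; under
    # model_time every bucket uses the model-time entry t instead)
    p_iv = np.array([cycle_death_probability(spec.iv_survival, c)
                     for c in range(H + 1)])
    model_time = spec.clock_mode == "model_time"

    # hospitalization monthly cost by (episode month, prior-episode flag)
    hosp_cost = np.array(
        [[costs.hospitalization_monthly(mth, pr) for pr in (False, True)]
         for mth in range(H + 1)])

    states = spec.states
    occ_rows = np.zeros((H + 1, len(states)))
    cycle_cost = np.zeros(H + 1)
    cycle_qaly = np.zeros(H + 1)
    transfer_frac = np.zeros(H + 1)
    detail_rows: list[tuple[int, str, int, float]] = []

    def record(t: int) -> None:
        vals = {State.NIV: niv, State.IV: float(iv.sum()),
                State.HOSPITALIZATION: float(hosp.sum()), State.DEATH: dead}
        occ_rows[t] = [vals.get(s, 0.0) for s in states]
        if niv > 0 or t == 0:
            detail_rows.append((t, State.NIV.value, t, niv))
        iv_by_clock = iv.sum(axis=1)
        for c in np.nonzero(iv_by_clock)[0]:
            detail_rows.append((t, State.IV.value, int(c), iv_by_clock[c]))
        hosp_by_month = hosp.sum(axis=(0, 2))
        for mth in np.nonzero(hosp_by_month)[0]:
            detail_rows.append(
                (t, State.HOSPITALIZATION.value, int(mth), hosp_by_month[mth]))
        detail_rows.append((t, State.DEATH.value, 0, dead))

    for t in range(H):
        record(t)

        # --- accrual in the states occupied at cycle start -------------
        age = utilities.start_age + t / MONTHS_PER_YEAR
        u_home = state_utility(utilities, State.NIV, arm, age)
        u_fac = utilities.facility_multiplier * utility_at(utilities, age)
        iv_total = float(iv.sum())
        hosp_total = float(hosp.sum())
        if arm is Arm.HMV:
            state_cost = (niv * costs.niv_home_monthly
                          + iv_total * costs.iv_home_monthly
                          + float((hosp.sum(axis=0) * hosp_cost).sum()))
            util = (niv + iv_total) * u_home + hosp_total * u_fac
        else:
            state_cost = (niv + iv_total) * costs.mv_facility_monthly
            util = (niv + iv_total) * u_home  # u_home already decremented (MV)
        cycle_cost[t] += disc[t] * state_cost
        cycle_qaly[t] += disc[t] * util / MONTHS_PER_YEAR

        # --- transitions ------------------------------------------------
        new_iv = np.zeros_like(iv)
        new_hosp = np.zeros_like(hosp)
        new_niv = 0.0
        transfers = 0.0

        if niv > 0:
            row = build_transition_row(spec, State.NIV, t, t).as_dict()
            new_niv = niv * row.get(State.NIV, 0.0)
            dead += niv * row.get(State.DEATH, 0.0)
            if arm is Arm.HMV:
                entering = niv * row.get(State.HOSPITALIZATION, 0.0)
                new_hosp[0, 0, 0] += entering
                transfers += entering
            else:
                new_iv[0, 0] += niv * row.get(State.IV, 0.0)

        pd_iv = p_iv[t] if model_time else p_iv[:H]
        live = iv[:H] * (1.0 - (pd_iv if model_time else pd_iv[:, None]))
        dead += float(iv[:H].sum() - live.sum())
        if arm is Arm.HMV:
            new_iv[1:] += live * sp.iv_continue
            entering = live * sp.iv_to_hosp  # admission month counts as IV time
            new_hosp[1:, 0, :] += entering
            transfers += float(entering.sum())
        else:
            new_iv[1:] += live

        if hosp_total > 0:
            new_hosp[:, 1:, :] += hosp[:, :H, :] * sp.hosp_stay
            back = hosp.sum(axis=1) * sp.hosp_to_iv  # by paused clock
            if spec.iv_clock_resumes_after_hospital:
                new_iv[:, 1] += back.sum(axis=1)
            else:
                new_iv[0, 1] += float(back.sum())
            transfers += float(back.sum())
            dead += hosp_total * sp.hosp_death

        if transfers > 0:
            cycle_cost[t + 1] += disc[t + 1] * transfers * costs.transfer_cost
            transfer_frac[t + 1] = transfers

        niv, iv, hosp = new_niv, new_iv, new_hosp

    record(H)

    occupancy = pd.DataFrame(occ_rows, columns=[s.value for s in states])
    occupancy.index.name = "cycle"
    detail = pd.DataFrame(
        detail_rows, columns=["cycle", "state", "time_in_state", "occupancy"])
    row_sums = occupancy.sum(axis=1).to_numpy()
    if np.any(np.abs(row_sums - 1.0) > _MASS_TOL):
        worst = int(np.argmax(np.abs(row_sums - 1.0)))
        raise NumericDomainError(
            f"mass leak: occupancy row {worst} sums to {row_sums[worst]!r}")
    return CohortTrace(
        arm=arm, occupancy=occupancy, cycle_cost=cycle_cost,
        cycle_qaly=cycle_qaly, transfer_fraction=transfer_frac, detail=detail,
        discount_rate_annual=spec.discount_rate_annual,
        start_age=utilities.start_age)


def cumulative_outputs(trace: CohortTrace) -> tuple[float, float]:
    """(total discounted cost CZK, total discounted QALY) of a trace."""
    return trace.cumulative_cost, trace.cumulative_qaly


def with_discount_rate(spec: ModelSpec, rate: float) -> ModelSpec:
    return replace(spec, discount_rate_annual=rate)


def with_initial_distribution(spec: ModelSpec,
                              distribution: Mapping[State, float]) -> ModelSpec:
    return replace(spec, initial_distribution=dict(distribution))
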