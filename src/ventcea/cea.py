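"""Cost-utility comparison of the two ventilation strategies.

The headline statistic is the incremental cost-utility ratio

    ICUR = (Cost_1 - Cost_2) / (QALY_1 - QALY_2) = dCost / dQALY

with the home strategy as intervention (subscript 1) and facility care as
comparator.  A ratio is only meaningful when |dQALY| is not vanishingly
small, and its sign alone cannot distinguish a dominant intervention
(cheaper and more effective) from a dominated one, so results carry an
explicit dominance classification and a near-zero guard.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Callable, Mapping, Sequence

import pandas as pd

from .costs import CostSchedule
from .engine import (Arm, CohortTrace, ModelSpec, State, run_cohort,
                     with_discount_rate, with_initial_distribution)
from .survival import SurvivalParams
from .utilities import UtilityCurve

DOMINANT = "intervention_dominant"
DOMINATED = "comparator_dominant"
TRADEOFF = "tradeoff"
NEAR_ZERO = "near_zero_delta_qaly"

DEFAULT_GUARD_QALY = 1e-6
# SA rows are additionally flagged near-zero at the coarser reporting
# threshold used for the published 0%-decrement row (|dQALY| < 0.01).
SA_NEAR_ZERO_QALY = 0.01


@dataclass(frozen=True)
class CEAResult:
    cost1: float
    qaly1: float
    cost2: float
    qaly2: float
    delta_cost: float
    delta_qaly: float
    cost_per_qaly1: float
    cost_per_qaly2: float
    icur: float | None          # None when the near-zero guard fires
    raw_ratio: float | None     # unguarded ratio, for diagnostics
    dominance: str

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "cost1", "qaly1", "cost2", "qaly2", "delta_cost", "delta_qaly",
            "cost_per_qaly1", "cost_per_qaly2", "icur", "raw_ratio",
            "dominance")}


def cost_per_qaly(cost: float, qaly: float) -> float:
    if qaly <= 0:
        raise ValueError(f"cost per QALY undefined for qaly={qaly}")
    return cost / qaly


def icur(cost1: float, qaly1: float, cost2: float, qaly2: float,
         guard: float = DEFAULT_GUARD_QALY) -> CEAResult:
    """Incremental cost-utility ratio with dominance classification."""
    if guard <= 0:
        raise ValueError("guard must be positive")
    for v in (cost1, qaly1, cost2, qaly2):
        if not math.isfinite(v):
            raise ValueError("ICUR inputs must be finite")
    dc = cost1 - cost2
    dq = qaly1 - qaly2
    raw = dc / dq if dq != 0 else None
    if abs(dq) < guard:
        dominance = NEAR_ZERO
        ratio = None
    elif dc < 0 and dq > 0:
        dominance, ratio = DOMINANT, raw
    elif dc > 0 and dq < 0:
        dominance, ratio = DOMINATED, raw
    else:
        dominance, ratio = TRADEOFF, raw
    return CEAResult(
        cost1=cost1, qaly1=qaly1, cost2=cost2, qaly2=qaly2,
        delta_cost=dc, delta_qaly=dq,
        cost_per_qaly1=cost_per_qaly(cost1, qaly1),
        cost_per_qaly2=cost_per_qaly(cost2, qaly2),
        icur=ratio, raw_ratio=raw, dominance=dominance)


@dataclass(frozen=True)
class ModelBundle:
    """Both arms' specs plus the shared cost and utility configuration."""

    spec_hmv: ModelSpec
    spec_mv: ModelSpec
    costs: CostSchedule
    utilities: UtilityCurve

    def run(self) -> tuple[CohortTrace, CohortTrace]:
        return (run_cohort(self.spec_hmv, self.costs, self.utilities),
                run_cohort(self.spec_mv, self.costs, self.utilities))


def run_cua(bundle: ModelBundle, guard: float = DEFAULT_GUARD_QALY) -> CEAResult:
    """Run both arms and compare (home = intervention, facility = comparator)."""
    hmv, mv = bundle.run()
    return icur(hmv.cumulative_cost, hmv.cumulative_qaly,
                mv.cumulative_cost, mv.cumulative_qaly, guard=guard)


def calibrate_utility_scale(bundle: ModelBundle, target_qaly: float,
                            arm: Arm = Arm.HMV) -> ModelBundle:
    """Rescale the utility anchors so one arm's cumulative QALY hits a target.

    Cumulative QALYs are exactly linear in a common anchor scale (mortality
    is utility-independent), so a single ratio suffices.  Used to reproduce
    published cumulative-utility totals whose underlying anchor values were
    never released.
    """
    if target_qaly <= 0:
        raise ValueError("target QALY must be positive")
    spec = bundle.spec_hmv if Arm(arm) is Arm.HMV else bundle.spec_mv
    current = run_cohort(spec, bundle.costs, bundle.utilities).cumulative_qaly
    if current <= 0:
        raise ValueError("cannot calibrate: current cumulative QALY is 0")
    return replace(bundle,
                   utilities=bundle.utilities.scaled(target_qaly / current))


# ---------------------------------------------------------------------------
# one-way sensitivity analysis
# ---------------------------------------------------------------------------

def _scale_cost(field: str) -> Callable[[ModelBundle, float], ModelBundle]:
    def apply(bundle: ModelBundle, p: float) -> ModelBundle:
        value = getattr(bundle.costs, field) * (1.0 + p)
        return replace(bundle, costs=replace(bundle.costs, **{field: value}))
    return apply


def _scale_split(bundle: ModelBundle, name: str, p: float,
                 renormalize: Mapping[str, float]) -> ModelBundle:
    """Scale one split probability and renormalize its companions."""
    def fix(spec: ModelSpec) -> ModelSpec:
        sp = spec.splits
        new = getattr(sp, name) * (1.0 + p)
        if not (0.0 <= new <= 1.0):
            raise ValueError(f"perturbed {name}={new} leaves [0, 1]")
        others = {k: getattr(sp, k) for k in renormalize}
        total_others = sum(others.values())
        residual = 1.0 - new
        scale = residual / total_others if total_others > 0 else 0.0
        updates = {name: new}
        updates.update({k: v * scale for k, v in others.items()})
        return replace(spec, splits=replace(sp, **updates))
    return replace(bundle, spec_hmv=fix(bundle.spec_hmv),
                   spec_mv=fix(bundle.spec_mv))


def _scale_survival(which: str) -> Callable[[ModelBundle, float], ModelBundle]:
    """Stretch a survival time scale by (1+p): Weibull scale, or exp(mu)."""
    def apply(bundle: ModelBundle, p: float) -> ModelBundle:
        def fix(spec: ModelSpec) -> ModelSpec:
            params: SurvivalParams = getattr(spec, which)
            if params.family == "weibull":
                new = replace(params, scale=params.scale * (1.0 + p))
            elif params.family == "lognormal":
                new = replace(params, mu=params.mu + math.log1p(p))
            else:
                new = params
            return replace(spec, **{which: new})
        return replace(bundle, spec_hmv=fix(bundle.spec_hmv),
                       spec_mv=fix(bundle.spec_mv))
    return apply


def _facility_multiplier(bundle: ModelBundle, p: float) -> ModelBundle:
    # Offset relative to the undecremented home utility: multiplier = 1 + p,
    # so p = -0.1 recovers the baseline 10% facility decrement.
    return replace(bundle,
                   utilities=bundle.utilities.with_multiplier(1.0 + p))


def _discount(bundle: ModelBundle, p: float) -> ModelBundle:
    return replace(
        bundle,
        spec_hmv=with_discount_rate(
            bundle.spec_hmv, bundle.spec_hmv.discount_rate_annual * (1 + p)),
        spec_mv=with_discount_rate(
            bundle.spec_mv, bundle.spec_mv.discount_rate_annual * (1 + p)))


SA_PARAMETERS: dict[str, Callable[[ModelBundle, float], ModelBundle]] = {
    "niv_home_monthly": _scale_cost("niv_home_monthly"),
    "iv_home_monthly": _scale_cost("iv_home_monthly"),
    "hosp_nip_monthly": _scale_cost("hosp_nip_monthly"),
    "hosp_nvp_monthly": _scale_cost("hosp_nvp_monthly"),
    "mv_facility_monthly": _scale_cost("mv_facility_monthly"),
    "transfer_cost": _scale_cost("transfer_cost"),
    "niv_exit_probability":
        lambda b, p: _scale_split(b, "niv_exit", p, {"niv_continue": 1.0}),
    "iv_hospitalization_probability":
        lambda b, p: _scale_split(b, "iv_to_hosp", p, {"iv_continue": 1.0}),
    "hospitalization_death_probability":
        lambda b, p: _scale_split(b, "hosp_death", p,
                                  {"hosp_stay": 1.0, "hosp_to_iv": 1.0}),
    "niv_survival_scale": _scale_survival("niv_survival"),
    "iv_survival_scale": _scale_survival("iv_survival"),
    "facility_utility_multiplier": _facility_multiplier,
    "discount_rate_annual": _discount,
}

DEFAULT_SA_STEPS = (-0.30, -0.20, -0.10, 0.0, 0.10, 0.20, 0.30)


def one_way_sa(bundle: ModelBundle, parameter: str,
               steps: Sequence[float] = DEFAULT_SA_STEPS,
               guard: float = DEFAULT_GUARD_QALY,
               near_zero_qaly: float = SA_NEAR_ZERO_QALY) -> pd.DataFrame:
    """Re-run both arms under each perturbation of one parameter.

    Perturbations are multiplicative (value x (1+p)), except the facility
    utility multiplier, which is stepped as an offset from the undecremented
    home value (multiplier = 1 + p).  Probability perturbations renormalize
    the residual mass of their conditional split.  The p = 0 row reproduces
    the unperturbed run exactly for multiplicative parameters.
    """
    if parameter not in SA_PARAMETERS:
        raise KeyError(
            f"unknown sensitivity parameter {parameter!r}; valid: "
            f"{sorted(SA_PARAMETERS)}")
    apply = SA_PARAMETERS[parameter]
    rows = []
    for p in steps:
        res = run_cua(apply(bundle, p), guard=guard)
        rows.append({
            "parameter": parameter, "perturbation": p,
            "hmv_cost": res.cost1, "hmv_qaly": res.qaly1,
            "mv_cost": res.cost2, "mv_qaly": res.qaly2,
            "delta_cost": res.delta_cost, "delta_qaly": res.delta_qaly,
            "icur": res.icur, "raw_ratio": res.raw_ratio,
            "dominance": res.dominance,
            "near_zero": abs(res.delta_qaly) < near_zero_qaly,
        })
    return pd.DataFrame(rows)


def discount_scenarios(bundle: ModelBundle, rates: Sequence[float],
                       guard: float = DEFAULT_GUARD_QALY
                       ) -> list[tuple[float, CEAResult]]:
    """One CEA per annual discount rate (e.g. 0, 0.03, 0.05)."""
    out = []
    for rate in rates:
        if rate < 0:
            raise ValueError("discount rate must be >= 0")
        scen = replace(bundle,
                       spec_hmv=with_discount_rate(bundle.spec_hmv, rate),
                       spec_mv=with_discount_rate(bundle.spec_mv, rate))
        out.append((rate, run_cua(scen, guard=guard)))
    return out


def scenario_initial_distribution(bundle: ModelBundle,
                                  distribution: Mapping[State, float],
                                  guard: float = DEFAULT_GUARD_QALY
                                  ) -> CEAResult:
    """Re-run both arms with a replacement entry distribution.

    The distribution must be supported on states live in both arms (NIV/IV),
    e.g. the 100%-NIV entry scenario.
    """
    dist = {State(k): float(v) for k, v in distribution.items()}
    scen = replace(
        bundle,
        spec_hmv=with_initial_distribution(bundle.spec_hmv, dist),
        spec_mv=with_initial_distribution(bundle.spec_mv, dist))
    return run_cua(scen, guard=guard)
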