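"""Age-indexed utility trajectory and per-state utility assignment.

Quality of life enters the model as an EQ-5D index curve over patient age:
anchor values (obtained in practice by mapping SF-36 domain scores through a
published crosswalk) are interpolated from the cohort's mean entry age of
42.8 years down to 0 at a terminal age of 120 years.  Home states carry the
full curve value; facility states (hospitalization, and every state of the
facility arm) carry a multiplicative decrement, 0.9 at baseline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.interpolate import PchipInterpolator, interp1d

EQ5D_MIN = -0.594
EQ5D_MAX = 1.0


@dataclass(frozen=True)
class UtilityCurve:
    anchor_ages: tuple
    anchor_utilities: tuple
    facility_multiplier: float = 0.9
    method: str = "pchip"  # monotone piecewise-cubic; or "linear"

    def __post_init__(self):
        ages = np.asarray(self.anchor_ages, dtype=float)
        utils = np.asarray(self.anchor_utilities, dtype=float)
        if ages.size < 2 or ages.size != utils.size:
            raise ValueError("need >= 2 matching (age, utility) anchors")
        if np.any(np.diff(ages) <= 0):
            raise ValueError("anchor ages must be strictly increasing")
        if utils[-1] != 0.0:
            raise ValueError("terminal anchor utility must be 0")
        if not (0.0 < self.facility_multiplier < 2.0):
            raise ValueError("facility multiplier must lie in (0, 2)")
        if self.method not in ("pchip", "linear"):
            raise ValueError("interpolation method must be 'pchip' or 'linear'")
        if self.method == "pchip":
            interp = PchipInterpolator(ages, utils, extrapolate=False)
        else:
            interp = interp1d(ages, utils, bounds_error=True)
        object.__setattr__(self, "_interp", interp)
        object.__setattr__(self, "_ages", ages)
        object.__setattr__(self, "_utils", utils)

    @property
    def start_age(self) -> float:
        return float(self._ages[0])

    @property
    def terminal_age(self) -> float:
        return float(self._ages[-1])

    def with_multiplier(self, multiplier: float) -> "UtilityCurve":
        return replace(self, facility_multiplier=multiplier)

    def scaled(self, factor: float) -> "UtilityCurve":
        """Rescale all anchor utilities (the terminal 0 stays 0).

        Used by the calibration helper; a factor pushing utilities above 1
        leaves the EQ-5D index range and is warned about, not clamped, so
        cumulative outputs stay exactly linear in the factor.
        """
        if factor <= 0:
            raise ValueError("scale factor must be positive")
        scaled = tuple(u * factor for u in self.anchor_utilities)
        if max(scaled) > EQ5D_MAX:
            warnings.warn(
                f"scaled anchor utilities exceed 1 (max {max(scaled):.3f}); "
                "curve leaves the EQ-5D index range", stacklevel=2)
        return replace(self, anchor_utilities=scaled)


def utility_at(curve: UtilityCurve, age) -> np.ndarray | float:
    """Interpolated utility at `age` years; anchors are reproduced exactly."""
    age_arr = np.asarray(age, dtype=float)
    if np.any(age_arr < curve.start_age) or np.any(age_arr > curve.terminal_age):
        raise ValueError(
            f"age outside [{curve.start_age}, {curve.terminal_age}]")
    vals = np.asarray(curve._interp(age_arr), dtype=float)
    # the terminal anchor is exactly 0 by contract; kill interpolation dust
    vals = np.where(age_arr == curve.terminal_age, 0.0, vals)
    return float(vals) if age_arr.ndim == 0 else vals


def state_utility(curve: UtilityCurve, state, arm, age: float) -> float:
    """Utility of occupying `state` in `arm` at patient age `age`.

    Home NIV and home IV carry the full curve value; hospitalization and
    every facility-arm state carry the facility decrement; death is 0.
    """
    from .engine import Arm, State  # local import to avoid a cycle

    state = State(state)
    arm = Arm(arm)
    if state is State.DEATH:
        return 0.0
    base = utility_at(curve, age)
    if arm is Arm.MV or state is State.HOSPITALIZATION:
        return curve.facility_multiplier * base
    return base


def sf36_to_eq5d(domain_scores: Sequence[float],
                 coefficients: Sequence[float],
                 intercept: float = 0.0) -> float:
    """Map the 8 SF-36 domain scores to an EQ-5D index by an affine crosswalk.

    result = intercept + sum(coef_i * score_i), clamped to the EQ-5D index
    range with a warning.  The coefficient set is supplied by configuration.
    """
    scores = np.asarray(domain_scores, dtype=float)
    coefs = np.asarray(coefficients, dtype=float)
    if scores.shape != (8,) or coefs.shape != (8,):
        raise ValueError("expected 8 domain scores and 8 coefficients")
    if np.any(scores < 0) or np.any(scores > 100):
        raise ValueError("SF-36 domain scores must lie in [0, 100]")
    value = float(intercept + scores @ coefs)
    if value > EQ5D_MAX or value < EQ5D_MIN:
        clamped = min(EQ5D_MAX, max(EQ5D_MIN, value))
        warnings.warn(
            f"mapped index {value:.4f} outside [{EQ5D_MIN}, {EQ5D_MAX}]; "
            f"clamped to {clamped}", stacklevel=2)
        return clamped
    return value


def default_anchor_curve(facility_multiplier: float = 0.9,
                         method: str = "pchip") -> UtilityCurve:
    """Shipped placeholder anchor set.

    Quarterly anchors over the first 1.5 years of follow-up (a gently
    declining plateau around 0.4, typical of ventilated ALS cohorts), then a
    monotone decline to 0 at the 120-year terminal age.  These anchors are
    configuration, not published values; the calibration helper rescales
    them for reproduction exercises.
    """
    ages = tuple(42.8 + 0.25 * k for k in range(7)) + (120.0,)
    utils = (0.42, 0.415, 0.41, 0.405, 0.40, 0.395, 0.39, 0.0)
    return UtilityCurve(ages, utils, facility_multiplier=facility_multiplier,
                        method=method)
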