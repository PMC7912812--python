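"""Parametric survival curves, per-cycle death probabilities and fitting.

The two ventilation modalities are calibrated to published median survival
times: non-invasive ventilation follows a Weibull law, invasive ventilation a
log-normal law, selected between by maximised log-likelihood on (right-
censored) time-to-death records.  Time is measured in months everywhere.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter, LogNormalFitter, WeibullFitter
from lifelines.exceptions import ConvergenceError
from scipy.stats import norm

WEIBULL = "weibull"
LOGNORMAL = "lognormal"
NONE = "none"  # degenerate no-event law (S == 1); internal, never fitted

FITTABLE_FAMILIES = (WEIBULL, LOGNORMAL)


class FitError(RuntimeError):
    """Raised when maximum-likelihood fitting fails; carries diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


@dataclass(frozen=True)
class SurvivalParams:
    """Parameters of a time-to-death distribution (months).

    Weibull: S(t) = exp(-(t/scale)^shape).
    Log-normal: S(t) = 1 - Phi((ln t - mu) / sigma); median = exp(mu).
    """

    family: str
    shape: float | None = None   # Weibull k
    scale: float | None = None   # Weibull lambda, months
    mu: float | None = None      # log-normal location (log-months)
    sigma: float | None = None

    def __post_init__(self):
        if self.family == WEIBULL:
            if self.shape is None or self.scale is None:
                raise ValueError("weibull requires shape and scale")
            if self.shape <= 0 or self.scale <= 0:
                raise ValueError("weibull shape and scale must be positive")
        elif self.family == LOGNORMAL:
            if self.mu is None or self.sigma is None:
                raise ValueError("lognormal requires mu and sigma")
            if self.sigma <= 0:
                raise ValueError("lognormal sigma must be positive")
        elif self.family != NONE:
            raise ValueError(f"unknown survival family: {self.family!r}")

    @classmethod
    def weibull(cls, shape: float, scale: float) -> "SurvivalParams":
        return cls(WEIBULL, shape=shape, scale=scale)

    @classmethod
    def lognormal(cls, mu: float, sigma: float) -> "SurvivalParams":
        return cls(LOGNORMAL, mu=mu, sigma=sigma)

    @classmethod
    def none(cls) -> "SurvivalParams":
        return cls(NONE)

    @classmethod
    def weibull_from_median(cls, median: float, shape: float) -> "SurvivalParams":
        """Weibull with the given shape whose median equals ``median`` months."""
        scale = median / math.log(2.0) ** (1.0 / shape)
        return cls.weibull(shape, scale)

    @classmethod
    def lognormal_from_median(cls, median: float, sigma: float) -> "SurvivalParams":
        return cls.lognormal(math.log(median), sigma)

    @property
    def median(self) -> float:
        if self.family == WEIBULL:
            return self.scale * math.log(2.0) ** (1.0 / self.shape)
        if self.family == LOGNORMAL:
            return math.exp(self.mu)
        return math.inf


@dataclass(frozen=True)
class SurvivalRecord:
    """One subject: follow-up time in months and death indicator."""

    time: float
    event: int  # 1 = death observed, 0 = right-censored

    def __post_init__(self):
        if not math.isfinite(self.time) or self.time <= 0:
            raise ValueError(f"time must be finite and positive, got {self.time}")
        if self.event not in (0, 1):
            raise ValueError(f"event flag must be 0 or 1, got {self.event}")


def survival_at(params: SurvivalParams, t) -> np.ndarray | float:
    """S(t) for scalar or array t >= 0 months."""
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("survival_at requires t >= 0")
    if params.family == WEIBULL:
        s = np.exp(-((t_arr / params.scale) ** params.shape))
    elif params.family == LOGNORMAL:
        with np.errstate(divide="ignore"):
            z = (np.log(t_arr, out=np.full_like(t_arr, -np.inf),
                        where=t_arr > 0) - params.mu) / params.sigma
        s = norm.sf(z)
    else:  # NONE
        s = np.ones_like(t_arr)
    return float(s) if np.isscalar(t) or t_arr.ndim == 0 else s


def cycle_death_probability(params: SurvivalParams, t: float) -> float:
    """Conditional probability of death within [t, t+1) given alive at t.

    p(t) = 1 - S(t+1)/S(t); if S(t) has vanished the residual mass dies (1).
    """
    if t < 0:
        raise ValueError("cycle index must be >= 0")
    s0 = survival_at(params, t)
    if s0 <= 0.0:
        return 1.0
    s1 = survival_at(params, t + 1.0)
    return float(min(1.0, max(0.0, 1.0 - s1 / s0)))


@dataclass
class KaplanMeierEstimate:
    """Right-continuous product-limit step function, S(0) = 1."""

    times: np.ndarray
    survival: np.ndarray

    def __call__(self, t) -> np.ndarray | float:
        t_arr = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.times, t_arr, side="right") - 1
        s = np.where(idx < 0, 1.0, self.survival[np.clip(idx, 0, None)])
        return float(s) if t_arr.ndim == 0 else s


def km_estimate(records: Sequence[SurvivalRecord]) -> KaplanMeierEstimate:
    """Kaplan-Meier product-limit estimate of the survival function."""
    if len(records) == 0:
        raise ValueError("km_estimate requires at least one record")
    times = np.array([r.time for r in records])
    events = np.array([r.event for r in records])
    kmf = KaplanMeierFitter().fit(times, events)
    sf = kmf.survival_function_
    return KaplanMeierEstimate(
        times=sf.index.to_numpy(dtype=float),
        survival=sf.iloc[:, 0].to_numpy(dtype=float),
    )


@dataclass
class FitResult:
    params: SurvivalParams
    log_likelihood: float
    diagnostics: dict = field(default_factory=dict)


def log_likelihood(params: SurvivalParams, records: Sequence[SurvivalRecord]) -> float:
    """Right-censored log-likelihood: deaths contribute log f, censorings log S."""
    t = np.array([r.time for r in records])
    e = np.array([r.event for r in records], dtype=bool)
    if params.family == WEIBULL:
        from scipy.stats import weibull_min

        dist = weibull_min(params.shape, scale=params.scale)
    elif params.family == LOGNORMAL:
        from scipy.stats import lognorm

        dist = lognorm(params.sigma, scale=math.exp(params.mu))
    else:
        raise ValueError("log-likelihood undefined for the degenerate family")
    return float(dist.logpdf(t[e]).sum() + dist.logsf(t[~e]).sum())


def fit_parametric(records: Sequence[SurvivalRecord], family: str) -> FitResult:
    """Maximum-likelihood fit of one family to right-censored records."""
    if family not in FITTABLE_FAMILIES:
        raise ValueError(f"family must be one of {FITTABLE_FAMILIES}, got {family!r}")
    times = np.array([r.time for r in records])
    events = np.array([r.event for r in records])
    n_events = int(events.sum())
    diagnostics = {"n": len(records), "n_events": n_events,
                   "low_confidence": n_events < 10}
    if n_events < 2:
        raise ValueError("fit_parametric requires at least 2 observed events")
    if np.ptp(times[events == 1]) == 0.0 and n_events == len(records):
        raise FitError(
            "degenerate sample: all event times identical, likelihood unbounded",
            diagnostics,
        )
    fitter = WeibullFitter() if family == WEIBULL else LogNormalFitter()
    try:
        fitter.fit(times, events)
    except (ConvergenceError, ValueError) as exc:  # pragma: no cover - rare
        raise FitError(f"{family} fit did not converge: {exc}", diagnostics) from exc
    if family == WEIBULL:
        params = SurvivalParams.weibull(float(fitter.rho_), float(fitter.lambda_))
    else:
        params = SurvivalParams.lognormal(float(fitter.mu_), float(fitter.sigma_))
    ll = float(fitter.log_likelihood_)
    if not math.isfinite(ll):
        raise FitError(f"{family} fit returned non-finite log-likelihood", diagnostics)
    return FitResult(params=params, log_likelihood=ll, diagnostics=diagnostics)


@dataclass
class SelectionResult:
    family: str
    fits: dict  # family -> FitResult
    low_confidence: bool


def select_family(
    records: Sequence[SurvivalRecord],
    candidates: Iterable[str] = FITTABLE_FAMILIES,
) -> SelectionResult:
    """Pick the candidate family with the highest maximised log-likelihood.

    Ties break toward the earlier candidate (weibull first by default).
    """
    candidates = list(candidates)
    if len(candidates) < 2:
        raise ValueError("select_family requires at least 2 candidate families")
    fits: dict[str, FitResult] = {}
    errors: dict[str, Exception] = {}
    for fam in candidates:
        try:
            fits[fam] = fit_parametric(records, fam)
        except (FitError, ValueError) as exc:
            errors[fam] = exc
    if not fits:
        raise FitError(f"all candidate fits failed: {errors}")
    best = max(fits, key=lambda f: (fits[f].log_likelihood, -candidates.index(f)))
    low_conf = any(f.diagnostics.get("low_confidence", False) for f in fits.values())
    return SelectionResult(family=best, fits=fits, low_confidence=low_conf)


def load_survival_records(path) -> list[SurvivalRecord]:
    """Read records from CSV with required header columns time,event."""
    df = pd.read_csv(path)
    missing = {"time", "event"} - set(df.columns)
    if missing:
        raise ValueError(f"survival CSV missing columns: {sorted(missing)}")
    return [SurvivalRecord(float(t), int(e)) for t, e in zip(df["time"], df["event"])]


def save_survival_records(records: Sequence[SurvivalRecord], path) -> None:
    pd.DataFrame(
        {"time": [r.time for r in records], "event": [r.event for r in records]}
    ).to_csv(path, index=False)
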