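"""Structured text configuration: YAML schema, validation and (de)serialization.

A configuration file fully determines both arms of the model: horizon,
discounting, clocks, entry distribution, transition splits, survival
calibration, payer costs and the utility curve.  `validate_config` returns
human-readable findings with field paths (an empty list means valid);
`bundle_from_dict` constructs the runnable `ModelBundle`.
"""

from __future__ import annotations

import hashlib
import json
import math
from importlib import resources
import yaml

from .cea import ModelBundle
from .costs import CostSchedule
from .engine import Arm, ConfigError, ModelSpec, State, TransitionSplits
from .survival import LOGNORMAL, WEIBULL, SurvivalParams
from .utilities import UtilityCurve

_SPLIT_SUMS = (
    ("model.transitions", ("niv_continue", "niv_exit")),
    ("model.transitions", ("iv_continue", "iv_to_hosp")),
    ("model.transitions", ("hosp_stay", "hosp_to_iv", "hosp_death")),
)
_COST_FIELDS = ("niv_home_monthly", "iv_home_monthly", "hosp_nip_monthly",
                "hosp_nvp_monthly", "mv_facility_monthly", "transfer_cost")


def validate_config(cfg: dict) -> list[str]:
    """Schema and invariant checks; returns findings, empty when valid."""
    findings: list[str] = []

    def need(section: str) -> dict:
        if section not in cfg or not isinstance(cfg[section], dict):
            findings.append(f"{section}: missing section")
            return {}
        return cfg[section]

    model = need("model")
    survival = need("survival")
    costs = need("costs")
    utilities = need("utilities")

    horizon = model.get("horizon_cycles", 120)
    if not isinstance(horizon, int) or horizon < 1:
        findings.append(f"model.horizon_cycles: {horizon!r} must be int >= 1")
    rate = model.get("discount_rate_annual", 0.03)
    if not isinstance(rate, (int, float)) or rate < 0:
        findings.append(f"model.discount_rate_annual: {rate!r} must be >= 0")
    mode = model.get("clock_mode", "state_entry")
    if mode not in ("state_entry", "model_time"):
        findings.append(f"model.clock_mode: unknown mode {mode!r}")

    dist = model.get("initial_distribution", {})
    total = 0.0
    for key, p in dist.items():
        path = f"model.initial_distribution.{key}"
        if key not in (s.value for s in State) or key == State.DEATH.value:
            findings.append(f"{path}: not a live health state")
            continue
        if not isinstance(p, (int, float)) or p < 0 or p > 1:
            findings.append(f"{path}: {p!r} outside [0, 1]")
        else:
            total += p
    if dist and abs(total - 1.0) > 1e-12:
        findings.append(f"model.initial_distribution: sums to {total!r}, not 1")

    trans = model.get("transitions", {})
    for name, p in trans.items():
        if not isinstance(p, (int, float)) or not (0.0 <= p <= 1.0):
            findings.append(f"model.transitions.{name}: {p!r} outside [0, 1]")
    defaults = TransitionSplits()
    get = lambda k: trans.get(k, getattr(defaults, k))
    for path, names in _SPLIT_SUMS:
        try:
            s = sum(float(get(k)) for k in names)
        except (TypeError, ValueError):
            continue
        if abs(s - 1.0) > 1e-12:
            findings.append(f"{path}[{'+'.join(names)}]: splits sum to {s:g}")

    for key in ("niv", "iv"):
        sub = survival.get(key, {})
        path = f"survival.{key}"
        fam = sub.get("family")
        if fam not in (WEIBULL, LOGNORMAL, "none"):
            findings.append(f"{path}.family: unknown family {fam!r}")
            continue
        for pname in ("shape", "sigma", "scale", "median_months"):
            if pname in sub and (not isinstance(sub[pname], (int, float))
                                 or sub[pname] <= 0):
                findings.append(f"{path}.{pname}: {sub[pname]!r} must be > 0")

    for name in _COST_FIELDS:
        if name in costs and (not isinstance(costs[name], (int, float))
                              or costs[name] < 0):
            findings.append(f"costs.{name}: {costs[name]!r} must be >= 0")

    mult = utilities.get("facility_multiplier", 0.9)
    if not isinstance(mult, (int, float)) or not (0.0 < mult < 2.0):
        findings.append(
            f"utilities.facility_multiplier: {mult!r} outside (0, 2)")
    anchors = utilities.get("anchors", [])
    if anchors:
        ages = [a[0] for a in anchors]
        utils = [a[1] for a in anchors]
        if any(b <= a for a, b in zip(ages, ages[1:])):
            findings.append("utilities.anchors: ages not strictly increasing")
        if utils and utils[-1] != 0:
            findings.append(
                f"utilities.anchors: terminal utility {utils[-1]!r} != 0")
        if any(not math.isfinite(float(u)) for u in utils):
            findings.append("utilities.anchors: non-finite utility value")
    return findings


def _survival_from_dict(sub: dict) -> SurvivalParams:
    fam = sub["family"]
    if fam == WEIBULL:
        if "scale" in sub:
            return SurvivalParams.weibull(sub["shape"], sub["scale"])
        return SurvivalParams.weibull_from_median(sub["median_months"],
                                                  sub["shape"])
    if fam == LOGNORMAL:
        if "mu" in sub:
            return SurvivalParams.lognormal(sub["mu"], sub["sigma"])
        return SurvivalParams.lognormal_from_median(sub["median_months"],
                                                     sub["sigma"])
    return SurvivalParams.none()


def _survival_to_dict(params: SurvivalParams) -> dict:
    if params.family == WEIBULL:
        return {"family": WEIBULL, "shape": params.shape, "scale": params.scale}
    if params.family == LOGNORMAL:
        return {"family": LOGNORMAL, "mu": params.mu, "sigma": params.sigma}
    return {"family": "none"}


def bundle_from_dict(cfg: dict) -> ModelBundle:
    findings = validate_config(cfg)
    if findings:
        raise ConfigError("; ".join(findings))
    model = cfg["model"]
    niv_params = _survival_from_dict(cfg["survival"]["niv"])
    iv_params = _survival_from_dict(cfg["survival"]["iv"])
    splits = TransitionSplits(**model.get("transitions", {}))
    init = {State(k): float(v)
            for k, v in model["initial_distribution"].items()}
    common = dict(
        niv_survival=niv_params, iv_survival=iv_params,
        initial_distribution=init,
        horizon_cycles=model.get("horizon_cycles", 120),
        discount_rate_annual=model.get("discount_rate_annual", 0.03),
        splits=splits, clock_mode=model.get("clock_mode", "state_entry"),
        iv_clock_resumes_after_hospital=model.get(
            "iv_clock_resumes_after_hospital", True))
    c = cfg["costs"]
    schedule = CostSchedule(
        niv_home_monthly=c["niv_home_monthly"],
        iv_home_monthly=c["iv_home_monthly"],
        hosp_nip_monthly=c["hosp_nip_monthly"],
        hosp_nvp_monthly=c["hosp_nvp_monthly"],
        mv_facility_monthly=c["mv_facility_monthly"],
        transfer_cost=c["transfer_cost"],
        nip_episode_months=c.get("nip_episode_months", 3),
        nip_first_episode_only=c.get("nip_first_episode_only", False))
    u = cfg["utilities"]
    curve = UtilityCurve(
        anchor_ages=tuple(a[0] for a in u["anchors"]),
        anchor_utilities=tuple(a[1] for a in u["anchors"]),
        facility_multiplier=u.get("facility_multiplier", 0.9),
        method=u.get("method", "pchip"))
    return ModelBundle(
        spec_hmv=ModelSpec(arm=Arm.HMV, **common),
        spec_mv=ModelSpec(arm=Arm.MV, **common),
        costs=schedule, utilities=curve)


def bundle_to_dict(bundle: ModelBundle) -> dict:
    spec = bundle.spec_hmv
    c = bundle.costs
    u = bundle.utilities
    return {
        "model": {
            "horizon_cycles": spec.horizon_cycles,
            "discount_rate_annual": spec.discount_rate_annual,
            "clock_mode": spec.clock_mode,
            "iv_clock_resumes_after_hospital":
                spec.iv_clock_resumes_after_hospital,
            "initial_distribution": {
                s.value: p for s, p in spec.initial_distribution.items()},
            "transitions": dict(spec.splits.__dict__),
        },
        "survival": {"niv": _survival_to_dict(spec.niv_survival),
                     "iv": _survival_to_dict(spec.iv_survival)},
        "costs": {
            "niv_home_monthly": c.niv_home_monthly,
            "iv_home_monthly": c.iv_home_monthly,
            "hosp_nip_monthly": c.hosp_nip_monthly,
            "hosp_nvp_monthly": c.hosp_nvp_monthly,
            "mv_facility_monthly": c.mv_facility_monthly,
            "transfer_cost": c.transfer_cost,
            "nip_episode_months": c.nip_episode_months,
            "nip_first_episode_only": c.nip_first_episode_only,
        },
        "utilities": {
            "facility_multiplier": u.facility_multiplier,
            "method": u.method,
            "anchors": [[float(a), float(v)] for a, v in
                        zip(u.anchor_ages, u.anchor_utilities)],
        },
    }


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    return cfg


def load_bundle(path) -> ModelBundle:
    return bundle_from_dict(load_config(path))


def dump_bundle(bundle: ModelBundle, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(bundle_to_dict(bundle), fh, sort_keys=False)


def baseline_config() -> dict:
    """The bundled baseline configuration shipped with the package."""
    text = resources.files("ventcea").joinpath("data/baseline.yaml").read_text()
    return yaml.safe_load(text)


def config_hash(cfg: dict) -> str:
    """Stable hash of a configuration for run manifests."""
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True).encode()).hexdigest()[:16]
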