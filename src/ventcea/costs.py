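"""Czech-payer cost arithmetic for home and facility mechanical ventilation.

Reimbursement follows the point system: each treatment day carries a
performance point value plus a fixed overhead point allowance, converted to
koruna at the decreed rate for the year.  Home-care costs combine device
amortization, accessory payments, nursing care and other averaged payer
costs.  All amounts are CZK at 2020 price level; a month is 30 days and a
year 365 days, matching the payer tables the baseline reproduces.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import pandas as pd

# 2020 decree constants
NURSING_POINT_VALUE = 1.07     # CZK per point, home nursing (expertise 925)
INPATIENT_POINT_VALUE = 1.18   # CZK per point, inpatient treatment days
OVERHEAD_POINTS = 191.86       # overhead points per treatment day
NIP_POINTS = 9364              # OD 00017, follow-up intensive care
NVP_POINTS = 6150              # OD 00015, follow-up ventilation care

DAYS_PER_MONTH = 30
DAYS_PER_YEAR = 365

# Non-invasive home ventilation: BiPAP device and annual accessory payments
BIPAP_PRICE = 62_424.0
BIPAP_AMORTIZATION_YEARS = 7
ACCESSORIES_ANNUAL = {"masks": 4202.0, "hoses": 967.0,
                      "humidifiers": 1500.0, "filters": 699.0}
NIV_NURSING_OTHER_MONTHLY = 15_720.0
NIV_NURSING_OTHER_ANNUAL = 191_266.0
NIV_TECH_MONTHLY = 1338.0
NIV_HOME_MONTHLY_TOTAL = 17_058.0

# Invasive home ventilation component totals (monthly), by patient mobility
IV_TECH_MONTHLY = {"mobile": 20_550.0, "immobile": 23_550.0}
IV_NURSING_MONTHLY = 38_809.0
IV_OTHER_MONTHLY = 68_192.0

# Transport between home and facility (one event, either direction)
TRANSPORT_COMPONENTS = {"medical_performance": 2055.46,
                        "transport_services": 2725.68,
                        "material_or_medication": 450.0}

# Printed monthly hospitalization figure for the first three episode months;
# note it differs from 30x the unrounded per-day intensive-care payment
# (338,277) -- the recompute mode rebuilds it from the daily payment instead.
NIP_MONTHLY_PUBLISHED = 333_277.0


@dataclass(frozen=True)
class PointSchedule:
    """Koruna-per-point rate plus the per-treatment-day overhead allowance."""

    point_value: float = INPATIENT_POINT_VALUE
    overhead_points: float = OVERHEAD_POINTS

    def __post_init__(self):
        if self.point_value <= 0 or self.overhead_points < 0:
            raise ValueError("point schedule values must be positive")


def treatment_day_payment_exact(performance_points: float,
                                schedule: PointSchedule) -> float:
    """Unrounded CZK per treatment day: (points + overhead) x point value."""
    if performance_points < 0:
        raise ValueError("performance points must be >= 0")
    return (performance_points + schedule.overhead_points) * schedule.point_value


def treatment_day_payment(performance_points: float,
                          schedule: PointSchedule) -> int:
    """CZK per treatment day rounded to whole koruna."""
    return round(treatment_day_payment_exact(performance_points, schedule))


def monthly_from_daily(daily: float) -> float:
    """CZK per 30-day month from an (unrounded) daily amount."""
    if daily < 0:
        raise ValueError("daily amount must be >= 0")
    return daily * DAYS_PER_MONTH


def device_amortization(price: float, amortization_years: float,
                        annual_accessories: float = 0.0) -> float:
    """Annual CZK for a device amortized over its payment horizon plus
    yearly accessory payments."""
    if amortization_years <= 0:
        raise ValueError("amortization horizon must be positive")
    return price / amortization_years + annual_accessories


def invasive_home_monthly(tech: float, nursing: float, other: float) -> float:
    """Monthly invasive home-ventilation cost as the sum of its components."""
    if min(tech, nursing, other) < 0:
        raise ValueError("cost components must be >= 0")
    return tech + nursing + other


def mobility_average(mobile: float, immobile: float) -> float:
    """Average the mobile- and immobile-patient monthly totals."""
    return (mobile + immobile) / 2.0


def cpi_escalate(amount: float, annual_inflation_factors: Iterable[float]) -> float:
    """Escalate a historical amount by compounding annual CPI factors."""
    out = amount
    for f in annual_inflation_factors:
        if f <= -1:
            raise ValueError("inflation factor must exceed -1")
        out *= 1.0 + f
    return out


def transport_total(components: Sequence[float]) -> float:
    if any(c < 0 for c in components):
        raise ValueError("transport components must be >= 0")
    return float(sum(components))


@dataclass(frozen=True)
class CostSchedule:
    """Per-state monthly costs and the per-event transfer cost (CZK).

    Hospitalization is billed as follow-up intensive care (NIP) for the
    first `nip_episode_months` months of an episode and follow-up
    ventilation care (NVP) thereafter; the facility arm bills NVP for every
    state.  With `nip_first_episode_only`, readmissions bill NVP from the
    first month.
    """

    niv_home_monthly: float
    iv_home_monthly: float
    hosp_nip_monthly: float
    hosp_nvp_monthly: float
    mv_facility_monthly: float
    transfer_cost: float
    nip_episode_months: int = 3
    nip_first_episode_only: bool = False

    def __post_init__(self):
        amounts = (self.niv_home_monthly, self.iv_home_monthly,
                   self.hosp_nip_monthly, self.hosp_nvp_monthly,
                   self.mv_facility_monthly, self.transfer_cost)
        if any(a < 0 for a in amounts):
            raise ValueError("all costs must be non-negative")
        if self.nip_episode_months < 0:
            raise ValueError("nip_episode_months must be >= 0")

    def hospitalization_monthly(self, episode_month: int,
                                had_prior_episode: bool = False) -> float:
        """Monthly cost in an admission's `episode_month` (0-based)."""
        if episode_month < 0:
            raise ValueError("episode month must be >= 0")
        if self.nip_first_episode_only and had_prior_episode:
            return self.hosp_nvp_monthly
        if episode_month < self.nip_episode_months:
            return self.hosp_nip_monthly
        return self.hosp_nvp_monthly

    def perturb(self, **scaled) -> "CostSchedule":
        return replace(self, **scaled)


def nvp_monthly_exact(schedule: PointSchedule | None = None) -> float:
    schedule = schedule or PointSchedule()
    return monthly_from_daily(treatment_day_payment_exact(NVP_POINTS, schedule))


def nip_monthly_exact(schedule: PointSchedule | None = None) -> float:
    schedule = schedule or PointSchedule()
    return monthly_from_daily(treatment_day_payment_exact(NIP_POINTS, schedule))


def baseline_cost_schedule(recompute_from_daily: bool = False) -> CostSchedule:
    """Assemble the baseline payer cost schedule.

    By default the published monthly NIP figure is used verbatim; with
    `recompute_from_daily` the hospitalization months are rebuilt from the
    unrounded per-treatment-day payments (which yields 338,277 for NIP).
    """
    nvp_monthly = round(nvp_monthly_exact())
    nip_monthly = (round(nip_monthly_exact()) if recompute_from_daily
                   else NIP_MONTHLY_PUBLISHED)
    iv_monthly = mobility_average(
        invasive_home_monthly(IV_TECH_MONTHLY["mobile"], IV_NURSING_MONTHLY,
                              IV_OTHER_MONTHLY),
        invasive_home_monthly(IV_TECH_MONTHLY["immobile"], IV_NURSING_MONTHLY,
                              IV_OTHER_MONTHLY),
    )
    return CostSchedule(
        niv_home_monthly=NIV_HOME_MONTHLY_TOTAL,
        iv_home_monthly=iv_monthly,
        hosp_nip_monthly=float(nip_monthly),
        hosp_nvp_monthly=float(nvp_monthly),
        mv_facility_monthly=float(nvp_monthly),
        transfer_cost=transport_total(list(TRANSPORT_COMPONENTS.values())),
    )


def cost_audit() -> pd.DataFrame:
    """Trace every assembled baseline figure back to its components.

    Returns a frame with columns component, source, value suitable for CSV
    export and eyeball checks against the payer tables.
    """
    schedule = PointSchedule()
    accessories = sum(ACCESSORIES_ANNUAL.values())
    tech_annual = device_amortization(BIPAP_PRICE, BIPAP_AMORTIZATION_YEARS,
                                      accessories)
    rows = [
        ("niv_accessories_annual", "niv_home", accessories),
        ("niv_tech_support_annual", "niv_home", round(tech_annual)),
        ("niv_home_monthly_total", "niv_home",
         NIV_TECH_MONTHLY + NIV_NURSING_OTHER_MONTHLY),
        ("niv_home_annual_total", "niv_home",
         round(tech_annual) + NIV_NURSING_OTHER_ANNUAL),
        ("iv_home_monthly_mobile", "iv_home",
         invasive_home_monthly(IV_TECH_MONTHLY["mobile"], IV_NURSING_MONTHLY,
                               IV_OTHER_MONTHLY)),
        ("iv_home_monthly_immobile", "iv_home",
         invasive_home_monthly(IV_TECH_MONTHLY["immobile"], IV_NURSING_MONTHLY,
                               IV_OTHER_MONTHLY)),
        ("iv_home_monthly_average", "iv_home",
         baseline_cost_schedule().iv_home_monthly),
        ("nip_daily_payment", "point_system",
         treatment_day_payment(NIP_POINTS, schedule)),
        ("nvp_daily_payment", "point_system",
         treatment_day_payment(NVP_POINTS, schedule)),
        ("nvp_monthly", "point_system", round(nvp_monthly_exact(schedule))),
        ("nip_monthly_recomputed", "point_system",
         round(nip_monthly_exact(schedule))),
        ("nip_monthly_published", "point_system", NIP_MONTHLY_PUBLISHED),
        ("transfer_total", "transport",
         transport_total(list(TRANSPORT_COMPONENTS.values()))),
    ]
    return pd.DataFrame(rows, columns=["component", "source", "value"])
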