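"""Rebuild the payer cost schedule from its published components.

Prints the cost audit: every monthly figure used by the model traced back
to point-system payments, device amortization and component sums.
"""

from ventcea import baseline_cost_schedule, cost_audit

print(cost_audit().to_string(index=False))

sched = baseline_cost_schedule()
print("\nassembled schedule (CZK per 30-day month):")
print(f"  home NIV   {sched.niv_home_monthly:>10,.0f}")
print(f"  home IV    {sched.iv_home_monthly:>10,.0f}")
print(f"  hospital   {sched.hosp_nip_monthly:>10,.0f} (months 1-3, intensive"
      f" care) then {sched.hosp_nvp_monthly:,.0f} (ventilation care)")
print(f"  facility   {sched.mv_facility_monthly:>10,.0f} (both states)")
print(f"  transfer   {sched.transfer_cost:>10,.2f} per transport event")
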