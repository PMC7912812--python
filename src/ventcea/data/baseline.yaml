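# Baseline two-arm configuration: 120 monthly cycles, 3% annual discounting,
# published transition splits and payer costs, 10% facility utility
# decrement, survival calibrated to the cited median survival on each
# ventilation modality.  Utility anchors and the entry split are documented
# configuration choices (see docs/methods.md), not published values.
model:
  horizon_cycles: 120
  discount_rate_annual: 0.03
  clock_mode: state_entry
  iv_clock_resumes_after_hospital: true
  initial_distribution:
    NIV: 0.74
    IV: 0.26
  transitions:
    niv_continue: 0.99812
    niv_exit: 0.00188
    iv_continue: 0.999
    iv_to_hosp: 0.001
    hosp_stay: 0.01
    hosp_to_iv: 0.95
    hosp_death: 0.04
survival:
  niv:
    family: weibull
    shape: 1.5
    median_months: 25.8
  iv:
    family: lognormal
    sigma: 0.8
    median_months: 33.8
costs:
  niv_home_monthly: 17058.0
  iv_home_monthly: 129051.0
  hosp_nip_monthly: 333277.0        # published monthly intensive-care figure
  hosp_nvp_monthly: 224502.0        # 30 x unrounded ventilation-care day
  mv_facility_monthly: 224502.0
  transfer_cost: 5231.14
  nip_episode_months: 3
  nip_first_episode_only: false
utilities:
  facility_multiplier: 0.9
  method: pchip
  anchors:                           # [age in years, EQ-5D index]
    - [42.8, 0.42]
    - [43.05, 0.415]
    - [43.3, 0.41]
    - [43.55, 0.405]
    - [43.8, 0.40]
    - [44.05, 0.395]
    - [44.3, 0.39]
    - [120.0, 0.0]
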