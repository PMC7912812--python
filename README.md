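# ventcea

Cost–utility modelling of **home mechanical ventilation (HMV)** versus
**mechanical ventilation in a healthcare facility (MV)** for adults with
amyotrophic lateral sclerosis (ALS), from a healthcare-payer perspective.
The package is aimed at health-economics and HTA practitioners who want a
tested, configurable reimplementation of this comparison: a deterministic
Markov cohort engine with time-in-state clocks, parametric survival
calibration, Czech payer cost arithmetic, utility trajectories, and the
incremental cost–utility ratio with sensitivity and scenario analyses.

## The model

Two strategy arms are propagated over a 10-year horizon in 120 monthly
cycles:

* **HMV arm** (4 states): home non-invasive ventilation (NIV), home
  invasive ventilation (IV), Hospitalization, Death.
* **MV arm** (3 states): facility NIV, facility IV, Death.

Each cycle, the probability of death is taken from a parametric survival
curve — Weibull for NIV (median 25.8 months) and log-normal for IV (median
33.8 months), each evaluated on a clock that starts when the modality
starts — and the surviving mass is split by fixed conditional transition
probabilities (NIV continues with 0.99812; IV continues with 0.999; a
hospital episode resolves 1% stay / 95% back to IV / 4% death per month).
States accrue monthly payer costs (whole-CZK point-system arithmetic for
facility treatment days, component sums for home care, a CZK 5,231.14
transport cost per transfer) and utilities from an age-indexed EQ-5D curve
interpolated from 42.8 down to 0 at 120 years, with a 10% multiplicative
decrement in facility settings. Costs and QALYs are discounted at 3% per
year and compared as

```
ICUR = (Cost_HMV − Cost_MV) / (QALY_HMV − QALY_MV) = ΔCost / ΔQALY
```

with an explicit dominance classification (the sign of the ratio alone
cannot distinguish a dominant intervention from a dominated one) and a
near-zero ΔQALY guard. A 20,000-patient microsimulation oracle validates
the cohort engine, and a synthetic-data module generates right-censored
survival cohorts for calibration exercises.

## Worked example

```python
from ventcea import baseline_fixture, run_cua

bundle = baseline_fixture()       # shipped baseline configuration
res = run_cua(bundle)
print(f"HMV CZK {res.cost1:,.0f} / {res.qaly1:.2f} QALY; "
      f"MV CZK {res.cost2:,.0f} / {res.qaly2:.2f} QALY; {res.dominance}")
```

prints

```
HMV CZK 1,899,575 / 1.05 QALY; MV CZK 7,277,668 / 0.94 QALY; intervention_dominant
```

Home care costs roughly a quarter of facility care over ten years (the
facility bills a ventilation-care treatment day for every patient-month,
CZK 224,502 per month) while accruing more quality-adjusted life because
home states carry the undecremented utility. Home care is therefore the
dominant strategy: cheaper and more effective. The QALY totals depend on
the shipped placeholder utility anchors; `calibrate_utility_scale`
rescales them so an arm reproduces a published cumulative-utility total
(see `examples/04_cost_utility.py`).

The `examples/` directory contains one short script per capability:
survival calibration, the cohort model, cost assembly, the cost–utility
comparison, sensitivity/scenario analyses and microsimulation validation.
A thin CLI covers the same ground for config-driven use:

```sh
ventcea run -o out/          # traces, cumulative curves, CUA report, manifest
ventcea validate -c my.yaml  # schema and invariant findings with field paths
ventcea sensitivity -p facility_utility_multiplier -o sa.csv
ventcea scenario --niv 1.0 --iv 0.0 -o scenario.csv
ventcea synth --n 1000 --family weibull --median 25.8 -o records.csv
```

## Documentation

`docs/methods.md` describes the model and its assumptions, the clock and
accrual conventions, every tunable parameter with its default and
rationale, what the synthetic-data generator does and does not emulate,
and known limitations.
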