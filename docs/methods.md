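# Methods

## Model structure

The comparison is a pair of deterministic Markov cohort models run in
monthly cycles over a 10-year horizon (120 cycles). The home-ventilation
arm has four states — non-invasive ventilation (NIV), invasive ventilation
(IV), Hospitalization and Death — and the facility arm three (NIV, IV,
Death); Death is the only absorbing state and Hospitalization exists only
in the home arm, since facility patients are already hospitalized.

Each cycle a state's death probability is evaluated first from its
parametric survival curve, and the surviving mass is then divided by fixed
conditional splits:

| source | split of surviving mass |
|---|---|
| NIV (home) | 0.99812 stay, 0.00188 to Hospitalization |
| NIV (facility) | 0.99812 stay, 0.00188 to IV |
| IV (home) | 0.999 stay, 0.001 to Hospitalization |
| IV (facility) | 1.0 stay |
| Hospitalization | unconditional 0.01 stay / 0.95 to IV / 0.04 death |

Hospitalization carries no parametric hazard; its 4% monthly death
probability is part of the unconditional split.

## Survival and clocks

NIV deaths follow a Weibull law and IV deaths a log-normal law, calibrated
so the medians equal the literature values for each modality: 25.8 months
(NIV) and 33.8 months (IV). The published analyses never report the fitted
shape parameters, so the shipped configuration uses documented placeholder
values — Weibull shape k = 1.5 and log-normal σ = 0.8 — which the
`survival` module can replace by maximum-likelihood fits on (time, event)
records (`fit_parametric`, with `select_family` choosing between families
by maximised log-likelihood, ties broken toward Weibull).

Per-cycle death probabilities use the standard conditional conversion
p(t) = 1 − S(t+1)/S(t) with time in months; compounding 1 − p(t) over
cycles reconstructs S exactly, which the tests assert to 1e−10.

Because the source survival curves measure time from each modality's
initiation, hazards run on **state-entry clocks** by default: the NIV
clock coincides with model time (NIV is only occupied from entry), and the
IV clock starts at invasive-ventilation initiation. A hospital admission
pauses the IV clock (the admission month itself counts as IV time) and the
clock resumes on return to IV; a documented alternative
(`iv_clock_resumes_after_hospital: false`) restarts it, and
`clock_mode: model_time` evaluates all hazards on model time instead. Both
alternatives are exercised against the microsimulation oracle in the test
suite. Each hospital admission restarts the episode clock that drives the
billing switch below.

## Costs

All amounts are CZK at the 2020 price level; a month is 30 days and a year
365 days, following the payer tables. Facility treatment days follow the
Czech point system: a treatment day is paid
(performance points + 191.86 overhead points) × CZK 1.18, rounded to whole
koruna — CZK 11,276/day for follow-up intensive care (NIP, 9,364 points)
and CZK 7,483/day for follow-up ventilation care (NVP, 6,150 points).
Monthly figures multiply the *unrounded* daily payment by 30 (NVP:
CZK 224,502/month).

Home NIV costs CZK 17,058/month (device amortization CZK 62,424 over 7
years plus CZK 7,368/year of accessories, with nursing/other costs);
home IV costs CZK 129,051/month, the average of the mobile
(CZK 127,551) and immobile (CZK 130,551) component totals. A
hospitalization episode bills NIP for its first three months and NVP
thereafter; by default every episode restarts at NIP
(`nip_first_episode_only` bills readmissions at NVP from month one, since
the payer rule caps NIP reporting at 90 days). The facility arm bills NVP
for every alive patient-month. Transfers into hospital and back each cost
CZK 5,231.14, charged at the destination cycle's discount factor.

Two source-table quirks are handled explicitly: the published monthly NIP
figure (CZK 333,277) does not equal 30 × the NIP daily payment
(CZK 338,277.44); the baseline uses the published figure verbatim and a
`recompute_from_daily` mode rebuilds it from the daily payment. The
published *annual* mobile-IV total also exceeds its printed components by
CZK 135; monthly totals, which the model uses, are internally consistent
(the cost audit exposes both).

## Utilities

Quality of life is an EQ-5D index curve over patient age. Anchor values —
in practice obtained by mapping SF-36 domain scores through a published
crosswalk, for which `sf36_to_eq5d` provides a generic affine interface
with configurable coefficients — are interpolated by a monotone piecewise
cubic (configurable to linear) from the cohort entry age of 42.8 years to
0 at a terminal age of 120 years. Age advances with model time. Home NIV
and home IV carry the full curve value (quality-of-life differences
between the modalities at home are reported to be insignificant);
Hospitalization and both facility-arm states carry a multiplicative
decrement, 0.9 at baseline. The decrement is multiplicative rather than
subtractive because facility-arm cumulative QALYs then scale exactly
linearly in the multiplier, matching the exactly proportional pattern of
the published sensitivity table.

The shipped anchor set is a documented placeholder (a gently declining
plateau around 0.4 over the first 1.5 years of follow-up, then a monotone
decline to the terminal zero): the converted anchor values behind the
published totals were never released. `calibrate_utility_scale` rescales
all anchors by one factor so a chosen arm reproduces a published
cumulative-utility total; reproducing totals above the 10-QALY ceiling of
a 120-month horizon requires anchors above 1 (the published accounting
evidently summed monthly utilities without the 1/12-year conversion), so
the helper warns when the rescaled curve leaves the EQ-5D index range.
This package always accrues utility/12 QALY per monthly cycle.

## Accrual and discounting

No half-cycle correction is applied: each cycle accrues the full monthly
cost and utility of the state occupied at cycle start. Discounting is
exact annual compounding at monthly resolution, (1 + r)^(−t/12) at cycle
t, with r = 0.03 at baseline and 0 %/5 % as standard scenarios. Zero
discounting reproduces plain sums exactly. All arithmetic is
floating-point; rounding (whole CZK, two-decimal QALYs) happens only in
the reporting layer, and the run manifest keeps full precision.

## CEA, sensitivity and scenarios

`icur` reports ΔCost/ΔQALY with a dominance classification; when
|ΔQALY| falls below a guard (default 1e−6 QALY) the ratio is suppressed as
`near_zero_delta_qaly` (the raw ratio stays available as a diagnostic),
because dividing by a vanishing denominator produces arbitrarily large,
meaningless ratios.

`one_way_sa` perturbs one parameter at a time over a ±30% grid in 10%
steps. The registry resolves "all input parameters" explicitly: every
per-state monthly cost, the transfer cost, the exit-probability splits
(renormalizing the residual of their conditional split), survival
time-scale factors, and the discount rate. The facility utility
multiplier is special-cased as an *offset from the undecremented home
value* (multiplier = 1 + p, so p = −0.1 is the baseline decrement),
mirroring how the published sensitivity analysis varied it. Sensitivity
rows additionally carry a `near_zero` reporting flag at |ΔQALY| < 0.01,
the threshold at which the published table footnotes its 0%-offset row;
note this absolute threshold is scale-dependent — on the uncalibrated
baseline (≈1 QALY totals) the 0%-offset row is flagged, while on curves
calibrated to the published totals (≈12.6 QALY) the structural QALY gap
between the arms (hospital-pathway mortality exists only in the home arm,
and grows with the IV share of the entry cohort) is about 0.012 and
narrowly escapes the flag.

`scenario_initial_distribution` re-runs both arms under a replacement
entry mix, e.g. the all-NIV entry scenario, which sharply reduces
home-arm costs by removing expensive invasive-ventilation starters. The
direction of the *facility*-arm cost change under that scenario depends on
the relative truncated, discounted survival of the two modalities; with
the shipped placeholder tails IV starters outlive NIV starters within the
horizon, so facility costs fall slightly rather than rise.

## Synthetic data and validation

`simulate_survival` draws event times from the configured family with
independent Uniform(0, U) censoring, U solved so the expected censored
fraction matches the requested rate; one seeded generator per run with a
documented draw order makes every artifact bit-reproducible. The
generator emulates the statistical shape of ventilation-survival cohorts
(parametric event times, independent right censoring) but not patient
covariates, bulbar-onset subgroups, informative censoring or calendar-time
effects — passing calibration tests therefore demonstrates correctness of
the fitting machinery, not fidelity to any real cohort.

`microsim_oracle` is an independent cross-check of the cohort engine: n
patient paths sampled by direct categorical draws from the same transition
rows, with identical accrual rules. Engine and oracle agree within
Monte-Carlo error (3 binomial/sample standard errors at n = 20,000) on
occupancy and cumulative accruals across the baseline, a model-time-clock
variant and an all-NIV entry variant. Test problem sizes (n = 1,000–20,000
records or paths, 20 selection replicates) are chosen so the full suite
runs in well under a minute while keeping standard errors far below the
asserted tolerances.

## Configuration defaults that are choices, not data

* **Entry distribution** NIV 0.74 / IV 0.26: the source cohort's modality
  split was never published; this split was fixed once so the baseline's
  cohort-level cumulative costs land at the magnitude the published
  analysis reports (≈1.9M CZK home, ≈7.3M CZK facility), and the all-NIV
  scenario is the only externally anchored alternative.
* **Weibull k = 1.5, log-normal σ = 0.8**: placeholder second parameters;
  only the medians are externally constrained.
* **Utility anchors**: placeholder plateau-then-decline set, see above.
* **Censoring rate** of synthetic cohorts: free parameter (the source
  curves' censoring structure is unknown); tests use 0–25%.

## Known limitations

Cohort-level model only: no patient covariates or probabilistic
sensitivity analysis (one-way analysis matches the source analysis's
scope). No half-cycle or life-table correction. The societal perspective
(informal caregiver time and costs) is out of scope. Published headline
totals are reproducible only up to the unpublished inputs listed above;
the package instead asserts the reproducible structure: exact cost
arithmetic, dominance under calibration, exact multiplier linearity and
engine–microsimulation agreement.
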