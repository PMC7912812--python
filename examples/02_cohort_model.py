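"""Run the baseline Markov cohort model for both strategy arms.

Propagates the cohort over 120 monthly cycles and prints state occupancy
at one, five and ten years plus the cumulative discounted cost and QALYs
of each arm.
"""

from ventcea import baseline_fixture, cumulative_outputs, run_cohort

bundle = baseline_fixture()
for spec in (bundle.spec_hmv, bundle.spec_mv):
    trace = run_cohort(spec, bundle.costs, bundle.utilities)
    print(f"\n{spec.arm.value} arm ({len(spec.states)} states)")
    for cycle in (12, 60, 120):
        occ = trace.occupancy.loc[cycle]
        states = ", ".join(f"{s} {occ[s]:.3f}" for s in trace.occupancy)
        print(f"  cycle {cycle:3d}: {states}")
    cost, qaly = cumulative_outputs(trace)
    print(f"  cumulative: CZK {cost:,.0f} and {qaly:.2f} QALY "
          "(discounted at 3%/year)")
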