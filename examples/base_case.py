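"""Base-case comparison: biennial MRM vs XM screening over 20 years.

Runs the Markov cohort model for both strategies on the packaged rate
fixtures and prints cumulative discounted costs, effects, incrementals
and the ICER.  An ICER below the $100,000/QALY willingness-to-pay
threshold means the extra cost of MRM buys QALYs at an acceptable price.
"""

import densescreen as ds

params = ds.base_case()
rates = ds.load_default_rates()

xm = ds.run_strategy(ds.Modality.XM, params, rates)
mrm = ds.run_strategy(ds.Modality.MRM, params, rates)
result = ds.compare_strategies(xm, mrm, params.wtp)

print(f"{'strategy':>8} {'cost ($)':>10} {'effects (QALYs)':>16}")
print(f"{'XM':>8} {xm.total_cost:>10,.0f} {xm.total_qaly:>16.3f}")
print(f"{'MRM':>8} {mrm.total_cost:>10,.0f} {mrm.total_qaly:>16.3f}")
print(
    f"\nincremental cost ${result.incr_cost:,.0f}, incremental effect "
    f"{result.incr_effect:.3f} QALYs\n"
    f"ICER {result.icer:,.0f} $/QALY "
    f"({'cost-effective' if result.cost_effective_at_wtp else 'not cost-effective'} "
    f"at ${params.wtp:,.0f}/QALY)"
)
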