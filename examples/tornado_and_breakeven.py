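"""Deterministic sensitivity analysis: tornado bars and break-even costs.

The tornado ranks single-parameter swings by how far they move the ICER;
the break-even analysis asks what an MRM examination may cost before the
MRM strategy stops saving money overall (equal cumulative costs).
"""

import densescreen as ds

params = ds.base_case()
rates = ds.load_default_rates()

entries = ds.one_way_tornado(params, ds.default_tornado_ranges(params), rates)
print("tornado (widest first); cells are incremental $/QALY, negative = MRM dominant")
for e in entries:
    print(
        f"  {e.parameter:>22}: [{e.low:>9.3f}, {e.high:>9.3f}] -> "
        f"ICER [{e.icer_low:>9,.0f}, {e.icer_high:>9,.0f}]  span {e.span:>9,.0f}"
    )

print()
for spec in (0.92, 0.99):
    be = ds.break_even_mrm_cost(params, spec, rates)
    print(
        f"at later-round specificity {spec:.0%}: equal strategy costs at an "
        f"MRM tariff of ${be:,.2f}"
    )
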