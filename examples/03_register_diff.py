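"""Approximate annual workforce flows by diffing two register snapshots.

Run:  python examples/03_register_diff.py
"""

import oralforce as of

truth = of.default_truth(seed=0)
earlier, later, planted = of.gen_register_pair(truth, n0=3053, seed=3)
print(f"register {earlier.as_of_year}: {len(earlier)} practitioners; "
      f"{later.as_of_year}: {len(later)}")

est = of.diff_registers(earlier, later, retirement_heuristic=True)
print(f"inflows:  {est.inflow_new_graduates} new graduates, "
      f"{est.inflow_foreign_trained} foreign-trained, "
      f"{est.inflow_returning_domestic} returning domestic")
print(f"outflows: {est.total_outflow} total "
      f"({est.outflow_retirement_estimate} presumed retired - qualified 41+ years ago)")
print(f"planted truth: {planted}")
# The differ recovers the planted inflow categories and total outflow exactly;
# outflow subtypes beyond the retirement heuristic need auxiliary data.

flows = est.to_flow_assumptions()
print(f"\nas projection assumptions, net non-graduate flow: {flows.net:+.0f}/yr")
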