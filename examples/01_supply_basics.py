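"""Supply-side building blocks: activity rate, graduate pipeline, FTE supply.

Run:  python examples/01_supply_basics.py
"""

import oralforce as of

# 30% of dentists work part-time at 50% of full-time hours
rate = of.activity_rate(part_time_share=0.30, part_time_hours_fraction=0.50)
print(f"activity rate: {rate:.2f}")  # 0.85 - the workforce delivers 85% of full-time hours

# 100 first-year dental places, 10% never reach year 2, 5% attrition after
# that, and 80% of graduates take up domestic employment
pipeline = of.GraduatePipeline(
    intake_places=100, nonprogression_y2=0.10, attrition_rate=0.05,
    domestic_employment_share=0.80, course_length=5,
)
grads = of.new_graduates(pipeline)
print(f"graduates available per cohort: {grads:.1f}, "
      f"2017 entrants arrive in {of.graduate_arrival_year(pipeline, 2017)}")

# 3053 registrants, 95% actively practising, 85% activity rate
params = of.SupplyParams(participation_rate=0.95, part_time_share=0.30,
                         part_time_hours_fraction=0.50)
print(f"FTE supply from a stock of 3053: {of.fte_supply(3053, params):.1f}")
# = 3053 x 0.95 x 0.85: the register headcount shrunk to full-time equivalents
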