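"""Full run: supply vs needs-based requirement, baseline and three scenarios.

Run:  python examples/04_projection_and_scenarios.py
"""

import oralforce as of
from oralforce.report import format_results

truth = of.default_truth(seed=0)
survey = of.gen_survey(truth, n=20_000, seed=1)
rates = of.estimate_need_rates(survey)
population = of.gen_population(truth, horizon=(2017, 2050))

params = of.ModelParams(
    initial_stock=3053,
    flows={2017: of.FlowAssumptions(inflow_foreign_trained=40,
                                    inflow_returning_domestic=10,
                                    outflow_emigration=25, outflow_absence=20,
                                    outflow_retirement_death=30)},
    pipeline=of.GraduatePipeline(60, 0.08, 0.04, 0.85),
)

baseline = of.run_projection(params, rates, population)
print("baseline (first and last years, printed precision):")
print(format_results(baseline.iloc[[0, -1]]).to_string(index=False))
# ratio > 1 means FTE supply exceeds the needs-based FTE requirement that year

table = of.compare_scenarios(params, of.reference_scenarios(), rates, population)
first = table[table.year == 2017].copy()
print("\n2017 requirement under each scenario:")
print(format_results(first)[["scenario", "fte_requirement", "ratio"]].to_string(index=False))
# adjusted_service_times: longer chair times (30/40/60 min) raise requirement;
# reduced_adult_hours: 20% of dentist time goes to children, so adult capacity
# falls to 80% and the adult requirement rises by exactly 1.25x; combined: both.
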