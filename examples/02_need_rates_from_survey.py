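"""Estimate stratified per-capita visit rates from (synthetic) survey microdata.

Run:  python examples/02_need_rates_from_survey.py
"""

import oralforce as of

truth = of.default_truth(seed=0)
survey = of.gen_survey(truth, n=20_000, seed=1)
print(f"survey: {len(survey)} respondents, "
      f"{survey['visited_12m'].mean():.1%} visited a dentist in 12 months")

rates = of.estimate_need_rates(survey)  # default mapping once->1, twice->2, 3+->3.5
print("\nper-capita annual visits by stratum and visit type:")
print(rates.table.round(3).to_string())
# 'total' is visits/person/year in that sex x age-band stratum; the three
# type columns split it by check-up vs routine vs emergency care and sum to it.

iv = of.bootstrap_need_rates(survey, B=500, seed=2)
print("\n95% bootstrap interval for the total rate, female 45-64:")
lo = iv.lo.loc[("female", "45-64"), "total"]
hi = iv.hi.loc[("female", "45-64"), "total"]
truth_rate = truth.expected_need_rates().table.loc[("female", "45-64"), "total"]
print(f"  [{lo:.3f}, {hi:.3f}]  (generator truth: {truth_rate:.3f})")
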