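"""Deterministic base case: five strategies on the default parameter set.

Builds the documented default (noise-free) parameter set, propagates a
cohort of 65-year-old fit CLL patients through each strategy's Markov model
for 30 years of 28-day cycles, and prints discounted per-patient means with
the incremental ladders.  "DOM" marks strategies that are costlier and no
more effective than an alternative; "EXT.DOM" marks those priced off the
efficient frontier; the remaining ICERs are read against a willingness to
pay of 20,000-50,000 GBP per life-year or QALY.
"""

from cllcea import base_parameter_set, evaluate_strategies, frontier

ps = base_parameter_set()
results = evaluate_strategies(ps)

for scale, label in (("LY", "cost-effectiveness (life-years)"),
                     ("QALY", "cost-utility (QALYs)")):
    fr = frontier(results, scale)
    print(f"\n== {label} ==")
    print(fr.to_frame().to_string(index=False))
    for lam in ps.thresholds_gbp:
        print(f"optimal at £{lam:,.0f}/{scale}: {fr.optimal_at(lam)}")
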