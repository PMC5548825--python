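"""NHS vs societal costing perspective, at age 65 and age 25.

The societal extension adds productivity (friction-cost), informal-care and
out-of-pocket costs to every state, and premature-mortality production
losses at death.  For 65-year-olds (mostly retired) the increments are
small; for 25-year-olds costed by the human-capital method, mortality
losses dominate and strategies that extend life (ibrutinib) become cheap in
societal terms.
"""

from cllcea import (
    apply_societal,
    base_parameter_set,
    evaluate_strategies,
    frontier,
    spec_from_params,
)

for age, approach in ((65.0, "friction"), (25.0, "human-capital")):
    ps = base_parameter_set(starting_age_years=age)
    soc = apply_societal(ps, spec_from_params(ps, approach))
    nhs_res = evaluate_strategies(ps)
    soc_res = evaluate_strategies(soc)
    print(f"\n== starting age {age:.0f}, mortality costing: {approach} ==")
    print(f"{'strategy':>9} {'NHS cost':>12} {'societal':>12} {'QALYs':>7}")
    for name in ("C", "A", "Int2", "B", "Int1"):
        print(f"{name:>9} £{nhs_res[name].mean_cost:>11,.0f}"
              f" £{soc_res[name].mean_cost:>11,.0f}"
              f" {soc_res[name].mean_qaly:>7.2f}")
    fr = frontier(soc_res, "QALY")
    print("societal optimum at £30,000/QALY:", fr.optimal_at(30_000))
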