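"""Scenario analyses and the ibrutinib price threshold.

Runs three built-in scenarios (75% ibrutinib drug-price cut, doubled
responder effect, genomic-test equalisation) and bisects the first-line
ibrutinib drug cost per 28-day cycle for the value at which the genomic
first-line strategy (Int1) becomes optimal at £30,000/QALY.
"""

from cllcea import base_parameter_set, builtin_scenario, run_scenario, threshold_search

ps = base_parameter_set()

for sid in (1, 3, 7):
    rep = run_scenario(builtin_scenario(sid), ps)
    opt = rep["optimal"]["QALY"]
    print(f"{rep['scenario']}: {rep['description']}")
    print("  optimal (QALY):", {f"£{t:,.0f}": s for t, s in opt.items()})

out = threshold_search(
    "cost_ibr_drug_cycle", ps, target_strategy="Int1",
    threshold=30_000.0, effect_scale="QALY",
    bracket=(0.0, ps.value("cost_ibr_drug_cycle")),
)
print(f"\nIbrutinib drug-cost crossover for Int1 at £30,000/QALY: "
      f"{out['status']}, £{out['critical_value']:.0f} per cycle")
print("Below that drug price, stratifying likely FCR non-responders to")
print("first-line ibrutinib is the optimal use of the threshold.")
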